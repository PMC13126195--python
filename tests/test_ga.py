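"""Selection, crossover, both mutation operators and the evolve loop."""

import json
import re

import numpy as np
import pytest

from r2gbga.chemcore import canonicalize
from r2gbga.fitness import Objective
from r2gbga.ga import (
    ExtinctionError,
    GAConfig,
    Individual,
    crossover,
    enforce_scaffold,
    evolve,
    mutate_conventional,
    mutate_reaction,
    select_parents,
)
from r2gbga.reactions import ProvenanceRecord, ReactionPool, ReactionTemplate, trace_route

AMIDE = ReactionTemplate(
    "amide", "amide coupling", "coupling", 1.0,
    "[C:1](=[O:2])[OX2H1].[NX3;H2,H1;!$(NC=O):3]>>[C:1](=[O:2])[N:3]",
)
SULFONAMIDE = ReactionTemplate(
    "sulfonamide", "sulfonamide formation", "coupling", 1.0,
    "[S:1](=[O:2])(=[O:3])[Cl].[NX3;H2,H1;!$(NC=O):4]>>[S:1](=[O:2])(=[O:3])[N:4]",
)


def _pop(smiles_fitness, start_id=0):
    return [
        Individual(
            id=start_id + i,
            molecule=canonicalize(s),
            provenance=ProvenanceRecord(operation="init"),
            fitness=f,
        )
        for i, (s, f) in enumerate(smiles_fitness)
    ]


class TestSelection:
    def test_population_of_two_always_pairs_both(self):
        pop = _pop([("CCO", 1.0), ("CCN", 0.5)])
        rng = np.random.default_rng(0)
        for a, b in select_parents(pop, 20, rng):
            assert {a.id, b.id} == {0, 1}

    def test_uniform_fitness_selects_uniformly_over_top_half(self):
        pop = _pop([(s, 1.0) for s in ["CCO", "CCN", "CCC", "CCF", "CCCl", "CCS",
                                        "CCCC", "CCCO", "CCCN", "CCCS"]])
        rng = np.random.default_rng(1)
        counts = {}
        n_draws = 10_000
        for a, b in select_parents(pop, n_draws, rng):
            counts[a.id] = counts.get(a.id, 0) + 1
        k = 5  # top half of 10
        assert set(counts) <= {ind.id for ind in pop}
        assert len(counts) == k or len(counts) == len(pop)  # only eligible ids drawn
        p = 1 / k
        sigma = (n_draws * p * (1 - p)) ** 0.5
        for c in counts.values():
            assert abs(c - n_draws * p) < 3 * sigma

    def test_top_ranked_selected_most_often(self):
        pop = _pop([("CCO", 10.0), ("CCN", 1.0), ("CCC", 0.9), ("CCF", 0.8)])
        rng = np.random.default_rng(2)
        counts = {}
        for a, _ in select_parents(pop, 2000, rng):
            counts[a.id] = counts.get(a.id, 0) + 1
        assert counts[0] == max(counts.values())

    def test_tiny_population_fatal(self):
        with pytest.raises(ValueError, match="at least 2"):
            select_parents(_pop([("CCO", 1.0)]), 1, np.random.default_rng(0))

    def test_unevaluated_fitness_fatal(self):
        pop = _pop([("CCO", 1.0), ("CCN", None)])
        with pytest.raises(ValueError, match="evaluated"):
            select_parents(pop, 1, np.random.default_rng(0))


class TestCrossover:
    def test_butane_children_are_small_alkanes(self):
        butane = canonicalize("CCCC")
        rng = np.random.default_rng(3)
        seen = set()
        for _ in range(50):
            child = crossover(butane, butane, rng, min_heavy_atoms=1, p_ring=0.0)
            assert child is not None
            assert re.fullmatch(r"C+", child.smiles)  # cut-and-splice of alkanes
            assert 2 <= child.heavy_atom_count <= 6
            seen.add(child.smiles)
        assert len(seen) >= 2  # multiple splice outcomes reachable

    def test_ring_crossover_of_cyclohexane(self):
        cyclohexane = canonicalize("C1CCCCC1")
        rng = np.random.default_rng(4)
        child = crossover(cyclohexane, cyclohexane, rng, min_heavy_atoms=3, p_ring=1.0)
        assert child is not None
        assert child.mol.GetRingInfo().NumRings() >= 1

    def test_impossible_size_window_fails(self):
        pyrene = canonicalize("c1cc2ccc3cccc4ccc(c1)c2c34")
        rng = np.random.default_rng(5)
        child = crossover(pyrene, pyrene, rng, max_tries=1,
                          min_heavy_atoms=100, max_heavy_atoms=200)
        assert child is None


class TestConventionalMutation:
    def test_outputs_sanitize_and_differ(self, fixture_mols):
        rng = np.random.default_rng(6)
        n_success = 0
        for mol in fixture_mols[:20]:
            out = mutate_conventional(mol, rng)
            if out is not None:
                n_success += 1
                assert canonicalize(out.smiles) == out
                assert out.smiles != mol.smiles
        assert n_success >= 15  # the operator set rarely exhausts retries

    def test_methane_can_become_nitrogen_bearing(self):
        rng = np.random.default_rng(7)
        outcomes = set()
        for _ in range(200):
            out = mutate_conventional(canonicalize("C"), rng)
            if out is not None:
                outcomes.add(out.smiles)
        assert any("N" in s for s in outcomes)  # atom-type change reachable

    def test_single_atom_deletion_degenerates_gracefully(self):
        # one heavy atom: deletion impossible, other ops may still apply,
        # but every returned structure is valid
        rng = np.random.default_rng(8)
        for _ in range(20):
            out = mutate_conventional(canonicalize("C"), rng)
            if out is not None:
                assert out.heavy_atom_count >= 1


class TestReactionMutation:
    def test_aniline_plus_acetic_acid_gives_acetanilide(self):
        rng = np.random.default_rng(9)
        res = mutate_reaction(
            canonicalize("Nc1ccccc1"),
            ReactionPool((AMIDE,)),
            [canonicalize("CC(=O)O")],
            rng,
            parent_id=0,
        )
        assert res is not None
        product, prov = res
        assert product.smiles == canonicalize("CC(=O)Nc1ccccc1").smiles
        assert prov.template_id == "amide" and prov.operation == "reaction_mutation"
        assert prov.partner_smiles == ("CC(=O)O",)

    def test_no_applicable_site_counted_separately(self):
        stats = {}
        res = mutate_reaction(
            canonicalize("CCCC"),
            ReactionPool((AMIDE,)),
            [canonicalize("CC(=O)O")],
            np.random.default_rng(10),
            stats=stats,
        )
        assert res is None and stats["n_no_site"] == 1

    def test_template_weights_steer_sampling(self):
        heavy = ReactionTemplate("amide_w", AMIDE.name, "coupling", 0.999, AMIDE.smarts)
        light = ReactionTemplate("sulf_w", SULFONAMIDE.name, "coupling", 0.001, SULFONAMIDE.smarts)
        pool = ReactionPool((heavy, light))
        partners = [canonicalize("CC(=O)O"), canonicalize("O=S(=O)(Cl)C")]
        aniline = canonicalize("Nc1ccccc1")
        rng = np.random.default_rng(11)
        n, counts = 1000, {"amide_w": 0, "sulf_w": 0}
        for _ in range(n):
            res = mutate_reaction(aniline, pool, partners, rng)
            assert res is not None
            counts[res[1].template_id] += 1
        p = 0.999
        sigma = (n * p * (1 - p)) ** 0.5
        assert abs(counts["amide_w"] - n * p) < 3 * sigma


class TestScaffold:
    def test_resorcinol_contains_itself(self):
        assert enforce_scaffold(canonicalize("Oc1cccc(O)c1"), "Oc1cccc(O)c1")

    def test_benzene_lacks_resorcinol(self):
        assert not enforce_scaffold(canonicalize("c1ccccc1"), "Oc1cccc(O)c1")

    def test_invalid_smarts_fatal_at_config(self):
        with pytest.raises(ValueError, match="scaffold SMARTS"):
            GAConfig(scaffold_smarts="((((")


def _archive_signature(result):
    return json.dumps(
        [
            (
                i,
                result.archive[i].smiles,
                result.archive[i].provenance.operation,
                result.archive[i].provenance.template_id,
                result.archive[i].fitness,
            )
            for i in sorted(result.archive)
        ]
        + [g.population_smiles for g in result.trajectory.generations]
    )


@pytest.fixture(scope="module")
def objective():
    return Objective(
        mode="maximize_similarity", target=canonicalize("CC(=O)Nc1ccc(Br)cc1")
    )


class TestEvolve:
    def test_zero_generations_yields_initial_only(self, fixture_mols, objective, toy_pool):
        cfg = GAConfig(population_size=20, n_generations=0, seed=0)
        res = evolve(cfg, fixture_mols, objective, pool=toy_pool)
        assert len(res.trajectory.generations) == 1
        assert res.trajectory.generations[0].generation == 0

    @pytest.mark.parametrize("mode", ["reaction", "conventional"])
    def test_identical_seed_identical_archive(self, fixture_mols, objective, toy_pool, motifs, mode):
        cfg = GAConfig(population_size=25, n_generations=3, crossover_rate=0.5,
                       mutation_rate=0.8, mutation_mode=mode, seed=13)
        runs = [
            evolve(cfg, fixture_mols, objective, pool=toy_pool, building_blocks=motifs)
            for _ in range(2)
        ]
        assert _archive_signature(runs[0]) == _archive_signature(runs[1])

    def test_best_fitness_monotone_under_elitism(self, fixture_mols, objective, toy_pool, motifs):
        cfg = GAConfig(population_size=25, n_generations=4, elite_fraction=0.2,
                       mutation_rate=1.0, crossover_rate=0.5, seed=17)
        res = evolve(cfg, fixture_mols, objective, pool=toy_pool, building_blocks=motifs)
        best = res.trajectory.best_per_generation
        assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))

    def test_populations_deduplicated_and_valid(self, fixture_mols, objective, toy_pool, motifs):
        cfg = GAConfig(population_size=25, n_generations=3, mutation_rate=1.0, seed=19)
        res = evolve(cfg, fixture_mols, objective, pool=toy_pool, building_blocks=motifs)
        for g in res.trajectory.generations:
            assert len(set(g.population_smiles)) == len(g.population_smiles)
            for s in g.population_smiles:
                assert canonicalize(s).smiles == s

    def test_reaction_only_runs_have_pure_replayable_routes(
        self, fixture_mols, objective, toy_pool, motifs
    ):
        cfg = GAConfig(population_size=20, n_generations=3, crossover_rate=0.0,
                       mutation_rate=1.0, mutation_mode="reaction", seed=23)
        res = evolve(cfg, fixture_mols, objective, pool=toy_pool, building_blocks=motifs)
        non_init = [i for i in res.archive.values() if i.provenance.operation != "init"]
        assert non_init
        for ind in non_init:
            trace = trace_route(ind.id, res.archive, pool=toy_pool)
            assert trace.gaps == []
            assert trace.replay_ok is True

    def test_scaffold_filter_sound(self, toy_pool, motifs, objective):
        scaffold = "Oc1cccc(O)c1"
        init = [canonicalize(s) for s in
                ["Oc1cccc(O)c1", "Cc1cc(O)cc(O)c1", "Oc1cccc(O)c1Br",
                 "OB(O)c1cc(O)cc(O)c1", "Oc1cc(O)ccc1N"]]
        cfg = GAConfig(population_size=15, n_generations=3, crossover_rate=0.0,
                       mutation_rate=1.0, scaffold_smarts=scaffold, seed=29)
        res = evolve(cfg, init, objective, pool=toy_pool, building_blocks=motifs)
        for g in res.trajectory.generations:
            for s in g.population_smiles:
                assert enforce_scaffold(canonicalize(s), scaffold)

    def test_extinction_without_elites_is_fatal(self):
        inert = [canonicalize("CCCC"), canonicalize("CCCCC")]
        cfg = GAConfig(population_size=2, n_generations=2, crossover_rate=0.0,
                       mutation_rate=1.0, mutation_mode="reaction",
                       elite_fraction=0.0, min_heavy_atoms=1, seed=31)
        objective = Objective(mode="maximize_similarity", target=canonicalize("CCO"))
        with pytest.raises(ExtinctionError):
            evolve(cfg, inert, objective, pool=ReactionPool((AMIDE,)))

    def test_reaction_mode_requires_pool(self, fixture_mols):
        cfg = GAConfig(population_size=10, n_generations=1)
        objective = Objective(mode="maximize_similarity", target=fixture_mols[0])
        with pytest.raises(ValueError, match="ReactionPool"):
            evolve(cfg, fixture_mols, objective, pool=None)

    def test_config_rejects_bad_rates(self):
        with pytest.raises(ValueError):
            GAConfig(crossover_rate=1.5)
        with pytest.raises(ValueError):
            GAConfig(elite_fraction=1.0)
        with pytest.raises(ValueError):
            GAConfig(mutation_mode="quantum")
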