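"""Reaction pools, site finding, forward application and route tracing."""

import pytest

from r2gbga.chemcore import canonicalize
from r2gbga.ga import Individual
from r2gbga.reactions import (
    PoolFormatError,
    ProvenanceRecord,
    ReactionPool,
    ReactionTemplate,
    apply_reaction,
    find_sites,
    load_pool,
    remove_top_k,
    save_pool,
    subset_pool,
    trace_route,
)

AMIDE = ReactionTemplate(
    "amide", "amide coupling", "coupling", 1.0,
    "[C:1](=[O:2])[OX2H1].[NX3;H2,H1;!$(NC=O):3]>>[C:1](=[O:2])[N:3]",
)
SUZUKI = ReactionTemplate(
    "suzuki", "Suzuki coupling", "coupling", 1.0,
    "[c:1]B(O)O.[c:2][Br,I]>>[c:1][c:2]",
)
BROM = ReactionTemplate(
    "brom", "aromatic bromination", "substitution", 1.0, "[c;H1:1]>>[c:1]Br"
)


class TestPoolLoading:
    def test_toy_pool_loads_all_templates(self, toy_pool):
        assert len(toy_pool) == 12
        assert {t.category for t in toy_pool} <= {"coupling", "fgi", "substitution", "other"}

    def test_template_role_counts_match_smarts(self, toy_pool):
        for t in toy_pool:
            assert t.n_reactant_roles == t.smarts.split(">>")[0].count(".") + 1

    def test_malformed_line_skipped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "pool.tsv"
        p.write_text(
            "id\tname\tcategory\tweight\treaction_smarts\n"
            "a\tA\tcoupling\t1\t[c;H1:1]>>[c:1]Br\n"
            "bad\tB\tcoupling\t1\tnot_a_smarts(((\n"
            "c\tC\tfgi\t1\t[c:1][N+](=[O])[O-]>>[c:1][NH2]\n"
        )
        pool = load_pool(p)
        assert len(pool) == 2
        assert any("skipped 1 invalid" in r.message for r in caplog.records)

    def test_empty_pool_fatal(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("id\tname\tcategory\tweight\treaction_smarts\n")
        with pytest.raises(PoolFormatError, match="no valid"):
            load_pool(p)

    def test_duplicate_id_fatal(self):
        with pytest.raises(PoolFormatError, match="duplicate"):
            ReactionPool((BROM, BROM))

    def test_save_load_roundtrip(self, toy_pool, tmp_path):
        p = tmp_path / "pool.tsv"
        save_pool(toy_pool, p)
        again = load_pool(p)
        assert [t.id for t in again] == [t.id for t in toy_pool]
        assert [t.smarts for t in again] == [t.smarts for t in toy_pool]


class TestFindSites:
    def test_aniline_matches_amine_role_only(self):
        aniline = canonicalize("Nc1ccccc1")
        sites = find_sites(aniline, ReactionPool((AMIDE,)))
        assert sites and all(s.role_index == 1 for s in sites)

    def test_no_sites_on_inert_molecule(self):
        # no boronic acid / aryl halide anywhere in hexane
        sites = find_sites(canonicalize("CCCCCC"), ReactionPool((SUZUKI,)))
        assert sites == []

    def test_diboronic_acid_gives_two_suzuki_sites(self):
        diboronic = canonicalize("OB(O)c1ccc(B(O)O)cc1")
        sites = find_sites(diboronic, ReactionPool((SUZUKI,)))
        boron_sites = [s for s in sites if s.role_index == 0]
        assert len(boron_sites) == 2
        assert boron_sites[0].atom_map != boron_sites[1].atom_map

    def test_matches_bruteforce_enumeration(self, toy_pool, fixture_mols):
        # independent oracle: raw substructure matching per (template, role)
        for mol in fixture_mols[:40]:
            expected = []
            for t in toy_pool:
                for role in range(t.n_reactant_roles):
                    patt = t.rxn.GetReactantTemplate(role)
                    for match in sorted(mol.mol.GetSubstructMatches(patt)):
                        expected.append((t.id, role, tuple(match)))
            got = [(s.template_id, s.role_index, s.atom_map) for s in find_sites(mol, toy_pool)]
            assert got == expected


class TestApplyReaction:
    def test_amide_coupling_forward(self):
        out = apply_reaction(AMIDE, [canonicalize("CC(=O)O"), canonicalize("CN")])
        assert canonicalize("CNC(C)=O").smiles in {o.product.smiles for o in out}

    def test_suzuki_gives_biphenyl(self):
        out = apply_reaction(
            SUZUKI, [canonicalize("OB(O)c1ccccc1"), canonicalize("Brc1ccccc1")]
        )
        assert canonicalize("c1ccc(-c2ccccc2)cc1").smiles in {o.product.smiles for o in out}

    def test_invalid_product_dropped_and_counted(self):
        hexafluoro = ReactionTemplate(
            "bad", "valence breaker", "other", 1.0, "[CX4;H4:1]>>[C:1](F)(F)(F)(F)F"
        )
        stats = {}
        out = apply_reaction(hexafluoro, [canonicalize("C")], stats=stats)
        assert out == []
        assert stats["n_dropped_sanitization"] >= 1

    def test_wrong_reactant_count_rejected(self):
        with pytest.raises(ValueError, match="needs 2 reactants"):
            apply_reaction(AMIDE, [canonicalize("CC(=O)O")])

    def test_site_restricts_outcomes(self):
        resorcinol = canonicalize("Oc1cccc(O)c1")
        pool = ReactionPool((BROM,))
        all_products = {o.product.smiles for o in apply_reaction(BROM, [resorcinol])}
        assert len(all_products) == 3  # three symmetry-distinct positions
        for site in find_sites(resorcinol, pool):
            out = apply_reaction(BROM, [resorcinol], site=site)
            assert len(out) == 1
            assert out[0].product.smiles in all_products

    def test_main_product_keeps_parent_and_byproducts_recorded(self, toy_pool):
        hydrolysis = toy_pool.by_id("ester_hydrolysis")
        out = apply_reaction(hydrolysis, [canonicalize("CCOC(C)=O")])
        assert len(out) == 1
        # main product = largest parent-derived fragment (the acid)
        assert out[0].product.smiles == canonicalize("CC(=O)O").smiles
        assert out[0].byproducts == (canonicalize("CCO").smiles,)

    def test_symmetric_matches_deduplicated(self):
        # para-disubstituted benzene: two ortho positions give one product
        out = apply_reaction(BROM, [canonicalize("c1ccccc1")])
        assert len(out) == 1
        assert out[0].product.smiles == canonicalize("Brc1ccccc1").smiles


def _ind(i, smiles, prov):
    return Individual(id=i, molecule=canonicalize(smiles), provenance=prov)


class TestTraceRoute:
    def test_single_reaction_step(self, toy_pool):
        archive = {
            0: _ind(0, "Nc1ccccc1", ProvenanceRecord(operation="init")),
            1: _ind(
                1,
                "CC(=O)Nc1ccccc1",
                ProvenanceRecord(
                    operation="reaction_mutation",
                    template_id="amide_coupling",
                    parent_ids=(0,),
                    partner_smiles=("CC(=O)O",),
                    parent_role=1,
                ),
            ),
        }
        trace = trace_route(1, archive, pool=toy_pool)
        assert len(trace.steps) == 1 and trace.gaps == []
        assert trace.replay_ok is True
        assert set(trace.leaves) == {"Nc1ccccc1", "CC(=O)O"}

    def test_crossover_is_a_gap(self):
        archive = {
            0: _ind(0, "CCO", ProvenanceRecord(operation="init")),
            1: _ind(1, "CCN", ProvenanceRecord(operation="init")),
            2: _ind(2, "CCOCC", ProvenanceRecord(operation="crossover", parent_ids=(0, 1))),
        }
        trace = trace_route(2, archive)
        assert trace.steps == [] and len(trace.gaps) == 1

    def test_three_step_chain_replays(self, toy_pool):
        start = canonicalize("Nc1ccc(Br)cc1")
        chain = [
            ("amide_coupling", 1, ("CC(=O)O",)),       # N-acylation
            ("suzuki", 1, ("OB(O)c1ccccc1",)),         # aryl-aryl coupling
            ("aromatic_bromination", 0, ()),            # ring bromination
        ]
        archive = {0: _ind(0, start.smiles, ProvenanceRecord(operation="init"))}
        current = start
        for i, (tid, role, partners) in enumerate(chain, start=1):
            template = toy_pool.by_id(tid)
            reactants = [canonicalize(s) for s in partners]
            reactants.insert(role, current)
            outcome = apply_reaction(template, reactants)[0]
            archive[i] = _ind(
                i,
                outcome.product.smiles,
                ProvenanceRecord(
                    operation="reaction_mutation",
                    template_id=tid,
                    parent_ids=(i - 1,),
                    partner_smiles=partners,
                    parent_role=role,
                ),
            )
            current = outcome.product
        trace = trace_route(3, archive, pool=toy_pool)
        assert len(trace.steps) == 3 and trace.gaps == []
        assert trace.replay_ok is True
        assert trace.final_smiles == current.smiles

    def test_missing_parent_is_fatal(self):
        archive = {
            5: _ind(
                5,
                "CC(=O)Nc1ccccc1",
                ProvenanceRecord(
                    operation="reaction_mutation",
                    template_id="amide_coupling",
                    parent_ids=(99,),
                ),
            )
        }
        with pytest.raises(KeyError, match="missing parent"):
            trace_route(5, archive)

    def test_provenance_contract_violations(self):
        with pytest.raises(ValueError, match="template_id"):
            ProvenanceRecord(operation="reaction_mutation", parent_ids=(0,))
        with pytest.raises(ValueError, match="2 parent_ids"):
            ProvenanceRecord(operation="crossover", parent_ids=(0,))


class TestPoolEditing:
    def test_full_fraction_identity(self, toy_pool):
        sub = subset_pool(toy_pool, 1.0, seed=0)
        assert [t.id for t in sub] == [t.id for t in toy_pool]

    def test_subset_deterministic_under_seed(self, toy_pool):
        a = subset_pool(toy_pool, 0.5, seed=42)
        b = subset_pool(toy_pool, 0.5, seed=42)
        assert len(a) == 6
        assert [t.id for t in a] == [t.id for t in b]

    def test_different_seeds_differ(self):
        big = ReactionPool(
            tuple(
                ReactionTemplate(f"b{i}", f"brom {i}", "substitution", 1.0, "[c;H1:1]>>[c:1]Br")
                for i in range(100)
            )
        )
        ids = {tuple(t.id for t in subset_pool(big, 0.5, seed=s)) for s in range(5)}
        assert len(ids) == 5

    def test_empty_subset_rejected(self, toy_pool):
        with pytest.raises(ValueError, match="empty"):
            subset_pool(toy_pool, 0.001, seed=0)

    def test_remove_top_k(self, toy_pool):
        assert remove_top_k(toy_pool, {}, 0) is toy_pool
        counts = {"amide_coupling": 5, "suzuki": 3, "nitro_reduction": 1}
        out = remove_top_k(toy_pool, counts, 1)
        assert len(out) == 11 and "amide_coupling" not in {t.id for t in out}

    def test_remove_top_k_tie_broken_by_id(self, toy_pool):
        counts = {"suzuki": 5, "amide_coupling": 5}
        out = remove_top_k(toy_pool, counts, 1)
        assert "amide_coupling" not in {t.id for t in out}  # id-earlier removed
        assert "suzuki" in {t.id for t in out}

    def test_remove_too_many_rejected(self, toy_pool):
        with pytest.raises(ValueError):
            remove_top_k(toy_pool, {}, 12)
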