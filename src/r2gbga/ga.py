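"""The evolutionary engine.

Population management, rank-based selection, graph-level cut-and-splice
crossover (after Jensen's graph-based GA), the conventional atom/bond
mutation baseline, the reaction-driven mutation that is the point of the
method, scaffold constraints, and the generational loop.

Two mutation modes are supported:

``conventional``
    random atom/bond edits on the molecular graph (add/delete/retype an
    atom, change a bond order, form or break a ring bond) — chemically
    valid but not necessarily synthetically feasible.

``reaction``
    the molecule is edited only by applying a reaction template from the
    pool at a matched reactive site, with partner reactants drawn from a
    building-block list and/or the current population; every offspring
    therefore corresponds to a named chemical transformation and carries
    full provenance, from which a synthesis route can be traced.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem
from scipy.stats import rankdata

from .chemcore import Molecule, mol_to_molecule
from .reactions import (
    ProvenanceRecord,
    ReactionPool,
    apply_reaction,
    find_sites,
    matches_role,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GAConfig",
    "Individual",
    "Population",
    "GenerationRecord",
    "RunTrajectory",
    "RunResult",
    "ExtinctionError",
    "select_parents",
    "crossover",
    "mutate_conventional",
    "mutate_reaction",
    "enforce_scaffold",
    "evolve",
]


@dataclass(frozen=True)
class GAConfig:
    """Hyperparameters of one GA run.

    Defaults follow the package's declared conventions: crossover always
    attempted, mutation on half the offspring, 10% elitism, offspring
    heavy-atom window [5, 60]. ``mutation_mode`` selects the baseline
    (``conventional``) or the reaction-driven operator (``reaction``).
    """

    population_size: int = 100
    n_generations: int = 10
    crossover_rate: float = 1.0
    mutation_rate: float = 0.5
    mutation_mode: str = "reaction"
    scaffold_smarts: Optional[str] = None
    partner_source: str = "building_blocks"
    seed: int = 0
    elite_fraction: float = 0.1
    min_heavy_atoms: int = 5
    max_heavy_atoms: int = 60
    p_ring_crossover: float = 0.3
    crossover_max_tries: int = 10
    mutation_max_tries: int = 10
    offspring_attempt_factor: int = 10

    def __post_init__(self):
        if not 0 <= self.crossover_rate <= 1:
            raise ValueError("crossover_rate must be in [0,1]")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0,1]")
        if not 0 <= self.elite_fraction < 1:
            raise ValueError("elite_fraction must be in [0,1)")
        if self.mutation_mode not in ("reaction", "conventional"):
            raise ValueError(f"unknown mutation_mode {self.mutation_mode!r}")
        if self.partner_source not in ("building_blocks", "population", "both"):
            raise ValueError(f"unknown partner_source {self.partner_source!r}")
        if self.scaffold_smarts is not None:
            if Chem.MolFromSmarts(self.scaffold_smarts) is None:
                raise ValueError(f"invalid scaffold SMARTS {self.scaffold_smarts!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GAConfig":
        return cls(**d)


@dataclass
class Individual:
    id: int
    molecule: Molecule
    provenance: ProvenanceRecord
    generation_born: int = 0
    fitness: Optional[float] = None

    @property
    def smiles(self) -> str:
        return self.molecule.smiles


@dataclass
class Population:
    members: List[Individual]
    generation_index: int = 0
    capacity: int = 0

    def __post_init__(self):
        smiles = [m.smiles for m in self.members]
        if len(set(smiles)) != len(smiles):
            raise ValueError("duplicate canonical SMILES in population")
        if self.capacity and len(self.members) > self.capacity:
            raise ValueError("population exceeds capacity")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GenerationRecord:
    generation: int
    best_fitness: float
    mean_fitness: float
    population_smiles: List[str]
    operator_usage: Dict[str, int] = field(default_factory=dict)
    stats: Dict[str, int] = field(default_factory=dict)


@dataclass
class RunTrajectory:
    generations: List[GenerationRecord] = field(default_factory=list)

    @property
    def best_per_generation(self) -> List[float]:
        return [g.best_fitness for g in self.generations]

    def operator_usage_total(self) -> Dict[str, int]:
        total: Dict[str, int] = {}
        for g in self.generations:
            for k, v in g.operator_usage.items():
                total[k] = total.get(k, 0) + v
        return total


@dataclass
class RunResult:
    trajectory: RunTrajectory
    archive: Dict[int, Individual]
    population: Population
    config: GAConfig


class ExtinctionError(RuntimeError):
    """No valid offspring could be produced and no elites survive."""


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def _ranked(members: Sequence[Individual]) -> List[Individual]:
    # fitness descending, canonical SMILES ascending for reproducible ties
    return sorted(members, key=lambda i: (-i.fitness, i.smiles))


def select_parents(
    pop: Sequence[Individual], n_pairs: int, rng: np.random.Generator
) -> List[Tuple[Individual, Individual]]:
    """Rank-proportional sampling with replacement from the top half.

    The best of the eligible set gets weight k, the worst weight 1 (k =
    eligible size). The two parents of a pair are always distinct
    individuals. The eligible set is the top half of the population by
    fitness, widened to at least two members.
    """
    members = list(pop)
    if len(members) < 2:
        raise ValueError("population must have at least 2 members for selection")
    if any(m.fitness is None for m in members):
        raise ValueError("all members must have evaluated fitness")
    ranked = _ranked(members)
    k = max(2, math.ceil(len(ranked) / 2))
    top = ranked[:k]
    # rank-proportional weights; fitness ties share their average rank so
    # equally fit members are selected equally often
    avg_rank = rankdata([-t.fitness for t in top], method="average")
    weights = (k + 1) - avg_rank
    probs = weights / weights.sum()
    pairs = []
    for _ in range(n_pairs):
        i = rng.choice(k, p=probs)
        j = rng.choice(k, p=probs)
        while j == i:
            j = rng.choice(k, p=probs)
        pairs.append((top[i], top[j]))
    return pairs


# ---------------------------------------------------------------------------
# crossover (cut-and-splice on the molecular graph)
# ---------------------------------------------------------------------------

def _single_cut_pieces(mol, rng: np.random.Generator):
    bonds = [
        b.GetIdx()
        for b in mol.GetBonds()
        if not b.IsInRing() and b.GetBondType() == Chem.BondType.SINGLE
    ]
    if not bonds:
        return None
    bid = int(rng.choice(bonds))
    try:
        frag = Chem.FragmentOnBonds(mol, [bid], addDummies=True, dummyLabels=[(1, 1)])
        pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=False)
    except Exception:
        return None
    return pieces if len(pieces) == 2 else None


def _double_cut_pieces(mol, rng: np.random.Generator):
    ri = mol.GetRingInfo()
    ring_choices = []
    for ring_bonds in ri.BondRings():
        cuttable = [
            b
            for b in ring_bonds
            if mol.GetBondWithIdx(b).GetBondType() == Chem.BondType.SINGLE
        ]
        if len(cuttable) >= 2:
            ring_choices.append(cuttable)
    if not ring_choices:
        return None
    cuttable = ring_choices[int(rng.integers(len(ring_choices)))]
    pair = rng.choice(len(cuttable), size=2, replace=False)
    bids = [cuttable[int(pair[0])], cuttable[int(pair[1])]]
    try:
        frag = Chem.FragmentOnBonds(
            mol, bids, addDummies=True, dummyLabels=[(1, 1), (2, 2)]
        )
        pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=False)
    except Exception:
        return None
    # a two-bond cut of one ring splits the molecule into exactly two pieces,
    # each carrying one dummy of each label
    if len(pieces) != 2:
        return None
    for p in pieces:
        labels = sorted(a.GetIsotope() for a in p.GetAtoms() if a.GetAtomicNum() == 0)
        if labels != [1, 2]:
            return None
    return pieces


def _splice(fa, fb):
    """Join two fragments by bonding the neighbors of same-label dummies."""
    combo = Chem.RWMol(Chem.CombineMols(fa, fb))
    by_label: Dict[int, List[int]] = {}
    for atom in combo.GetAtoms():
        if atom.GetAtomicNum() == 0:
            by_label.setdefault(atom.GetIsotope(), []).append(atom.GetIdx())
    if not by_label or any(len(v) != 2 for v in by_label.values()):
        return None
    to_remove = []
    for label, (d1, d2) in sorted(by_label.items()):
        n1 = combo.GetAtomWithIdx(d1).GetNeighbors()
        n2 = combo.GetAtomWithIdx(d2).GetNeighbors()
        if len(n1) != 1 or len(n2) != 1:
            return None
        a1, a2 = n1[0].GetIdx(), n2[0].GetIdx()
        if a1 == a2 or combo.GetBondBetweenAtoms(a1, a2) is not None:
            return None
        combo.AddBond(a1, a2, Chem.BondType.SINGLE)
        to_remove.extend([d1, d2])
    for idx in sorted(to_remove, reverse=True):
        combo.RemoveAtom(idx)
    mol = combo.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    if len(Chem.GetMolFrags(mol)) != 1:
        return None
    return mol


def crossover(
    a: Molecule,
    b: Molecule,
    rng: np.random.Generator,
    max_tries: int = 10,
    min_heavy_atoms: int = 5,
    max_heavy_atoms: int = 60,
    p_ring: float = 0.3,
) -> Optional[Molecule]:
    """Cut-and-splice crossover of two parent graphs.

    With probability ``p_ring`` a double cut through a ring of each
    parent is attempted (exchanging ring arcs); otherwise a single
    acyclic-bond cut. Complementary fragments are spliced and the first
    sanitized child inside the heavy-atom window within ``max_tries``
    attempts is returned, else None.
    """
    for _ in range(max_tries):
        use_ring = rng.random() < p_ring
        cutter = _double_cut_pieces if use_ring else _single_cut_pieces
        pa = cutter(a.mol, rng)
        pb = cutter(b.mol, rng)
        if pa is None or pb is None:
            continue
        fa = pa[int(rng.integers(2))]
        fb = pb[int(rng.integers(2))]
        child = _splice(fa, fb)
        if child is None:
            continue
        n = child.GetNumHeavyAtoms()
        if not (min_heavy_atoms <= n <= max_heavy_atoms):
            continue
        try:
            return mol_to_molecule(child)
        except Exception:
            continue
    return None


# ---------------------------------------------------------------------------
# conventional mutation (atom/bond edits)
# ---------------------------------------------------------------------------

_ELEMENTS = (6, 7, 8, 9, 16, 17)  # C N O F S Cl


def _op_append_atom(rw, rng):
    candidates = [
        a.GetIdx() for a in rw.GetAtoms() if a.GetImplicitValence() > 0
    ]
    if not candidates:
        return False
    idx = int(rng.choice(candidates))
    new = rw.AddAtom(Chem.Atom(int(rng.choice(_ELEMENTS))))
    rw.AddBond(idx, new, Chem.BondType.SINGLE)
    return True


def _op_delete_atom(rw, rng):
    if rw.GetNumAtoms() <= 1:
        return False
    order = rng.permutation(rw.GetNumAtoms())
    for idx in order:
        atom = rw.GetAtomWithIdx(int(idx))
        deg = atom.GetDegree()
        if deg == 1:
            rw.RemoveAtom(int(idx))
            return True
        if deg == 2 and not atom.GetIsAromatic():
            n1, n2 = [n.GetIdx() for n in atom.GetNeighbors()]
            if rw.GetBondBetweenAtoms(n1, n2) is None:
                rw.RemoveAtom(int(idx))
                rw.AddBond(n1, n2, Chem.BondType.SINGLE)
                return True
    return False


def _op_change_atom(rw, rng):
    idx = int(rng.integers(rw.GetNumAtoms()))
    atom = rw.GetAtomWithIdx(idx)
    choices = [z for z in _ELEMENTS if z != atom.GetAtomicNum()]
    atom.SetAtomicNum(int(rng.choice(choices)))
    atom.SetFormalCharge(0)
    atom.SetNoImplicit(False)
    return True


def _op_change_bond(rw, rng):
    bonds = [
        b
        for b in rw.GetBonds()
        if not b.GetIsAromatic()
        and b.GetBondType() in (Chem.BondType.SINGLE, Chem.BondType.DOUBLE)
    ]
    if not bonds:
        return False
    b = bonds[int(rng.integers(len(bonds)))]
    b.SetBondType(
        Chem.BondType.DOUBLE
        if b.GetBondType() == Chem.BondType.SINGLE
        else Chem.BondType.SINGLE
    )
    return True


def _op_add_ring_bond(rw, rng):
    mol = rw.GetMol()
    dm = Chem.GetDistanceMatrix(mol)
    pairs = []
    for i in range(rw.GetNumAtoms()):
        for j in range(i + 1, rw.GetNumAtoms()):
            if (
                dm[i, j] >= 3
                and rw.GetBondBetweenAtoms(i, j) is None
                and rw.GetAtomWithIdx(i).GetImplicitValence() > 0
                and rw.GetAtomWithIdx(j).GetImplicitValence() > 0
            ):
                pairs.append((i, j))
    if not pairs:
        return False
    i, j = pairs[int(rng.integers(len(pairs)))]
    rw.AddBond(i, j, Chem.BondType.SINGLE)
    return True


def _op_delete_bond(rw, rng):
    ring_bonds = [
        b for b in rw.GetBonds() if b.IsInRing() and not b.GetIsAromatic()
    ]
    if not ring_bonds:
        return False
    b = ring_bonds[int(rng.integers(len(ring_bonds)))]
    rw.RemoveBond(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
    return True


_CONVENTIONAL_OPS = (
    _op_append_atom,
    _op_delete_atom,
    _op_change_atom,
    _op_change_bond,
    _op_add_ring_bond,
    _op_delete_bond,
)


def mutate_conventional(
    mol: Molecule, rng: np.random.Generator, max_tries: int = 10
) -> Optional[Molecule]:
    """One random atom/bond edit, retried until a sanitizable molecule
    different from the input emerges, or ``max_tries`` is exhausted."""
    for _ in range(max_tries):
        op = _CONVENTIONAL_OPS[int(rng.integers(len(_CONVENTIONAL_OPS)))]
        rw = Chem.RWMol(mol.mol)
        try:
            ok = op(rw, rng)
        except Exception:
            ok = False
        if not ok:
            continue
        out = rw.GetMol()
        try:
            candidate = mol_to_molecule(out)
        except Exception:
            continue
        if candidate.smiles != mol.smiles and candidate.heavy_atom_count >= 1:
            return candidate
    return None


# ---------------------------------------------------------------------------
# reaction-driven mutation
# ---------------------------------------------------------------------------

class MutationFailure(Exception):
    """Reaction mutation failed; ``reason`` distinguishes the causes."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


def mutate_reaction(
    mol: Molecule,
    pool: ReactionPool,
    partners: Sequence[Molecule],
    rng: np.random.Generator,
    max_tries: int = 10,
    stats: Optional[dict] = None,
    parent_id: int = -1,
) -> Optional[Tuple[Molecule, ProvenanceRecord]]:
    """Mutate by applying one reaction template at a matched reactive site.

    Sites across the whole pool are enumerated; one (template, role,
    site) is drawn with probability proportional to its template's
    weight; the remaining reactant roles are filled by uniform sampling
    from the partner molecules that match those roles; the template is
    applied forward and the main product returned with a provenance
    record naming the template, parent and partners.

    Returns None after ``max_tries`` failed draws. ``stats`` counters
    separate 'no applicable site' from sanitization/partner failures.
    """
    stats = stats if stats is not None else {}
    sites = find_sites(mol, pool)
    if not sites:
        stats["n_no_site"] = stats.get("n_no_site", 0) + 1
        return None
    weights = np.array([pool.by_id(s.template_id).weight for s in sites], dtype=float)
    probs = weights / weights.sum()
    for _ in range(max_tries):
        site = sites[int(rng.choice(len(sites), p=probs))]
        template = pool.by_id(site.template_id)
        partner_mols: List[Molecule] = []
        ok = True
        for role in range(template.n_reactant_roles):
            if role == site.role_index:
                continue
            candidates = [p for p in partners if matches_role(p, template, role)]
            if not candidates:
                ok = False
                break
            partner_mols.append(candidates[int(rng.integers(len(candidates)))])
        if not ok:
            stats["n_no_partner"] = stats.get("n_no_partner", 0) + 1
            continue
        reactants: List[Molecule] = list(partner_mols)
        reactants.insert(site.role_index, mol)
        outcomes = apply_reaction(template, reactants, site=site, stats=stats)
        if not outcomes:
            stats["n_sanitize_fail"] = stats.get("n_sanitize_fail", 0) + 1
            continue
        outcome = outcomes[int(rng.integers(len(outcomes)))]
        prov = ProvenanceRecord(
            operation="reaction_mutation",
            template_id=template.id,
            parent_ids=(parent_id,),
            partner_smiles=tuple(p.smiles for p in partner_mols),
            byproduct_smiles=outcome.byproducts,
            parent_role=site.role_index,
        )
        return outcome.product, prov
    return None


def enforce_scaffold(mol: Molecule, scaffold_smarts: str) -> bool:
    """True iff the molecule contains the scaffold substructure."""
    query = Chem.MolFromSmarts(scaffold_smarts)
    if query is None:
        raise ValueError(f"invalid scaffold SMARTS {scaffold_smarts!r}")
    return mol.mol.HasSubstructMatch(query)


# ---------------------------------------------------------------------------
# the generational loop
# ---------------------------------------------------------------------------

def _evaluate(ind: Individual, objective: Callable[[Molecule], float]) -> None:
    if ind.fitness is None:
        ind.fitness = float(objective(ind.molecule))


def evolve(
    config: GAConfig,
    init_pool: Sequence[Molecule],
    objective: Callable[[Molecule], float],
    pool: Optional[ReactionPool] = None,
    building_blocks: Sequence[Molecule] = (),
    early_stop: Optional[Callable[[GenerationRecord], bool]] = None,
) -> RunResult:
    """Run the genetic algorithm.

    Per generation: select parent pairs from the top half by fitness,
    produce offspring (crossover with probability ``crossover_rate``,
    then mutation with probability ``mutation_rate`` in the configured
    mode), sanitize/deduplicate, apply the scaffold filter when
    configured, evaluate fitness, carry the elite fraction over, and
    truncate to ``population_size``. Fully reproducible under
    ``config.seed``. Returns the trajectory plus the complete provenance
    archive of every individual ever created.
    """
    if not init_pool:
        raise ValueError("init_pool must be non-empty")
    if config.mutation_mode == "reaction" and config.mutation_rate > 0:
        if pool is None or len(pool) == 0:
            raise ValueError("reaction mutation mode requires a non-empty ReactionPool")

    rng = np.random.default_rng(config.seed)
    scaffold_query = (
        Chem.MolFromSmarts(config.scaffold_smarts) if config.scaffold_smarts else None
    )
    archive: Dict[int, Individual] = {}
    ids = itertools.count()

    def new_individual(mol: Molecule, prov: ProvenanceRecord, gen: int) -> Individual:
        ind = Individual(id=next(ids), molecule=mol, provenance=prov, generation_born=gen)
        archive[ind.id] = ind
        return ind

    # --- initial population: dedup by canonical SMILES, truncate
    members: List[Individual] = []
    seen = set()
    for m in init_pool:
        if m.smiles in seen:
            continue
        seen.add(m.smiles)
        members.append(new_individual(m, ProvenanceRecord(operation="init"), 0))
        if len(members) >= config.population_size:
            break
    for ind in members:
        _evaluate(ind, objective)
    members = _ranked(members)

    trajectory = RunTrajectory()

    def record(gen: int, usage: Dict[str, int], stats: Dict[str, int]) -> GenerationRecord:
        fits = [m.fitness for m in members]
        rec = GenerationRecord(
            generation=gen,
            best_fitness=max(fits),
            mean_fitness=float(np.mean(fits)),
            population_smiles=[m.smiles for m in members],
            operator_usage=dict(sorted(usage.items())),
            stats=dict(sorted(stats.items())),
        )
        trajectory.generations.append(rec)
        logger.info(
            "gen %d best %.4f mean %.4f n=%d %s",
            gen, rec.best_fitness, rec.mean_fitness, len(members), stats,
        )
        return rec

    rec = record(0, {}, {})
    if early_stop is not None and early_stop(rec):
        return RunResult(trajectory, archive,
                         Population(members, 0, config.population_size), config)

    partner_base: List[Molecule] = list(building_blocks)

    for gen in range(1, config.n_generations + 1):
        usage: Dict[str, int] = {}
        stats: Dict[str, int] = {
            "n_offspring": 0,
            "n_rejected_duplicate": 0,
            "n_rejected_scaffold": 0,
            "n_rejected_size": 0,
            "n_no_site": 0,
            "n_sanitize_fail": 0,
        }
        n_elite = math.floor(config.elite_fraction * config.population_size)
        target_offspring = config.population_size - n_elite

        if config.partner_source == "building_blocks":
            partners = partner_base
        elif config.partner_source == "population":
            partners = [m.molecule for m in members]
        else:
            partners = partner_base + [m.molecule for m in members]

        current_smiles = {m.smiles for m in members}
        offspring: List[Individual] = []
        offspring_smiles: set = set()
        attempts = 0
        max_attempts = target_offspring * config.offspring_attempt_factor
        while len(offspring) < target_offspring and attempts < max_attempts:
            attempts += 1
            (pa, pb) = select_parents(members, 1, rng)[0]
            base_ind = pa
            candidate: Optional[Individual] = None

            if rng.random() < config.crossover_rate:
                child = crossover(
                    pa.molecule,
                    pb.molecule,
                    rng,
                    max_tries=config.crossover_max_tries,
                    min_heavy_atoms=config.min_heavy_atoms,
                    max_heavy_atoms=config.max_heavy_atoms,
                    p_ring=config.p_ring_crossover,
                )
                if child is not None:
                    candidate = new_individual(
                        child,
                        ProvenanceRecord(
                            operation="crossover", parent_ids=(pa.id, pb.id)
                        ),
                        gen,
                    )
                    usage["crossover"] = usage.get("crossover", 0) + 1
                    base_ind = candidate

            if rng.random() < config.mutation_rate:
                if config.mutation_mode == "reaction":
                    res = mutate_reaction(
                        base_ind.molecule,
                        pool,
                        partners,
                        rng,
                        max_tries=config.mutation_max_tries,
                        stats=stats,
                        parent_id=base_ind.id,
                    )
                    if res is not None:
                        mol, prov = res
                        candidate = new_individual(mol, prov, gen)
                        usage[prov.template_id] = usage.get(prov.template_id, 0) + 1
                else:
                    mol = mutate_conventional(
                        base_ind.molecule, rng, max_tries=config.mutation_max_tries
                    )
                    if mol is not None:
                        candidate = new_individual(
                            mol,
                            ProvenanceRecord(
                                operation="conventional_mutation",
                                parent_ids=(base_ind.id,),
                            ),
                            gen,
                        )
                        usage["conventional_mutation"] = (
                            usage.get("conventional_mutation", 0) + 1
                        )

            if candidate is None:
                continue
            n_heavy = candidate.molecule.heavy_atom_count
            if not (config.min_heavy_atoms <= n_heavy <= config.max_heavy_atoms):
                stats["n_rejected_size"] += 1
                continue
            if scaffold_query is not None and not candidate.molecule.mol.HasSubstructMatch(
                scaffold_query
            ):
                stats["n_rejected_scaffold"] += 1
                continue
            if candidate.smiles in current_smiles or candidate.smiles in offspring_smiles:
                stats["n_rejected_duplicate"] += 1
                continue
            _evaluate(candidate, objective)
            offspring.append(candidate)
            offspring_smiles.add(candidate.smiles)
            stats["n_offspring"] += 1

        if not offspring and n_elite == 0:
            raise ExtinctionError(
                f"generation {gen}: no valid offspring produced in {attempts} "
                f"attempts and elitism is disabled"
            )

        # survivors: elites are guaranteed, then the best of previous
        # members and offspring together (mu+lambda truncation), dedup by
        # SMILES; carried-over members are re-archived as elite copies so
        # provenance chains stay unbroken
        prev_ranked = _ranked(members)
        pool_candidates: List[Tuple[Individual, bool]] = [
            (ind, True) for ind in prev_ranked[:n_elite]
        ]
        rest = [(ind, True) for ind in prev_ranked[n_elite:]]
        rest += [(ind, False) for ind in offspring]
        rest.sort(key=lambda pair: (-pair[0].fitness, pair[0].smiles))
        pool_candidates += rest

        next_members: List[Individual] = []
        next_smiles: set = set()
        for ind, carried in pool_candidates:
            if len(next_members) >= config.population_size:
                break
            if ind.smiles in next_smiles:
                continue
            if carried:
                copy = new_individual(
                    ind.molecule,
                    ProvenanceRecord(operation="elite_copy", parent_ids=(ind.id,)),
                    gen,
                )
                copy.fitness = ind.fitness
                ind = copy
            next_smiles.add(ind.smiles)
            next_members.append(ind)
        members = _ranked(next_members)

        rec = record(gen, usage, stats)
        if early_stop is not None and early_stop(rec):
            break

    return RunResult(
        trajectory,
        archive,
        Population(members, trajectory.generations[-1].generation, config.population_size),
        config,
    )
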