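"""Reaction-template pools, reactive-site search, forward application and
synthesis-route tracing.

The mutation operator of the reaction-regulated GA edits a molecule only
by applying a reaction template (reaction SMARTS) at a matched reactive
site, so every edit corresponds to a named chemical transformation. This
module owns the template pool, the exhaustive reactive-site enumeration,
the forward reaction engine (built on RDKit's ``RunReactants``), and the
provenance walk that reconstructs the synthesis route of any individual
produced by a run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdChemReactions, rdFMCS

from .chemcore import Molecule, MoleculeError, canonicalize, mol_to_molecule

logger = logging.getLogger(__name__)

__all__ = [
    "ReactionTemplate",
    "ReactionPool",
    "SiteMatch",
    "ProvenanceRecord",
    "RouteStep",
    "RouteTrace",
    "PoolFormatError",
    "load_pool",
    "save_pool",
    "find_sites",
    "apply_reaction",
    "ReactionOutcome",
    "trace_route",
    "subset_pool",
    "remove_top_k",
]

CATEGORIES = ("coupling", "fgi", "substitution", "other")


class PoolFormatError(ValueError):
    pass


@dataclass(frozen=True)
class ReactionTemplate:
    """One reaction SMARTS plus metadata; the unit of the reaction pool."""

    id: str
    name: str
    category: str
    weight: float
    smarts: str

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise PoolFormatError(
                f"template {self.id!r}: unknown category {self.category!r}"
            )
        if not self.weight > 0:
            raise PoolFormatError(f"template {self.id!r}: weight must be > 0")
        rxn = rdChemReactions.ReactionFromSmarts(self.smarts)
        if rxn is None or rxn.GetNumReactantTemplates() < 1:
            raise PoolFormatError(
                f"template {self.id!r}: invalid reaction SMARTS {self.smarts!r}"
            )

    @property
    def rxn(self):
        """Parsed RDKit reaction (cached per template)."""
        rxn = _RXN_CACHE.get(self.smarts)
        if rxn is None:
            rxn = rdChemReactions.ReactionFromSmarts(self.smarts)
            rdChemReactions.SanitizeRxn(rxn)
            rxn.Initialize()
            _RXN_CACHE[self.smarts] = rxn
        return rxn

    @property
    def n_reactant_roles(self) -> int:
        return self.rxn.GetNumReactantTemplates()


_RXN_CACHE: dict = {}


@dataclass(frozen=True)
class ReactionPool:
    templates: Tuple[ReactionTemplate, ...]
    source_label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "templates", tuple(self.templates))
        ids = [t.id for t in self.templates]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PoolFormatError(f"duplicate template ids: {dup}")

    def __len__(self) -> int:
        return len(self.templates)

    def __iter__(self):
        return iter(self.templates)

    def by_id(self, template_id: str) -> ReactionTemplate:
        for t in self.templates:
            if t.id == template_id:
                return t
        raise KeyError(template_id)


POOL_COLUMNS = ("id", "name", "category", "weight", "reaction_smarts")


def load_pool(path) -> ReactionPool:
    """Load a reaction pool from the tab-separated pool format.

    Columns: ``id<TAB>name<TAB>category<TAB>weight<TAB>reaction_smarts``
    with a header line. Lines whose SMARTS fail to parse are skipped with
    a warning naming the line number; zero valid templates or a duplicate
    id is fatal.
    """
    templates: List[ReactionTemplate] = []
    bad: List[int] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(h.strip() for h in header) != POOL_COLUMNS:
            raise PoolFormatError(
                f"{path}: expected header {POOL_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                bad.append(lineno)
                continue
            tid, name, category, weight, smarts = (p.strip() for p in parts)
            try:
                templates.append(
                    ReactionTemplate(tid, name, category, float(weight), smarts)
                )
            except (PoolFormatError, ValueError):
                bad.append(lineno)
    if bad:
        logger.warning("%s: skipped %d invalid template line(s): %s", path, len(bad), bad)
    if not templates:
        raise PoolFormatError(f"{path}: no valid reaction templates")
    pool = ReactionPool(tuple(templates), source_label=str(path))
    logger.info("loaded %d reaction templates from %s", len(pool), path)
    return pool


def save_pool(pool: ReactionPool, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(POOL_COLUMNS) + "\n")
        for t in pool:
            fh.write(f"{t.id}\t{t.name}\t{t.category}\t{t.weight:g}\t{t.smarts}\n")


@dataclass(frozen=True)
class SiteMatch:
    """One substructure match of a template's reactant-role pattern."""

    template_id: str
    role_index: int
    atom_map: Tuple[int, ...]


_SITE_CACHE: dict = {}
_ROLE_CACHE: dict = {}
_CACHE_LIMIT = 200_000


def find_sites(mol: Molecule, pool: ReactionPool) -> List[SiteMatch]:
    """Enumerate every reactive site of ``mol`` under every template.

    Exhaustive over all (template, reactant-role) pairs; ordering is
    deterministic (pool order, then role index, then atom indices of the
    match) so downstream sampling is reproducible. Results are memoized
    per (canonical SMILES, pool) — molecules are immutable, so matches
    never change.
    """
    key = (mol.smiles, pool.templates)
    cached = _SITE_CACHE.get(key)
    if cached is not None:
        return list(cached)
    sites: List[SiteMatch] = []
    for template in pool:
        rxn = template.rxn
        for role in range(template.n_reactant_roles):
            pattern = rxn.GetReactantTemplate(role)
            matches = mol.mol.GetSubstructMatches(pattern, uniquify=True)
            for match in sorted(matches):
                sites.append(SiteMatch(template.id, role, tuple(match)))
    if len(_SITE_CACHE) > _CACHE_LIMIT:
        _SITE_CACHE.clear()
    _SITE_CACHE[key] = tuple(sites)
    return sites


def matches_role(mol: Molecule, template: ReactionTemplate, role_index: int) -> bool:
    """True iff ``mol`` matches the reactant pattern of the given role
    (memoized per canonical SMILES)."""
    key = (mol.smiles, template, role_index)
    cached = _ROLE_CACHE.get(key)
    if cached is None:
        pattern = template.rxn.GetReactantTemplate(role_index)
        cached = mol.mol.HasSubstructMatch(pattern)
        if len(_ROLE_CACHE) > _CACHE_LIMIT:
            _ROLE_CACHE.clear()
        _ROLE_CACHE[key] = cached
    return cached


@dataclass(frozen=True)
class ReactionOutcome:
    product: Molecule
    byproducts: Tuple[str, ...]


def _mapno_roles(rxn) -> Dict[int, Tuple[int, int]]:
    """Map atom-map number -> (reactant role, pattern atom index)."""
    table: Dict[int, Tuple[int, int]] = {}
    for role in range(rxn.GetNumReactantTemplates()):
        patt = rxn.GetReactantTemplate(role)
        for atom in patt.GetAtoms():
            m = atom.GetAtomMapNum()
            if m:
                table[m] = (role, atom.GetIdx())
    return table


def _outcome_fragments(product_tuple):
    """Split an outcome's product molecules into sanitized fragments.

    Returns None if any fragment fails sanitization (the whole outcome is
    then dropped — validity conservation).
    """
    frags = []
    for prod in product_tuple:
        for frag in Chem.GetMolFrags(prod, asMols=True, sanitizeFrags=False):
            try:
                Chem.SanitizeMol(frag)
            except Exception:
                return None
            frags.append(frag)
    return frags


def _fragment_roles(frag) -> Dict[int, set]:
    """Roles of the reaction-center atoms present in a product fragment.

    RDKit annotates product atoms that came from mapped template atoms
    with ``old_mapno`` and their source-reactant atom index with
    ``react_atom_idx``; the map number identifies the reactant role.
    """
    roles: Dict[int, set] = {}
    for atom in frag.GetAtoms():
        if atom.HasProp("old_mapno") and atom.HasProp("react_atom_idx"):
            m = int(atom.GetProp("old_mapno"))
            roles.setdefault(m, set()).add(int(atom.GetProp("react_atom_idx")))
    return roles


def _site_consistent(mols, mapno_table, site: SiteMatch) -> bool:
    # every reaction-center atom that originates from the mutated role must
    # be exactly the molecule atom the site match assigned to its pattern
    # atom; needs only atom bookkeeping properties, so it runs on raw
    # (unsanitized) outcomes
    for frag in mols:
        for atom in frag.GetAtoms():
            if not (atom.HasProp("old_mapno") and atom.HasProp("react_atom_idx")):
                continue
            role, patt_idx = mapno_table.get(int(atom.GetProp("old_mapno")), (None, None))
            if role != site.role_index:
                continue
            if int(atom.GetProp("react_atom_idx")) != site.atom_map[patt_idx]:
                return False
    return True


def _main_fragment(frags, mapno_table, parent: Molecule, parent_role: int):
    """Pick the main product: the largest fragment carrying reaction-center
    atoms of the mutated parent's role; falls back to a maximum-common-
    substructure containment check for unmapped templates (approximate)."""
    candidates = []
    for frag in frags:
        roles = {mapno_table[m][0] for m in _fragment_roles(frag) if m in mapno_table}
        if parent_role in roles:
            candidates.append(frag)
    if not candidates and frags:
        # unmapped template fallback: MCS of the parent against each fragment
        best, best_n = None, 0
        for frag in frags:
            try:
                res = rdFMCS.FindMCS(
                    [parent.mol, frag], timeout=1, matchValences=False
                )
                if res.numAtoms > best_n:
                    best, best_n = frag, res.numAtoms
            except Exception:
                continue
        if best is not None and best_n >= 1:
            candidates = [best]
    if not candidates:
        return None
    return max(
        candidates, key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f))
    )


def apply_reaction(
    template: ReactionTemplate,
    reactants: Sequence[Molecule],
    site: Optional[SiteMatch] = None,
    stats: Optional[dict] = None,
    parent_role: Optional[int] = None,
) -> List[ReactionOutcome]:
    """Apply a reaction template forward to an ordered reactant list.

    Returns one :class:`ReactionOutcome` per distinct main product
    (deduplicated by canonical SMILES). The main product of an outcome is
    the fragment with the greatest heavy-atom count that contains at
    least one reaction-center atom of the mutated parent (the reactant at
    ``site.role_index``, or role 0 when no site is given); the remaining
    fragments are byproducts. Outcomes containing any unsanitizable
    fragment are dropped and counted in ``stats['n_dropped_sanitization']``.
    When ``site`` is given, only outcomes arising from that substructure
    match are returned.
    """
    if len(reactants) != template.n_reactant_roles:
        raise ValueError(
            f"template {template.id!r} needs {template.n_reactant_roles} "
            f"reactants, got {len(reactants)}"
        )
    if parent_role is None:
        parent_role = site.role_index if site is not None else 0
    rxn = template.rxn
    mapno_table = _mapno_roles(rxn)
    try:
        raw = rxn.RunReactants(tuple(r.mol for r in reactants))
    except Exception:
        raw = ()
    outcomes: List[ReactionOutcome] = []
    seen = set()
    for product_tuple in raw:
        # cheap site filter first: discard outcomes from other matches
        # before paying for sanitization
        if site is not None and mapno_table and not _site_consistent(
            product_tuple, mapno_table, site
        ):
            continue
        frags = _outcome_fragments(product_tuple)
        if frags is None:
            if stats is not None:
                stats["n_dropped_sanitization"] = stats.get("n_dropped_sanitization", 0) + 1
            continue
        main = _main_fragment(frags, mapno_table, reactants[parent_role], parent_role)
        if main is None:
            if stats is not None:
                stats["n_dropped_sanitization"] = stats.get("n_dropped_sanitization", 0) + 1
            continue
        try:
            product = mol_to_molecule(main)
        except Exception:
            if stats is not None:
                stats["n_dropped_sanitization"] = stats.get("n_dropped_sanitization", 0) + 1
            continue
        if product.smiles in seen:
            continue
        seen.add(product.smiles)
        byproducts = tuple(
            sorted(
                Chem.MolToSmiles(f) for f in frags if f is not main
            )
        )
        outcomes.append(ReactionOutcome(product=product, byproducts=byproducts))
    return outcomes


# ---------------------------------------------------------------------------
# provenance and route tracing
# ---------------------------------------------------------------------------

OPERATIONS = (
    "init",
    "reaction_mutation",
    "conventional_mutation",
    "crossover",
    "elite_copy",
)


@dataclass(frozen=True)
class ProvenanceRecord:
    """How an individual came to be: operation, parents, template, partners.

    For reaction mutations, ``parent_role`` is the reactant role the
    mutated parent occupied and ``partner_smiles`` fills the remaining
    roles in role order, so the full ordered reactant list (and hence the
    route) can be reconstructed exactly.
    """

    operation: str
    template_id: Optional[str] = None
    parent_ids: Tuple[int, ...] = ()
    partner_smiles: Tuple[str, ...] = ()
    byproduct_smiles: Tuple[str, ...] = ()
    parent_role: int = 0

    def __post_init__(self):
        if self.operation not in OPERATIONS:
            raise ValueError(f"unknown operation {self.operation!r}")
        if self.operation == "reaction_mutation" and not self.template_id:
            raise ValueError("reaction_mutation records must carry template_id")
        if self.operation == "crossover" and len(self.parent_ids) != 2:
            raise ValueError("crossover records carry exactly 2 parent_ids")
        object.__setattr__(self, "parent_ids", tuple(self.parent_ids))
        object.__setattr__(self, "partner_smiles", tuple(self.partner_smiles))
        object.__setattr__(self, "byproduct_smiles", tuple(self.byproduct_smiles))


@dataclass(frozen=True)
class RouteStep:
    template_id: str
    reactant_smiles: Tuple[str, ...]
    product_smiles: str
    parent_role: int = 0


@dataclass
class RouteTrace:
    """A synthesis route reconstructed from provenance.

    ``steps`` are the reaction transformations in topological (leaf to
    product) order; ``leaves`` are the precursors taken from the initial
    pool or building-block list; ``gaps`` lists non-reaction provenance
    steps (crossover / conventional mutation) encountered on the walk —
    a route with gaps is not fully reaction-derived. ``replay_ok`` is set
    when the route has been replayed through :func:`apply_reaction`.
    """

    individual_id: int
    final_smiles: str
    steps: List[RouteStep] = field(default_factory=list)
    leaves: List[str] = field(default_factory=list)
    gaps: List[str] = field(default_factory=list)
    replay_ok: Optional[bool] = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "individual_id": self.individual_id,
                "final_smiles": self.final_smiles,
                "steps": [asdict(s) for s in self.steps],
                "leaves": self.leaves,
                "gaps": self.gaps,
                "replay_ok": self.replay_ok,
            },
            indent=2,
        )


def trace_route(
    individual_id: int,
    archive: Mapping[int, "object"],
    pool: Optional[ReactionPool] = None,
) -> RouteTrace:
    """Walk an individual's ancestry back to initial-pool leaves.

    ``archive`` maps individual id -> an object with ``.molecule`` and
    ``.provenance`` attributes (the run archive). Reaction-mutation steps
    are collected in topological order; crossover and conventional-
    mutation ancestors are recorded as gaps (their subtrees are not
    expanded further — the route is not reaction-derived past a gap).
    When ``pool`` is given, the route is replayed step by step through
    :func:`apply_reaction` and ``replay_ok`` records whether the replay
    reproduces every intermediate product.
    """
    if individual_id not in archive:
        raise KeyError(f"individual {individual_id} not in archive")
    final = archive[individual_id]
    steps: List[RouteStep] = []
    leaves: List[str] = []
    gaps: List[str] = []

    def visit(ind_id: int) -> None:
        ind = archive.get(ind_id)
        if ind is None:
            raise KeyError(f"corrupt archive: missing parent record {ind_id}")
        prov = ind.provenance
        if prov.operation == "init":
            leaves.append(ind.molecule.smiles)
            return
        if prov.operation == "elite_copy":
            visit(prov.parent_ids[0])
            return
        if prov.operation == "reaction_mutation":
            parent_id = prov.parent_ids[0]
            visit(parent_id)
            parent = archive[parent_id]
            # ordered reactant list: partners fill the non-parent roles in
            # role order, parent inserted at its recorded role
            reactants = list(prov.partner_smiles)
            reactants.insert(prov.parent_role, parent.molecule.smiles)
            steps.append(
                RouteStep(
                    template_id=prov.template_id,
                    reactant_smiles=tuple(reactants),
                    product_smiles=ind.molecule.smiles,
                    parent_role=prov.parent_role,
                )
            )
            for p in prov.partner_smiles:
                leaves.append(p)
            return
        # crossover / conventional mutation: a gap in the reaction route
        gaps.append(f"{prov.operation}:{ind_id}")
        leaves.append(ind.molecule.smiles)

    visit(individual_id)
    # dedup leaves, keep first-seen order
    seen = set()
    uniq_leaves = []
    for s in leaves:
        if s not in seen:
            seen.add(s)
            uniq_leaves.append(s)
    trace = RouteTrace(
        individual_id=individual_id,
        final_smiles=final.molecule.smiles,
        steps=steps,
        leaves=uniq_leaves,
        gaps=gaps,
    )
    if pool is not None:
        trace.replay_ok = replay_route(trace, pool)
    return trace


def replay_route(trace: RouteTrace, pool: ReactionPool) -> bool:
    """Re-run every step of a route; True iff each recorded product is
    among the main products of re-applying its template to its reactants."""
    for step in trace.steps:
        try:
            template = pool.by_id(step.template_id)
            reactants = [canonicalize(s) for s in step.reactant_smiles]
        except (KeyError, MoleculeError):
            return False
        outcomes = apply_reaction(template, reactants, parent_role=step.parent_role)
        products = {o.product.smiles for o in outcomes}
        if step.product_smiles not in products:
            return False
    return True


def subset_pool(pool: ReactionPool, fraction: float, seed: int) -> ReactionPool:
    """Uniform random subset of the pool without replacement.

    Reproducible under ``seed``; original template order is preserved.
    Used for pool-size sensitivity (ablation) experiments.
    """
    n = len(pool)
    k = int(round(fraction * n))
    if not 0 < fraction <= 1 or k < 1:
        raise ValueError(f"fraction {fraction} yields an empty pool (n={n})")
    if k == n:
        return ReactionPool(pool.templates, source_label=pool.source_label)
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(n, size=k, replace=False).tolist())
    return ReactionPool(
        tuple(pool.templates[i] for i in idx),
        source_label=f"{pool.source_label}[subset {fraction:g} seed {seed}]",
    )


def remove_top_k(
    pool: ReactionPool, usage_counts: Mapping[str, int], k: int
) -> ReactionPool:
    """Remove the k most-used templates (ties broken by template id order).

    The directional ablation: dropping the workhorse reactions and
    regenerating quantifies how much the frequent templates carry.
    """
    if k >= len(pool):
        raise ValueError(f"k={k} must be < pool size {len(pool)}")
    if k == 0:
        return pool
    ranked = sorted(
        pool.templates,
        key=lambda t: (-usage_counts.get(t.id, 0), t.id),
    )
    removed = {t.id for t in ranked[:k]}
    return ReactionPool(
        tuple(t for t in pool.templates if t.id not in removed),
        source_label=f"{pool.source_label}[minus top {k}]",
    )
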