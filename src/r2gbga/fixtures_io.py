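"""File I/O and synthetic fixtures.

Readers/writers for every plain-text format the package exchanges —
SMILES lists, property CSVs, reaction-pool TSVs, provenance JSON-lines,
route JSON, trajectory CSVs and YAML configs — plus a deterministic
synthetic-fixture generator. The generator assembles small drug-like
molecules by decorating a motif library of common medicinal-chemistry
fragments (anilines, aryl halides, acids, boronic acids, a resorcinol
core, ...) with the toy reaction pool, so every fixture molecule is
reachable by the same chemistry the GA mutates with; a declared
property rule (linear in fingerprint popcount, with optional Gaussian
noise) supplies matched property tables for surrogate-model tests. No
external data is downloaded or bundled.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .chemcore import Molecule, MoleculeError, canonicalize
from .ga import GAConfig, Individual, RunResult
from .reactions import (
    ProvenanceRecord,
    ReactionPool,
    RouteTrace,
    apply_reaction,
    find_sites,
    load_pool,
    matches_role,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_smiles_file",
    "write_smiles_file",
    "read_property_csv",
    "write_property_csv",
    "toy_reaction_pool",
    "DEFAULT_MOTIFS",
    "FixtureSpec",
    "generate_toy_pool",
    "generate_reachable_target",
    "write_provenance_jsonl",
    "read_provenance_jsonl",
    "write_trajectory_csv",
    "load_config",
    "save_config",
]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_smiles_file(path) -> Tuple[List[Molecule], int]:
    """Read a SMILES file: one record per line, whitespace-separated
    optional name, '#' comment lines skipped. Unparsable lines are
    logged and counted, never fatal; returns (molecules, n_skipped)."""
    mols: List[Molecule] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            name = parts[1] if len(parts) > 1 else None
            try:
                mols.append(canonicalize(parts[0], name=name))
            except MoleculeError:
                skipped += 1
                logger.warning("%s:%d unparsable SMILES %r", path, lineno, parts[0])
    if skipped:
        logger.warning("%s: skipped %d unparsable line(s)", path, skipped)
    return mols, skipped


def write_smiles_file(path, mols: Sequence[Molecule]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for m in mols:
            fh.write(f"{m.smiles} {m.name}\n" if m.name else f"{m.smiles}\n")


def read_property_csv(path) -> Tuple[List[Molecule], List[float], int]:
    """Read a `smiles,value` training table; malformed rows logged and
    skipped with a count."""
    mols: List[Molecule] = []
    values: List[float] = []
    skipped = 0
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:2]] != ["smiles", "value"]:
            raise ValueError(f"{path}: expected header 'smiles,value', got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                mol = canonicalize(row[0])
                val = float(row[1])
            except (MoleculeError, ValueError, IndexError):
                skipped += 1
                logger.warning("%s:%d malformed row %r", path, lineno, row)
                continue
            mols.append(mol)
            values.append(val)
    if skipped:
        logger.warning("%s: skipped %d malformed row(s)", path, skipped)
    return mols, values, skipped


def write_property_csv(path, mols: Sequence[Molecule], values: Sequence[float]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["smiles", "value"])
        for m, v in zip(mols, values):
            writer.writerow([m.smiles, f"{v:.6g}"])


def toy_reaction_pool() -> ReactionPool:
    """The bundled 12-template medicinal-chemistry toy pool (amide
    coupling, Suzuki, Buchwald-Hartwig, alkylations, reductive
    amination, ester chemistry, nitro reduction, sulfonamide formation,
    aromatic bromination, Williamson ether)."""
    ref = resources.files("r2gbga").joinpath("data/toy_reactions.tsv")
    with resources.as_file(ref) as path:
        return load_pool(path)


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------

#: ~15 drug-like fragments giving the toy reaction pool sites to act on:
#: a resorcinol core, anilines, aryl halides, acids, boronic acids,
#: aldehydes, alcohols, a sulfonyl chloride, amines, a nitroarene.
DEFAULT_MOTIFS: Tuple[str, ...] = (
    "Oc1cccc(O)c1",            # resorcinol
    "Nc1ccccc1",               # aniline
    "Nc1ccc(Br)cc1",           # 4-bromoaniline
    "OC(=O)c1ccccc1",          # benzoic acid
    "CC(=O)O",                 # acetic acid
    "OB(O)c1ccccc1",           # phenylboronic acid
    "Brc1ccccc1",              # bromobenzene
    "Cc1ccc(Br)cc1",           # 4-bromotoluene
    "Oc1ccccc1",               # phenol
    "O=Cc1ccccc1",             # benzaldehyde
    "C1CCNCC1",                # piperidine
    "C1COCCN1",                # morpholine
    "OCc1ccccc1",              # benzyl alcohol
    "O=S(=O)(Cl)c1ccccc1",     # benzenesulfonyl chloride
    "O=[N+]([O-])c1ccccc1",    # nitrobenzene
    "CCBr",                    # bromoethane
)


@dataclass(frozen=True)
class FixtureSpec:
    """Declares a synthetic molecule pool and its property rule.

    Molecules are assembled by decorating motif-library cores with 0-2
    toy reactions; the property of each molecule is
    ``intercept + slope * popcount(ECFP4) + N(0, noise_sigma)`` — a
    smooth, deterministic function over fingerprint space suitable for
    exercising the GP surrogate.
    """

    n_molecules: int = 50
    heavy_atom_range: Tuple[int, int] = (5, 40)
    seed: int = 0
    motif_library: Tuple[str, ...] = DEFAULT_MOTIFS
    slope: float = 0.1
    intercept: float = 1.0
    noise_sigma: float = 0.0
    max_decorations: int = 2
    #: partner reactants for the decorating reactions; defaults to the
    #: motif library itself. A scaffold-constrained pool uses a single
    #: core motif with the full partner set.
    partner_library: Optional[Tuple[str, ...]] = None


def _decorate(
    core: Molecule,
    pool: ReactionPool,
    partners: Sequence[Molecule],
    rng: np.random.Generator,
    n_steps: int,
):
    """Apply up to n_steps random toy reactions to a core; returns the
    product and the realized route (may stop early if no site applies)."""
    current = core
    route = []
    for _ in range(n_steps):
        sites = find_sites(current, pool)
        if not sites:
            break
        applied = False
        order = rng.permutation(len(sites))
        for si in order:
            site = sites[int(si)]
            template = pool.by_id(site.template_id)
            partner_mols = []
            ok = True
            for role in range(template.n_reactant_roles):
                if role == site.role_index:
                    continue
                cands = [p for p in partners if matches_role(p, template, role)]
                if not cands:
                    ok = False
                    break
                partner_mols.append(cands[int(rng.integers(len(cands)))])
            if not ok:
                continue
            reactants = list(partner_mols)
            reactants.insert(site.role_index, current)
            outcomes = apply_reaction(template, reactants, site=site)
            if not outcomes:
                continue
            outcome = outcomes[int(rng.integers(len(outcomes)))]
            route.append(
                {
                    "template_id": template.id,
                    "reactant_smiles": [m.smiles for m in reactants],
                    "product_smiles": outcome.product.smiles,
                    "parent_role": site.role_index,
                }
            )
            current = outcome.product
            applied = True
            break
        if not applied:
            break
    return current, route


def generate_toy_pool(
    spec: FixtureSpec, pool: Optional[ReactionPool] = None
) -> Tuple[List[Molecule], List[float]]:
    """Generate a deterministic pool of unique drug-like molecules and
    matching property values following the declared property rule."""
    if pool is None:
        pool = toy_reaction_pool()
    rng = np.random.default_rng(spec.seed)
    motifs = [canonicalize(s) for s in spec.motif_library]
    partners = (
        motifs
        if spec.partner_library is None
        else [canonicalize(s) for s in spec.partner_library]
    )
    lo, hi = spec.heavy_atom_range
    mols: List[Molecule] = []
    seen = set()
    attempts = 0
    max_attempts = spec.n_molecules * 200
    while len(mols) < spec.n_molecules and attempts < max_attempts:
        attempts += 1
        core = motifs[int(rng.integers(len(motifs)))]
        n_steps = int(rng.integers(spec.max_decorations + 1))
        product, _ = _decorate(core, pool, partners, rng, n_steps)
        if not (lo <= product.heavy_atom_count <= hi):
            continue
        if product.smiles in seen:
            continue
        seen.add(product.smiles)
        mols.append(product)
    if not mols:
        raise RuntimeError("motif library produced zero valid molecules")
    if len(mols) < spec.n_molecules:
        logger.warning(
            "fixture generator produced %d/%d unique molecules", len(mols), spec.n_molecules
        )
    values = [
        spec.intercept
        + spec.slope * m.fingerprint().popcount
        + (rng.normal(0.0, spec.noise_sigma) if spec.noise_sigma > 0 else 0.0)
        for m in mols
    ]
    return mols, values


def generate_reachable_target(
    init_pool: Sequence[Molecule],
    reaction_pool: ReactionPool,
    building_blocks: Sequence[Molecule],
    n_steps: int = 1,
    seed: int = 0,
) -> Tuple[Molecule, List[dict]]:
    """Forward-generate a target guaranteed reachable from the pool.

    Applies ``n_steps`` random reactions starting from a pool member,
    with partners drawn from the building blocks, and returns the final
    product plus the ground-truth route (list of step dicts). For
    ``n_steps >= 1`` the target is additionally required to be absent
    from the initial pool, so the control is never degenerate (a target
    already in the pool is "rediscovered" at step 0 regardless of the
    chemistry). If no applicable chain of the requested length exists,
    the longest achievable route is returned with a warning. Enables
    positive-control rediscovery tests: the target is rediscoverable by
    construction.
    """
    rng = np.random.default_rng(seed)
    pool_smiles = {m.smiles for m in init_pool}
    best_product, best_route = None, []
    for _ in range(3):  # several passes over the pool in random order
        order = rng.permutation(len(init_pool))
        for idx in order:
            start = init_pool[int(idx)]
            product, route = _decorate(
                start, reaction_pool, building_blocks, rng, n_steps
            )
            if len(route) == n_steps and (
                n_steps == 0 or product.smiles not in pool_smiles
            ):
                return product, route
            if len(route) > len(best_route) and product.smiles not in pool_smiles:
                best_product, best_route = product, route
    logger.warning(
        "no reaction chain of length %d found; best achievable is %d step(s)",
        n_steps,
        len(best_route),
    )
    if best_product is None:
        best_product = init_pool[int(order[0])]
    return best_product, best_route


# ---------------------------------------------------------------------------
# run artifacts
# ---------------------------------------------------------------------------

def write_provenance_jsonl(path, result: RunResult) -> None:
    """One JSON record per archived individual."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for ind_id in sorted(result.archive):
            ind = result.archive[ind_id]
            rec = {
                "id": ind.id,
                "smiles": ind.smiles,
                "fitness": ind.fitness,
                "generation_born": ind.generation_born,
                "provenance": asdict(ind.provenance),
            }
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_provenance_jsonl(path) -> Dict[int, Individual]:
    """Rebuild a run archive from JSON-lines; raises on missing parents."""
    archive: Dict[int, Individual] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            prov = rec["provenance"]
            archive[rec["id"]] = Individual(
                id=rec["id"],
                molecule=canonicalize(rec["smiles"]),
                provenance=ProvenanceRecord(
                    operation=prov["operation"],
                    template_id=prov.get("template_id"),
                    parent_ids=tuple(prov.get("parent_ids", ())),
                    partner_smiles=tuple(prov.get("partner_smiles", ())),
                    byproduct_smiles=tuple(prov.get("byproduct_smiles", ())),
                    parent_role=prov.get("parent_role", 0),
                ),
                generation_born=rec["generation_born"],
                fitness=rec["fitness"],
            )
    for ind in archive.values():
        for pid in ind.provenance.parent_ids:
            if pid not in archive:
                raise KeyError(f"corrupt archive: missing parent record {pid}")
    return archive


def write_trajectory_csv(path, result: RunResult) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["generation", "best_fitness", "mean_fitness", "population_size"])
        for g in result.trajectory.generations:
            writer.writerow(
                [g.generation, f"{g.best_fitness:.6g}", f"{g.mean_fitness:.6g}",
                 len(g.population_smiles)]
            )


def write_operator_usage_tsv(path, result: RunResult) -> None:
    usage = result.trajectory.operator_usage_total()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("operator\tcount\n")
        for name in sorted(usage):
            fh.write(f"{name}\t{usage[name]}\n")


def write_route_json(path, trace: RouteTrace) -> None:
    Path(path).write_text(trace.to_json() + "\n", encoding="utf-8")


def load_config(path) -> GAConfig:
    """Load a GA config from YAML; unknown keys are fatal (typo guard)."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return GAConfig.from_dict(data)


def save_config(path, config: GAConfig) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
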