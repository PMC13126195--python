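"""Evaluation protocols: goal-directed rediscovery, reaction-pool
ablation, novelty analysis and the feasibility comparison harness.

The rediscovery benchmark purges the starting pool of near-identical
structures (Tanimoto to the target strictly greater than a threshold,
0.323 by convention), then runs many independent GA trajectories and
records the generation at which the target is first regenerated exactly
(Tanimoto 1 on ECFP4). "Step" means generation index, with the initial
pool counting as step 0; trajectories that never find the target within
the step budget are censored and reported, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from itertools import product as iter_product

from .chemcore import Molecule, NoveltyResult, novelty, tanimoto
from .fitness import Objective
from .ga import GAConfig, GenerationRecord, evolve
from .reactions import ReactionPool, apply_reaction, matches_role, subset_pool

logger = logging.getLogger(__name__)

__all__ = [
    "RediscoveryResult",
    "AblationCurve",
    "filter_init_pool",
    "run_rediscovery",
    "run_ablation",
    "novelty_report",
    "required_one_step_templates",
    "GUACAMOL_TARGETS",
]

#: Canonical SMILES of the three drug rediscovery targets used in
#: goal-directed benchmarking (GuacaMol convention), for convenience.
GUACAMOL_TARGETS: Dict[str, str] = {
    "celecoxib": "Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1",
    "troglitazone": "Cc1c(C)c2c(c(C)c1O)CCC(C)(COc1ccc(CC3SC(=O)NC3=O)cc1)O2",
    "thiothixene": "CN1CCN(CC/C=C2\\c3ccccc3Sc3ccc(S(=O)(=O)N(C)C)cc32)CC1",
}


def filter_init_pool(
    pool: Sequence[Molecule], target: Molecule, threshold: float
) -> List[Molecule]:
    """Remove pool molecules with Tanimoto to the target strictly greater
    than ``threshold`` (boundary values survive). Fatal if nothing
    survives — the threshold is then too tight for this pool."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0,1]")
    tfp = target.fingerprint()
    kept = [m for m in pool if tanimoto(m.fingerprint(), tfp) <= threshold]
    removed = len(pool) - len(kept)
    logger.info(
        "init-pool filter: removed %d/%d molecules above similarity %g",
        removed, len(pool), threshold,
    )
    if not kept:
        raise ValueError(
            f"no molecules survive the similarity filter at {threshold}; "
            "raise the threshold or supply a more diverse pool"
        )
    return kept


@dataclass
class RediscoveryResult:
    """Aggregate of many rediscovery trajectories for one target.

    ``steps_to_discovery`` holds the first-success generation per
    successful trajectory; ``n_censored`` counts trajectories that hit
    ``max_steps`` without success. ``mean_steps`` averages successful
    trajectories only.
    """

    target_smiles: str
    n_trajectories: int
    max_steps: int
    steps_to_discovery: List[int]
    n_censored: int
    max_similarity_curves: List[List[float]] = field(default_factory=list)

    @property
    def success_rate(self) -> float:
        return len(self.steps_to_discovery) / self.n_trajectories

    @property
    def mean_steps(self) -> Optional[float]:
        if not self.steps_to_discovery:
            return None
        return float(np.mean(self.steps_to_discovery))


def run_rediscovery(
    target: Molecule,
    init_pool: Sequence[Molecule],
    config: GAConfig,
    pool: Optional[ReactionPool],
    n_trajectories: int,
    base_seed: int = 0,
    building_blocks: Sequence[Molecule] = (),
) -> RediscoveryResult:
    """Run ``n_trajectories`` independent GA runs against one target.

    Trajectory ``i`` uses seed ``base_seed + i``; success is the first
    generation whose population contains a molecule with rediscovery
    score exactly 1 (identical ECFP4 fingerprint). The per-trajectory
    curve of maximum similarity per generation is kept for plotting.
    """
    if n_trajectories < 1:
        raise ValueError("n_trajectories must be >= 1")
    objective = Objective(mode="maximize_similarity", target=target)
    steps: List[int] = []
    censored = 0
    curves: List[List[float]] = []
    for i in range(n_trajectories):
        cfg = GAConfig(**{**config.to_dict(), "seed": base_seed + i})
        found = {"step": None}

        def stop(rec: GenerationRecord) -> bool:
            if rec.best_fitness >= 1.0 and found["step"] is None:
                found["step"] = rec.generation
                return True
            return False

        result = evolve(
            cfg,
            list(init_pool),
            objective,
            pool=pool,
            building_blocks=list(building_blocks),
            early_stop=stop,
        )
        curves.append(result.trajectory.best_per_generation)
        if found["step"] is not None:
            steps.append(found["step"])
        else:
            censored += 1
    return RediscoveryResult(
        target_smiles=target.smiles,
        n_trajectories=n_trajectories,
        max_steps=config.n_generations,
        steps_to_discovery=steps,
        n_censored=censored,
        max_similarity_curves=curves,
    )


@dataclass
class AblationCurve:
    """Rediscovery performance as a function of reaction-pool size."""

    points: List[dict] = field(default_factory=list)

    def fractions(self) -> List[float]:
        return [p["pool_fraction"] for p in self.points]


def run_ablation(
    target: Molecule,
    init_pool: Sequence[Molecule],
    config: GAConfig,
    pool: ReactionPool,
    fractions: Sequence[float],
    n_replicates: int = 1,
    n_trajectories: int = 5,
    base_seed: int = 0,
    building_blocks: Sequence[Molecule] = (),
) -> AblationCurve:
    """Quantify sensitivity to reaction-pool size.

    For each pool fraction, ``n_replicates`` random template subsets are
    drawn (disjoint seeds across the whole grid) and the rediscovery
    benchmark is run on each; fraction 1.0 uses the full pool verbatim.
    """
    fr = list(fractions)
    if fr != sorted(fr) or len(set(fr)) != len(fr):
        raise ValueError("fractions must be strictly increasing")
    curve = AblationCurve()
    seed_counter = base_seed
    for fraction in fr:
        rates, mean_steps_list, subset_seeds = [], [], []
        for _ in range(n_replicates):
            subset_seed = seed_counter
            run_seed = seed_counter + 1_000_000
            seed_counter += 1
            sub = (
                pool
                if fraction >= 1.0
                else subset_pool(pool, fraction, seed=subset_seed)
            )
            res = run_rediscovery(
                target, init_pool, config, sub,
                n_trajectories=n_trajectories,
                base_seed=run_seed,
                building_blocks=building_blocks,
            )
            rates.append(res.success_rate)
            if res.mean_steps is not None:
                mean_steps_list.append(res.mean_steps)
            subset_seeds.append(subset_seed)
        curve.points.append(
            {
                "pool_fraction": fraction,
                "success_rate": float(np.mean(rates)),
                "mean_steps": float(np.mean(mean_steps_list)) if mean_steps_list else None,
                "n_replicates": n_replicates,
                "subset_seeds": subset_seeds,
            }
        )
    return curve


def required_one_step_templates(
    target: Molecule,
    members: Sequence[Molecule],
    pool: ReactionPool,
    partners: Sequence[Molecule],
) -> set:
    """Template ids that can produce ``target`` in one step.

    Brute-force enumeration: every template applied to every member (in
    every reactant role) with every combination of role-matching
    partners, checking whether the target appears among the main
    products. Removing this whole set from the pool makes the target
    unreachable in a single reaction from the given molecules — the
    clean directional ablation.
    """
    required = set()
    for template in pool:
        n_roles = template.n_reactant_roles
        role_partners = [
            [p for p in partners if matches_role(p, template, role)]
            for role in range(n_roles)
        ]
        for parent_role in range(n_roles):
            candidates = [m for m in members if matches_role(m, template, parent_role)]
            if not candidates:
                continue
            other_roles = [r for r in range(n_roles) if r != parent_role]
            if any(not role_partners[r] for r in other_roles):
                continue
            found = False
            for member in candidates:
                for combo in iter_product(*(role_partners[r] for r in other_roles)):
                    reactants = list(combo)
                    reactants.insert(parent_role, member)
                    outcomes = apply_reaction(
                        template, reactants, parent_role=parent_role
                    )
                    if any(o.product.smiles == target.smiles for o in outcomes):
                        required.add(template.id)
                        found = True
                        break
                if found:
                    break
            if found:
                break
    return required


def novelty_report(
    generated: Sequence[Molecule], reference: Sequence[Molecule]
) -> Tuple[List[NoveltyResult], float]:
    """Per-molecule novelty N(g; D) against the reference set, plus the
    mean over the generated set."""
    if not generated or not reference:
        raise ValueError("generated and reference sets must be non-empty")
    results = [novelty(g, reference) for g in generated]
    mean = float(np.mean([r.novelty for r in results]))
    return results, mean
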