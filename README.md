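# r2gbga

A reaction-regulated graph-based genetic algorithm (R²GB-GA) for
**synthetically feasible molecular editing**, with the conventional
graph-based GA (GB-GA) as a built-in baseline.

Most molecular generative models perturb molecular graphs freely: the
structures they propose are chemically valid but often hard or impossible
to make. This package constrains the GA's mutation operator to a pool of
reaction SMARTS templates — a molecule can only change by undergoing a
named chemical reaction at a matched reactive site, with named partner
reactants. Consequences:

* generated molecules tend toward synthetically accessible chemistry;
* every candidate carries full provenance, so its **synthesis route**
  (reactions + precursors) can be reconstructed and replayed;
* restricting the pool and adding a scaffold constraint yields
  site-selective editing around a fixed core (late-stage
  functionalization style design).

It is aimed at computational and medicinal chemists who want goal-directed
molecule optimization (rediscovery benchmarks, property targeting with a
surrogate, scaffold-constrained ligand design) where the output must come
with a plausible route, not just a score.

## The method in brief

Each generation: evaluate fitness, select parent pairs
rank-proportionally from the top half, apply cut-and-splice crossover
(probability `crossover_rate`), then mutate (probability
`mutation_rate`). In `reaction` mode the mutation draws a (template,
role, site) triple with probability proportional to template weight from
all reactive sites found in the molecule, fills the other reactant roles
from the building-block list, and applies the reaction SMARTS forward;
in `conventional` mode it performs one random atom/bond edit. Offspring
are deduplicated by canonical SMILES, optionally filtered by a scaffold
SMARTS, and the best `population_size` of parents ∪ offspring survive.

Fitness functionals:

* **rediscovery** — Tanimoto similarity T(φ(m), φ(target)) on ECFP4
  fingerprints φ (Morgan radius 2, 2048 bits);
* **property targeting** — a Gaussian-process surrogate with Tanimoto
  kernel k(x, x′) = σ_f²·T(x, x′) fit to a `smiles,value` table; score
  −|μ(m) − target| (optionally on log10 scale for IC50-like values);
* **feasibility reporting** — Ertl synthetic-accessibility score
  (1 easy – 10 hard) plus pluggable external scorers (SYBA, RAscore)
  via `register_scorer`.

The novelty of a generated molecule g against a reference set D is
N(g; D) = 1 − max_{d∈D} T(φ(g), φ(d)); N = 0 means g already exists in D.

## Worked example

Build a toy world (bundled 12-reaction pool, a deterministic 50-molecule
drug-like pool), forward-generate a target guaranteed to be one reaction
away from the pool, then let the reaction-driven GA rediscover it and
print its traced route:

```python
import r2gbga as r
from r2gbga.fixtures_io import DEFAULT_MOTIFS, FixtureSpec, generate_toy_pool

pool = r.toy_reaction_pool()
blocks = [r.canonicalize(s) for s in DEFAULT_MOTIFS]
init, _ = generate_toy_pool(FixtureSpec(n_molecules=50, seed=1), pool=pool)

target, route = r.generate_reachable_target(init, pool, blocks, n_steps=1, seed=3)
print("target:", target.smiles)

cfg = r.GAConfig(population_size=100, n_generations=5, crossover_rate=0.0,
                 mutation_rate=1.0, mutation_mode="reaction", seed=0)
objective = r.Objective(mode="maximize_similarity", target=target)
result = r.evolve(cfg, init, objective, pool=pool, building_blocks=blocks)
for g in result.trajectory.generations:
    print(f"gen {g.generation}: best similarity {g.best_fitness:.3f}")

best = max(result.population.members, key=lambda i: i.fitness)
trace = r.trace_route(best.id, result.archive, pool=pool)
print("best molecule:", best.smiles)
for s in trace.steps:
    print("  step:", s.template_id, "+".join(s.reactant_smiles), "->", s.product_smiles)
print("route replays:", trace.replay_ok)
```

Output:

```
target: Oc1ccccc1Br
gen 0: best similarity 0.526
gen 1: best similarity 1.000
gen 2: best similarity 1.000
gen 3: best similarity 1.000
gen 4: best similarity 1.000
gen 5: best similarity 1.000
best molecule: Oc1ccccc1Br
  step: aromatic_bromination Oc1ccccc1 -> Oc1ccccc1Br
route replays: True
```

The target (2-bromophenol) is absent from the initial pool; the best
starting molecule scores similarity 0.526. One generation of
reaction-driven mutation finds it exactly (similarity 1.000 means
identical fingerprints), and the traced route — brominate phenol — is
the ground-truth transformation and replays successfully through the
reaction engine.

## Command line

```bash
r2gbga run        --config cfg.yaml --init-pool pool.smi --reactions rxns.tsv \
                  --building-blocks bb.smi --target-smiles celecoxib --out rundir/ --seed 0
r2gbga rediscover --target celecoxib --init-pool chembl.smi --threshold 0.323 \
                  --n-trajectories 100 --out result.json
r2gbga ablate     --target celecoxib --init-pool chembl.smi --fractions 0.25,0.5,1.0 --out curve.json
r2gbga novelty    --generated gen.smi --reference init.smi --out novelty.tsv
r2gbga feasibility --molecules gen.smi --out feasibility.tsv
r2gbga make-fixtures --n-molecules 50 --seed 0 --out-smiles toy.smi --out-csv toy.csv
```

`run` writes per-generation SMILES files, a trajectory CSV, the full
provenance archive (JSON-lines), operator-usage counts and the traced
route of the best individual. Reaction pools are TSV
(`id name category weight reaction_smarts`); a curated 12-template
medicinal-chemistry pool ships with the package and is used when
`--reactions` is omitted. Property tables are `smiles,value` CSV.
Built-in rediscovery targets: `celecoxib`, `troglitazone`, `thiothixene`.

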