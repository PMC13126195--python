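# Methods

## The model

`r2gbga` implements a reaction-regulated graph-based genetic algorithm
(R²GB-GA) for goal-directed molecular design, together with the
conventional graph-based GA (GB-GA) it is compared against. Both engines
share the same evolutionary skeleton — fitness evaluation, rank-based
selection from the top half of the population, Jensen-style cut-and-splice
crossover on the molecular graph, mutation, deduplication by canonical
SMILES, elitist μ+λ truncation — and differ only in the mutation operator:

* **conventional mutation** draws one random graph edit (append atom,
  delete atom, change atom type, change bond order, form a ring bond,
  break a ring bond) and keeps the first edit that sanitizes. The result
  is chemically *valid* but not necessarily synthetically *feasible*.
* **reaction-driven mutation** enumerates every reactive site of the
  molecule under a pool of reaction SMARTS templates, draws one
  (template, role, site) with probability proportional to the template
  weight, fills the remaining reactant roles with role-matching partner
  molecules, and applies the template forward with RDKit's reaction
  engine. Every offspring therefore corresponds to a named chemical
  transformation with named precursors, and the full reaction history of
  any individual can be replayed as a synthesis route.

Fitness is either Tanimoto similarity of ECFP4 fingerprints to a fixed
target structure (rediscovery), or a Gaussian-process surrogate over
fingerprints targeting a scalar property value with score
`-|μ(m) − target|`. An optional scaffold constraint (substructure SMARTS)
rejects any offspring that loses a required core, which restricts the
search to site-selective peripheral edits — the late-stage-
functionalization setting.

## Key design choices

**Fingerprints.** ECFP4 = Morgan radius 2, 2048 binary bits, chirality
excluded; all three are configurable (`FingerprintParams`). The Tanimoto
similarity of two all-zero fingerprints is defined as 1 (identical empty
feature sets) — relevant only for degenerate sub-heavy-atom inputs, and
covered by tests.

**Canonical atom ordering.** A `Molecule` re-derives its RDKit graph from
its own canonical SMILES rather than retaining the graph it was built
from. This makes substructure-match atom indices a pure function of the
canonical SMILES, so `SiteMatch` records are stable across reaction
products, file round-trips and the memoized site cache.

**Main-product selection.** A forward reaction application can yield
several fragments. The main product is the fragment with the greatest
heavy-atom count that contains at least one reaction-center atom
originating from the mutated parent (identified through RDKit's
`old_mapno`/`react_atom_idx` bookkeeping). For templates without atom
maps the parent-containment check falls back to a maximum-common-
substructure comparison, which is approximate and documented as such;
the bundled pool is fully atom-mapped. Outcomes are deduplicated by the
main product's canonical SMILES; remaining fragments are recorded as
byproducts. Any outcome containing an unsanitizable fragment is dropped
and counted. When a specific site is requested, outcomes arising from
other substructure matches are filtered out *before* sanitization (they
are identified purely from atom bookkeeping), which dominates the cost
profile of long runs.

**Selection.** Rank-proportional sampling with replacement from the top
half of the population (the best of k eligible members has weight k, the
worst 1); fitness ties share their average rank, so a uniform-fitness
population is sampled uniformly. The eligible set is widened to two when
the population is tiny, so a distinct parent pair always exists. Survivor
selection is μ+λ: the best `population_size` of the previous members and
the new offspring together, with the elite fraction guaranteed; every
carried-over member is re-archived with an `elite_copy` provenance record
so ancestry chains never break.

**Partner policy.** The remaining reactant roles of a multi-component
template are filled by uniform sampling from the candidates that match
the role pattern, drawn from a user-supplied building-block list, the
current population, or both (`partner_source`). Building-block partners
keep traced routes constructible from named, purchasable precursors.

**Crossover.** Cut-and-splice: with probability `p_ring_crossover` (0.3)
a double cut through one ring of each parent exchanges ring arcs;
otherwise a single acyclic single-bond cut exchanges fragments. The first
sanitized, connected child inside the heavy-atom window wins; after
`crossover_max_tries` (10) failures the operator reports failure and the
caller falls back to mutating a parent.

**Defaults.** `crossover_rate` 1.0, `mutation_rate` 0.5, `elite_fraction`
0.1, heavy-atom window [5, 60], reaction-mutation retry budget 10,
10 generations. These are declared package defaults — the benchmarks in
this field rarely publish their operator rates — and every one is exposed
in the YAML config. Rediscovery scores molecules directly with the true
similarity objective; the GP surrogate is fit once on a training table
for property-targeting tasks. IC50-like targets spanning orders of
magnitude should set `log10_scale`, which models values (and the target)
on the log10 scale.

**Gaussian process.** Exact GP regression with the binary Tanimoto
(MinMax) kernel `k(x, x′) = σ_f² · T(x, x′)` — the natural PSD kernel on
binary fingerprints. The prior mean is the training mean. Fitting uses a
Cholesky factorization with jitter escalation (0 → 1e-4); failure at the
largest jitter raises with the condition number. With zero noise the
posterior interpolates the training values (verified to 1e-6 relative)
and the posterior variance at training points is bounded by the jitter.
σ_f² can be set by maximizing the log marginal likelihood with a bounded
one-dimensional search; a recovery test checks the estimate lands within
a factor of two of the generating value.

**Feasibility scoring.** The synthetic-accessibility score (Ertl
fragment-contribution method, 1 easy – 10 hard) is computed through the
fragment-score table shipped with RDKit's contrib tree; if that resource
is missing the scorer reports itself unavailable rather than failing a
run. SYBA and RAscore are exposed only as pluggable adapters
(`register_scorer`) because their trained models are external artifacts;
tests exercise the adapters with stub scorers.

**Route tracing.** `trace_route` walks the provenance archive from an
individual to its initial-pool leaves, collecting reaction steps in
topological order. Elite copies are pass-through; crossover and
conventional-mutation ancestors are recorded as *gaps* (the route is not
reaction-derived past a gap) and their subtrees are not expanded. Each
reaction step stores the full ordered reactant list (the parent's role is
recorded at mutation time), so replaying the steps through the reaction
engine must reproduce every intermediate and the final canonical SMILES;
the replay verdict is stored on the trace. Traced routes are generation
histories, not minimal syntheses — no retrosynthetic search is performed.

## The synthetic data generator

No external molecular database ships with the package. The fixture
generator (`fixtures_io`) assembles drug-like molecules by decorating a
~16-fragment motif library (a resorcinol core, anilines, aryl halides,
carboxylic and boronic acids, amines, an aldehyde, alcohols, a sulfonyl
chloride, a nitroarene, an alkyl halide) with 0–2 reactions from the
bundled 12-template pool (amide coupling, Suzuki–Miyaura,
Buchwald–Hartwig, N-/O-alkylation, reductive amination, ester
formation/hydrolysis, nitro reduction, sulfonamide formation, aromatic
bromination, Williamson ether). Every fixture molecule is therefore
reachable by the same chemistry the GA mutates with. Property values for
surrogate tests follow a declared rule — linear in fingerprint popcount
with optional Gaussian noise — which is smooth over fingerprint space and
exactly recoverable at σ = 0. Generation is deterministic under the seed,
byte-identical on disk.

`generate_reachable_target` applies n forward reaction steps to a pool
member (partners from the building blocks) and returns the product with
its ground-truth route. For n ≥ 1 the product must be absent from the
initial pool, otherwise the rediscovery control would trivially succeed
at step 0. For the directional ablation,
`benchmarks.required_one_step_templates` brute-forces *every* template
able to produce the target in one step from the pool and building blocks,
so removing that whole set provably severs all one-step routes.

What the toy conditions do **not** emulate: ChEMBL/QM8-scale pools
(thousands of molecules, 2000/500/400-member populations), a
several-hundred-template reaction pool, measured assay values, or the
resulting magnitudes of feasibility-score gaps between the two mutation
modes. Passing tests demonstrate the mechanics and the guaranteed
invariants of the method at desk scale; they do not reproduce
database-scale effect sizes, and the mean SAScore difference between the
two modes on toy runs is small and seed-dependent. The full-scale
protocols run unchanged when users supply their own SMILES pools,
property tables and reaction TSVs — that pathway is exercised end to end
by the harness tests.

## Benchmark conventions

* Rediscovery purges the starting pool of molecules with Tanimoto
  similarity to the target *strictly greater than* the threshold
  (0.323 by convention); boundary values survive.
* A "step" is the generation index at first exact rediscovery
  (fingerprint Tanimoto 1.0), counting the initial pool as step 0.
  Trajectories that exhaust the generation budget are censored: counted
  and reported, never averaged into the mean step count.
* Trajectory i of a benchmark uses seed `base_seed + i`; ablation
  replicates draw disjoint subset seeds across the whole fraction grid.
* The positive-control configuration is reaction-only (crossover off,
  mutation rate 1) with a population of 200 — large enough that the
  required (parent, site, partner) draw is overwhelmingly likely within
  the 5-generation budget.

## Problem sizes and numerics

Shipped checks run at: 50-molecule pools for GA runs (population 50–200,
5–10 generations), 200-molecule corpora for oracle comparisons, GP checks
at n ≤ 100 with 1000-query variance scans, 20 rediscovery trajectories
for the positive control and 10 for the ablation. Ties are always broken
deterministically (fitness descending, then canonical SMILES ascending;
template removal by id order), and all randomness flows through a single
seeded NumPy generator per run, so complete runs are byte-identical under
a fixed seed.

## Known limitations

* Reaction templates are applied one step per mutation; no cascades,
  protecting groups, conditions or yields.
* Site filtering requires atom-mapped templates; unmapped templates fall
  back to an approximate MCS containment check.
* The conventional-mutation operator set is a compact re-implementation
  of the usual graph-GA edits, not a byte-level port of any particular
  codebase.
* Docking, 3-D geometry, t-SNE embedding internals and retrosynthetic
  planning are out of scope.
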