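# Methods

## The model

The object of analysis is a weighted bipartite interaction matrix
`A = (a_ij)` linking resource species (trees, rows) to colonizer OTUs
(columns). It is estimated from a samples × OTUs count table in two
steps: per-sample relative abundances (counts divided by the sample
total), then the median across a tree's replicates. The median makes a
tree's row robust to a single aberrant replicate; with three replicates
it is the middle order statistic, and the construction is equivariant in
replicate order.

Because sequencing effort differs between samples, counts are first
rarefied to a common depth by sampling reads without replacement
(multivariate hypergeometric). A single rarefied table is one arbitrary
draw, so every downstream quantity is computed independently on an
ensemble of `n_versions` rarefied tables with seeds
`base_seed + version`, and reported as ensemble summaries (mean,
variance, sd, min, median, max). Any single version can be regenerated
in isolation from its seed.

### Indices

All entropies are in nats. With `m = Σ a_ij`, `p_ij = a_ij/m`, row
totals `A_i` and availabilities `r_i = A_i/m`, `c_j = A_j/m`:

* `H = −Σ p_ij ln p_ij`, interaction evenness `H / ln(n_rows·n_cols)`
  (mode `prod`, the default) or `H / ln L` over realized links (`sum`).
* Generality of a side = `Σ_i r_i · exp(H_i)`, the abundance-weighted
  mean effective partner number. The exponent-of-weighted-mean-entropy
  variant `exp(Σ_i r_i H_i)` is available behind a flag; the two
  readings coincide on uniform rows, and the mean-of-effective-numbers
  form is used because it is the operationally explicit one.
* `H2' = (H2max − H) / (H2max − H2min)`, clamped to [0, 1] with
  tolerance 1e-9, and defined as 0 when the bounds collapse. `H2max` is
  the entropy of the outer product of the marginals (independence).
  `H2min` comes from greedy packing: repeatedly place
  `min(remaining row, remaining column)` mass on the cell pairing the
  largest remaining row with the largest remaining column. The
  continuous (real-valued) formulation is canonical here because the
  network weights are medians of proportions, not integer counts; an
  integer-constrained variant would need the original count scale,
  which the median construction deliberately discards.
* `d_i = Σ_j (a_ij/A_i) ln[(a_ij/A_i)/c_j]`, normalized by
  `d_max = ln(m/A_i)`; `d' = 0` when `d_max = 0` (one species holding
  all mass has no room to specialize). The lower reference point is
  fixed at 0 (continuous formulation).
* Barber bipartite modularity
  `Q = (1/m) Σ_ij [a_ij − A_i A_j/m] · 1(g_i = g_j)`.

All indices are invariant under global rescaling of the weights and
under simultaneous row/column permutation; tests assert both.

### Module search

`optimize_modules` is multi-start greedy search, deterministic per
seed: each start (two deterministic seeds — singletons and
columns-join-best-row — plus random label assignments) is refined by
single-node relocation sweeps in random order followed by pairwise
module merges until Q stops improving; an iterated-local-search phase
then repeatedly perturbs the incumbent (random relabeling of up to a
third of the nodes) and re-refines. Relocation gains are exact: moving a
row into a module changes Q by the sum of modularity-matrix entries to
that module's columns, so sweeps are vectorized with bincounts. The
all-in-one partition (Q = 0) is always a candidate, so the returned Q is
never negative. Module count is emergent, not fixed. Labels are
canonicalized (descending module weight, ties by lexicographically
smallest member) so partitions can be compared across ensemble versions.
`exhaustive_modules` enumerates all set partitions of up to 10 combined
nodes (restricted-growth strings, vectorized Q over all partitions) and
serves as the optimizer's ground-truth oracle in the tests; on a
randomized suite of 200 small matrices the optimizer matches it to
1e-9.

### Null models

* **Patefield** (fixed marginals): sequential multivariate-
  hypergeometric row filling, the classical fixed-margin contingency
  table sampler. It requires integer weights; quantitative networks are
  discretized first by `to_integer_matrix` (largest-remainder rounding
  to a fixed quantum total, default 10,000 — cells below half a quantum
  may round to zero, which is acceptable because this null does not
  preserve links). Note the sampler draws from the fixed-margin
  hypergeometric (Fisher) distribution over tables; on instances whose
  feasible tables are all 0/1-valued that distribution is provably
  uniform, which is what the uniformity tests exercise.
* **Vazquez** (fixed connectance and total, abundance-informed): L
  distinct cells are chosen sequentially with probability ∝ r_i·c_j,
  rejecting choices that would leave a row or column uncoverable; the
  total m is then distributed as N quanta (N = m for integer matrices,
  10,000 otherwise): one per chosen cell plus a multinomial on the
  rest.
* **Shuffle** (fixed weight multiset and connectance): the nonzero
  weights are permuted onto a uniformly random cell subset. Marginals
  are generally destroyed, and any index that depends only on the value
  multiset — Shannon diversity, evenness on the full-grid denominator —
  is unchanged by construction. This is why observed-vs-shuffle tests of
  diversity indices are reported as degenerate rather than significant.

### Paired testing and the table-level null

Observed-vs-null comparisons are paired by rarefied version (one null
per version) and tested with classical two-sided paired t tests; raw
P values are reported, with an optional Holm helper. Zero-variance
differences raise an explicit degenerate-test error.

For the ensemble pipeline the Patefield null is, by default, applied to
the rarefied count table itself (per-sample depths and per-OTU totals
are genuinely integer there) and propagated through the identical
median-of-replicates construction. This choice matters: randomizing the
derived network instead requires discretizing medians of proportions to
an arbitrary quantum total, and the null's sampling-noise floor then
depends on that constant — pilot runs on structure-free communities
showed the observed−null H2' gap flipping sign with the quantum total
(−0.034 at 10k quanta, +0.023 at 39k). Randomizing at the level where
the data are integer makes the paired comparison exact: on
structure-free communities the paired t statistic is calibrated
(mean ≈ 0, sd ≈ 1 across generator reruns). `PipelineSettings
(null_level="matrix")` restores the network-level route for comparison
with the standalone null-model functions.

## The synthetic generator

The generator emulates the assumed study design: `n_trees` resource
species (default 13, named after the deciduous/conifer panel the
pipeline is aimed at) × `n_replicates` (default 3) × optional
compartments; OTU base abundances are lognormal (mu 0, sigma 1,
the usual skewed amplicon abundance shape). Trees are split into K
near-equal planted modules, each OTU is assigned one, and the
specialization dial `s` gives an OTU a fraction `s` of its expected
mass on its own module's trees, the rest spread uniformly over the
other trees. `s="equalizing"` uses, per OTU, `s = |module|/n_trees`,
which makes the expected composition exactly uniform — the generator's
no-structure reference point (a single global equalizing value does not
exist when module sizes are unequal, e.g. 13 trees in modules of
4/3/3/3). Per sample, the expected composition is perturbed by
unit-mean lognormal noise (`replicate_noise_cv`), renormalized, and
`depth` reads are drawn multinomially.

Defaults and why:

* `depth = 20,000` reads per sample — the sequencing scale of typical
  MiSeq amplicon studies of this design; the pipeline's default
  rarefaction depth is 1/20 of the minimum sample total, i.e. the
  deep-sequencing / deliberately-shallow-rarefaction regime. Shallow
  rarefaction relative to sequencing depth also keeps ensemble versions
  close to independent draws; rarefying near the full depth would make
  all versions inherit the parent table's realized sampling noise,
  which paired version-wise tests would then read as signal
  (pseudo-replication).
* `replicate_noise_cv = 0.03` — technical sampling noise only,
  calibrated so that the no-structure reference condition is
  statistically indistinguishable from its fixed-margin null under the
  paired test. This is a deliberate separation of channels: planted
  structure lives in `s`, and multiplicative replicate noise beyond the
  multinomial is itself compositional overdispersion that a
  fixed-margin null correctly flags as structure (pilot runs: the
  observed−null H2' gap grows as cv², reaching +0.008 at cv 0.3).
  Real field replicates — logs on different plots — vary far more than
  this; with realistic ecological replicate heterogeneity the paired
  test will, correctly, report the community as non-random even without
  planted modules. Passing recovery tests therefore validate the
  machinery, not the claim that field data are noise-free.
* `fungus_like()` / `prokaryote_like()` presets echo the qualitative
  contrast the pipeline is designed to expose: fewer OTUs at high `s`
  versus many OTUs at low `s` (strong versus weak specialization under
  matched construction).

What the generator does **not** emulate: taxonomy, phylogenetic
correlation between trees or OTUs, co-occurrence dependence between
OTUs, chimeras/index-hopping, or compartment-correlated abundances —
recovery results say nothing about robustness to those.

## Numerical and degenerate-input choices

* Rarefaction requires every sample total ≥ depth and errors with the
  offending sample ids; rarefied columns are kept even if all-zero so
  ensemble versions stay aligned. All-zero OTU columns are dropped at
  table-split time and at network construction; all-zero tree rows are
  dropped with a warning.
* ACE uses the classical rare-abundance cutoff of 10 and raises an
  explicit estimator-undefined error when all rare species are
  singletons or the rare group holds ≤ 1 individual. A community with
  no rare species reduces to the observed richness.
* The coverage diagnostic (observed richness after one rarefaction ÷
  pooled ACE estimate) is reported, never enforced; depth is the
  user's choice.
* `to_integer_matrix` errors when the quantum total is below the link
  count; largest-remainder ties are broken in stable (row-major) cell
  order.
* Ensemble summaries use the sample variance (ddof = 1); a single
  record reports sd 0 by convention, logged.
* Consensus identity across versions is the tree-side grouping (trees
  are few and stable; OTU membership churns under rarefaction), matched
  by exact member-tree sets; the modal grouping wins, ties broken by
  higher mean Q then lexicographically. An OTU whose version-modules
  never match a consensus module is reported as `unassigned`.
* `relAbundanceModuleSamplesVsOthers` is `inf` when an OTU is absent
  outside its module's samples (logged), mirroring a perfectly
  module-exclusive colonizer.

## Problem sizes in tests

The test suite and the recovery experiments run at desk scale chosen by
the package: ensembles of 10–50 rarefied versions (the ensemble
machinery is size-agnostic; 1,000-version runs are a loop parameter),
300-OTU communities for recovery, 200-matrix oracle suites for the
optimizer, and 10,000-draw uniformity checks for the fixed-margin
sampler. The acceptance script evaluates closed-form boundary cases
only, so its output is exact and seed-independent.

## Known limitations

* H2' uses the continuous bounds; values are not numerically
  comparable to integer-constrained implementations on coarse count
  matrices (they converge as counts grow).
* The Vazquez weight placement uses a finite quantum approximation for
  non-integer matrices (N = 10,000), so its weight distribution — not
  its support, total, or link count — carries a small discretization.
* The module optimizer is a heuristic; oracle equivalence is
  established on ≤ 10-node matrices and planted-structure recovery on
  synthetic ensembles, not global optimality in general.
* Consensus matching by exact member-tree sets is strict: under very
  unstable ensembles most OTUs end up `unassigned` rather than fuzzily
  matched.
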