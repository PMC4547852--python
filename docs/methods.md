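# Methods

## Problem and model

Somatic driver alterations in tumors — recurrent point mutations,
copy-number gains and losses, and promoter hypermethylation events — do not
accumulate independently. A pair may **co-occur** (appear together more
often than expected) or be **mutually exclusive** (appear together less
often than expected), which is read as evidence of cooperative or partially
redundant epistasis. The statistical difficulty is that tumors differ
enormously in how many alterations they carry, alterations differ in
recurrence, and both distributions differ between cancer types. Any test
that ignores this heterogeneity produces spurious co-occurrence between any
two frequent events.

`epint` addresses this with a **fixed-margin permutation null**. The cohort
is a binary incidence matrix (samples x alterations). Within each
(cancer type x alteration class) block, randomized matrices are drawn that
preserve *exactly* every sample's event count and every alteration's
recurrence in that block; what is random is only which samples carry which
events. Classes (mutation, CNA gain, CNA loss, methylation) are permuted
separately because their event counts per sample come from different
calling processes, and cancer types are permuted separately because
frequencies differ between them.

### Sampler

Randomization uses the checkerboard-swap Markov chain: pick two rows and
two columns uniformly; if the 2x2 submatrix is `[[1,0],[0,1]]` or its
complement, exchange it. The move is self-inverse, the chain with lazy
self-loops is aperiodic and doubly stochastic on the margin class, so its
stationary distribution is uniform over all matrices with the given
margins. Defaults: burn-in of `10 x nnz` attempted swaps per block and one
matrix emitted every `nnz` attempted swaps (`nnz` = block event count).
Attempted rather than successful swaps are counted so cost is predictable
on sparse blocks. A `restart` mode re-runs an independent burn-in from the
observed block for every permutation; it costs ~10x more per matrix but
yields independent draws, and is what the distribution-level tests
(uniformity goodness-of-fit, enumeration comparisons) use, since chained
samples are autocorrelated. Randomness is driven by per-block counter-based
substreams of one master seed, so permutation *k* depends only on
(seed, *k*) and results are reproducible regardless of batching.

### Interaction test

For pair (A, B) the statistic is the co-occurrence count CO (samples
altered in both). With N permutations,

    P_co = #{CO_perm >= CO_obs} / N,    P_me = #{CO_perm <= CO_obs} / N,

ties counting toward both sides and both values floored at 1/N (an
empirical P cannot resolve below 1/N, and BH must never receive 0). The
per-scope family of `p_min = min(P_co, P_me)` values is BH-adjusted; a
capped two-sided value `min(1, 2 p_min)` is reported alongside for users
who want a two-sided-correct column. Direction is the side attaining
`p_min`, with the continuity-corrected odds ratio (vs 1) breaking exact
ties. The pan-cancer statistic is the *sum over cancer types* of
within-type co-occurrence, evaluated against the same stratified null, so
that a pair frequent in one large cohort cannot masquerade as a pan-cancer
interaction. One permutation stream is shared by all pairs of a scope —
the whole matrix is permuted once per iteration — keeping pair statistics
comparable within a permutation.

Pairs where **both** members are copy-number alterations on the same
chromosome are never tested (linkage, not epistasis, explains their
co-occurrence); no other location-based exclusion is applied.

### Cohort filtering

Two rules precede testing. Hyper-altered samples — total event count
strictly above `Q3 + 4.5 x IQR` of per-sample counts (linear-interpolation
quartiles, recorded in the filter report) — are excluded once, before
anything else, with thresholds not recomputed after exclusion. The scope of
this rule is `global` by default with a `per_cancer_type` option, since
either reading of a single pooled rule is defensible. Recurrence filtering
then keeps alterations present in at least `ceil(0.02 x n)` of the samples
under consideration; the ceiling guarantees a fractional threshold never
admits sub-threshold alterations. Recurrence is always recomputed inside a
scope (a cancer type, a pan-cancer cohort, or a saturation subsample).

### Differential interactions

A pair detected in one cancer type is re-tested against every other type
in which both members are individually recurrent (>= 2%). Each comparison
forms two 2x2 strata and computes the Breslow-Day heterogeneity chi-square
with Tarone's correction against the Mantel-Haenszel common odds ratio
(fitted cell from the positive root of the margin quadratic; variance =
inverse sum of reciprocal fitted cells). Because the chi-square reference
is unreliable under load heterogeneity, significance comes from the same
stratified permutation null: p = #{T_random > T_obs}/N (strict inequality,
floored at 1/N), BH-adjusted across **all** comparisons of a screen. The
reported effect is the change in natural-log odds ratio, from
continuity-corrected (+0.5 per cell) ORs. For the statistic itself, +0.5
is added to every cell of a comparison only when some cell is zero
(`auto`); `always` and `never` modes exist because either convention is
found in practice. The statistic was verified to 1e-6 against an
independently coded root-finding implementation and against
`statsmodels.stats.StratifiedTable.test_equal_odds(adjust=True)`.

### PPI enrichment

Two alterations count as PPI-linked when at least one gene of one has an
edge to a gene of the other (existential, using each alteration's member
genes; CNA regions contribute all their genes). Enrichment compares
N_obs, the number of linked pairs among detections, to random draws of
equally many distinct pairs from the testable recurrent-pair pool
(default 1,000 resamples): `fold = N_obs / mean(N_random)` and
`P = (#{N_random >= N_obs} + 1)/(n + 1)`. The +1/(n+1) estimator is used
here (unlike the main test) because the resample null is cheap and the
statistic coarse. Degenerate folds: 0/0 is reported as 1; positive/0 as
infinity.

### Saturation

Three down-sampling curves: within one type (step 10 samples), pan-cancer
proportionally across types (step 100, capped), and adding whole cancer
types in random orders. Within a replicate, subsets are nested (each size
extends the previous draw), which reduces variance; a non-nested mode
exists. Every curve ends at the full cohort in original sample order, so
with a shared seed the final point reproduces the full analysis
bit-for-bit. Subsample permutation count defaults to 1,000 (recorded in
output) to keep curves tractable; the full-analysis default is 10,000.

### Gene ranking within CNA regions

For each gene of a region, samples of a cancer type are split by region
status and log2 expression compared by a two-sided Mann-Whitney test
(exact enumeration when both groups <= 8 and untied, otherwise the normal
approximation with tie correction); genes are ranked by BH q within the
region. Two-sided is used because gains and losses shift expression in
opposite directions; BH scope is per region, with a global option.

## Synthetic cohorts and what they do (not) show

The generator plants pairwise interactions with *exact* odds ratios: the
both-altered cell probability solves
`(theta-1) p11^2 - [1 + (pA+pB)(theta-1)] p11 + theta pA pB = 0` on the
feasible branch, so manifest ORs equal the requested theta analytically.
Per-sample load heterogeneity is induced afterwards by logit-scale sample
effects applied to **non-planted** alterations only, keeping planted ORs
exact; a configurable fraction of samples receive a +6 logit boost,
emulating hypermutator outliers for the exclusion rule to catch.

Consequences worth knowing:

* On cohorts with **no** planted pairs the generative model is the Rasch
  (logit-additive) family, whose distribution conditional on margins is
  exactly uniform — the permutation null's assumption holds exactly, and
  measured detection on such a cohort is a true false-positive count
  (0 of 435 pairs at FDR 0.1 in the shipped null run).
* On cohorts **with** planted pairs, the load-immune planted columns break
  that structure: the null redistributes events into them, so unplanted
  load-coupled pairs can appear (mutually) co-occurring relative to the
  null. Recovery experiments therefore assert planted-pair behavior only;
  calibration is asserted on fully null cohorts. Real cohorts, where every
  event shares patient-level effects, do not have this artifact.
* Calibration of the empirical P-values is *conservative*, not exact:
  co-occurrence counts are discrete, and tie-inclusive one-sided P-values
  are super-uniform, the more so the rarer the events (at frequencies
  0.05-0.35 and n=200 the measured rejection rate at alpha 0.05 is
  ~0.02-0.03). Tests never over-reject; they under-reject.
* The generator does not emulate mutational signatures, subclonal
  structure, segment-level CNA correlation, or the empirical TCGA
  frequency spectrum; passing recovery tests shows the statistics behave
  as designed under controlled heterogeneity, not that real-data discovery
  rates will match.

Scenario scales: `smoke` (2 types x 100 samples), `standard` (4 x 300,
six planted pairs, 2% hyper-altered), `stress` (10 x 500), `null`
(no planted pairs), plus two benchmark scenarios: `power_spec` (planted
theta 8 / 0.1 at frequency 0.1, 4 x 300) and `differential_spec`
(theta 8-vs-1 and 8-vs-8 pairs at frequency 0.15, 2 x 400; at n=400 the
heterogeneity test needs ~27 expected both-altered samples per stratum to
resolve a ln 8 change reliably, which sets that frequency). Baseline
frequencies span 0.05-0.35, the range typical of driver events surviving a
2% recurrence filter; logit dispersion 0.5 gives clearly over-dispersed
loads without swamping planted signal.

## Numerical choices and degenerate inputs

* Quartiles: linear interpolation (NumPy default), recorded in the filter
  report; scopes with fewer than 4 samples skip hyper-filtering with a
  warning.
* Empirical P floors at 1/N; direction ties resolved by OR vs 1.
* Tarone statistic clamped at 0 against floating-point cancellation; a
  comparison with a zero cell anywhere gets +0.5 on all cells before the
  MH fit (`auto` mode); K=1 strata return T=0, df=0.
* Blocks with two columns have margin-determined overlap (the null is
  degenerate and every P-value is 1) — mathematically correct, and the
  reason toy examples need background columns.
* `joint_bernoulli_with_or` picks the quadratic root inside
  `[max(0, pA+pB-1), min(pA, pB)]` and clips at the boundary; theta = 1
  short-circuits to independence.
* Permutation problem sizes in the shipped tests and acceptance script
  (1,000-10,000 permutations, cohorts of 200-1,200 samples, 20 seeds per
  recovery experiment) were chosen as the smallest sizes at which the
  planted effects are comfortably in the asymptotic regime of each test.

## Known limitations

* The swap chain's default thinning (`nnz` attempted swaps) trades
  independence for speed; distribution-sensitive uses should switch to
  `restart` mode.
* The differential screen's permuted reference is generated under
  within-type independence (common OR ~ 1); for pairs with equal but large
  ORs in both types the observed statistic is only approximately matched
  in distribution, and false differential calls concentrate there
  (measured ~5-10% of conserved theta=8 pairs at FDR 0.1).
* Enrichment resamples alteration pairs (not gene pairs) from the
  testable pool; sources that publish per-edge confidence scores must be
  thresholded by the user (a score-column cutoff is provided).
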