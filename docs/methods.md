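# Methods

## Scope and inputs

The package estimates clade-level net diversification rates from standing
taxonomic richness and crown ages, and tests clades for exceptional
species richness against a background birth–death expectation. Crown ages
(e.g. Bayesian relaxed-clock estimates with 95% HPD intervals) and species
richness are **consumed as inputs**: dating, tree inference, alignment and
calibration happen upstream in dedicated tools and are out of scope, as is
any re-estimation of the packaged *Hypericum* ages themselves. Ages may be
supplied directly in a clade table, or measured from a rooted ultrametric
Newick chronogram with `crown_age`.

## Rate estimator

`net_rate` implements the taxonomic likelihood approximation
r = (ln N₁ − ln N₀)/t under a constant-rate pure-birth model. N₀ defaults
to 1 even though the ages used are crown ages; this mirrors the convention
of the analysis the packaged table comes from, and `n0=2` (the strict
crown convention, a crown group starting from two lineages) is exposed for
users who prefer it. Printed-value comparisons use round-half-even at
3 decimals, the precision of the source table.

**Bias.** On crown-conditioned Yule data the estimator is biased upward:
the median clade size is ≈ 1.68/(1 − β) with β = 1 − e^{−rt}, so the
median of ln(N)/t sits near r + ln(1.68 e^{rt})/t − r ≈ r + 0.52/t, a
relative error that falls below 15% only once rt ≳ 3.5. The simulation
study (`cladediv simulate`, and the recovery tests) quantifies this
rather than hiding it; at the *Hypericum* Páramo scale (rt ≈ 4.2) the
median recovery error is ~11–13%.

## Richness confidence band

The published description of the band's closed form is typographically
corrupted in the source (inline sub/superscripts collapsed), so the band
is derived from first principles of the linear birth–death process, which
is the construction that description cites. With
β = (e^{rt} − 1)/(e^{rt} − ε) and α = εβ:

- a lineage surviving to the present leaves Geometric(β) descendants;
- a crown group of age t, conditioned on **both** basal daughter lineages
  surviving (that is what observing a crown group entails), has size
  N = G₁ + G₂ with Gᵢ i.i.d. Geometric(β):
  P(N = n) = (n−1)(1−β)²β^{n−2}, CDF 1 − β^{n−1}(n(1−β)+β).

Integer band edges use conservative quantile conventions —
k_upper = min{n : P(N ≤ n) ≥ 0.975},
k_lower = max{n ≥ 2 : P(N < n) ≤ 0.025} — and verdicts use strict
inequalities, so a clade sitting exactly on an edge is *within
expectation*. Because the quantiles are integers the band over-covers
slightly (empirically ~95.5–96.5% at the *Hypericum* grid cells).
Continuous relaxations of the same tail equations (solved with Brent's
method) provide smooth curves for the diversity-vs-age plot. Clades are
tested at their mean crown age only, one point per clade; HPD age
uncertainty is not propagated into the test. When the background is named
by clade, its rate is recomputed from the table at full precision (0.1948
for the *Hypericum* background clade, not the printed 0.195), and that
clade is excluded from testing since it defines the null.

The conditioning convention is the one genuinely open design choice: the
source analysis does not state whether it conditioned on both daughters
surviving or used a whole-clade α-correction. Both-daughters conditioning
is adopted because it matches what a crown age means observationally, and
the Monte-Carlo oracle (below) arbitrates: analytic band edges agree with
crown-conditioned simulation quantiles to within ±2 species at 10⁵
replicates across the full (ε, t) grid. Under this convention the Páramo
verdict at ε = 0.9 (observed 67 vs k_upper = 66) is numerically borderline
but reproduces the reported "exceptionally rich" flag.

**Numerics.** β is always computed via the e^{−rt} form
(1 − e^{−rt})/(1 − ε e^{−rt}) with `expm1`, which is exact at small rt and
cannot overflow; if β rounds to 1 at working precision the band is
unbounded and a `RichnessOverflowError` says so rather than returning
garbage. Quantile searches bracket exponentially then bisect.

## Simulator

`simulate_bd` is an event-driven Gillespie simulation over the set of live
lineages (total rate (λ+μ)k, birth probability λ/(λ+μ) per event), with
λ = r/(1−ε), μ = ελ. Realisations start from a single origin lineage or a
crown pair, stop at fixed duration (or at a target tip count, pure birth
only, where the stopping rule is unambiguous), and are conditioned — on
survival, or on both crown lineages surviving — by rejection with an
attempt cap, which reproduces the conditional law exactly. Extinct
subtrees are pruned and unifurcations suppressed before output, so the
analysis only ever sees reconstructed trees; true node ages are recorded
at generation time, keyed by descendant tip set, so tests can verify that
`crown_age` recovers them exactly. Incomplete sampling is emulated as
independent tip retention with probability ρ (`subsample_tips`); results
with fewer than two surviving tips are flagged degenerate. One seed drives
all randomness and identical configs give identical trees.

For distribution-level validation at large replicate counts
(`mc_crown_sizes`, `mc_clade_size_quantiles`) the same process is
simulated at the level of its lineage-count jump chain in a
numba-compiled kernel — no tree construction — and crown conditioning
exploits the independence of the two basal lineages (each side simulated
survival-conditioned, sizes summed), which is the same law as joint
rejection. The tree-building and count-level routes are cross-checked
against each other by a two-sample test in the suite.

## What the synthetic data does and does not emulate

Simulated chronograms have constant rates, exact ultrametricity,
independent Bernoulli tip sampling, and known (r, ε). Real chronograms
carry dating error, rate variation across lineages and time, non-random
(often diversified) taxon sampling, and topological uncertainty — none of
which the generator produces. Passing tests therefore demonstrate the
internal consistency of the estimator, the band and the simulator under
the stated model, not robustness of the biological conclusions to model
violations (punctual extinction or decelerating rates can mimic elevated
net diversification, and richness counts for open taxonomies are
themselves estimates).

## Problem sizes

Default validation scales are chosen to keep quantile noise well inside
the tolerances they check: 10⁵ crown-conditioned replicates per grid cell
for oracle agreement (percentile standard error below one species at the
scales used), 2 000 replicates for empirical coverage, 500 tree
replicates for estimator recovery, and brute-force CDF checks over
n ≤ 500. All are recomputed at run time; nothing is cached.

## Known limitations

- No stem-age variant of the richness test; crown ages only.
- No per-clade extinction estimation; ε enters only as a null hypothesis.
- No time-varying rates or diversified/clustered sampling schemes in the
  simulator, and no sampling-through-time tree-prior density.
- The rate estimator is the pure-birth taxonomic form; method-of-moments
  estimators with ε > 0 are deliberately out of scope.
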