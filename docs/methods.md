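# Methods

This note records the statistical models the package implements, the
conventions and numerical choices behind them, what the synthetic-data
generator does and does not emulate, and the known limitations. Everything
quantitative stated here is computed by the test suite or the examples.

## Sequence handling

Alignments are rectangular nucleotide matrices over {A, C, G, T, N, -}. Two
site-handling policies run through the package. *Pairwise deletion* drops,
per sequence pair, the sites ambiguous in either member; it is the default
for raw distance matrices. *Complete deletion* drops any column ambiguous in
any sequence, so that S, Π, π and the mismatch histograms all share one site
set (the convention of the standard diversity software this package
replaces); it is the default for the summary statistics. Under pairwise
deletion the effective length used for π is the per-pair complete-site count
averaged over pairs, which keeps π = Π/L exact for gap-free data.

Haplotype collapsing offers a *wildcard* policy (N and - compatible with
every base; a sequence joins the first haplotype whose representative it is
compatible with — compatibility is not transitive, so classes are anchored
on their first member to keep the partition deterministic) and a *strict*
policy (literal identity). Deposited barcode data carry terminal Ns, which
is why wildcard is the default; the statistics that feed Fu's Fs use strict
identity so that the haplotype count matches the Ewens-model definition of
"distinct allele".

Distances are uncorrected mismatch counts or p-distances; a Jukes–Cantor
correction is available behind a flag but off by default, since at
within-species divergences (≈1%) the correction is negligible.

## Diversity indices

Per group and pooled: sample size n, haplotype count k, private haplotypes
PH (haplotypes seen in exactly one group) with ratio PH/k(group), Nei's
unbiased gene diversity H = n/(n−1)(1 − Σp²) (the uncorrected form is a
flag), segregating sites S, mean pairwise difference Π, per-site π, and
Watterson's θ_W = S/a₁ with a₁ = Σ_{i<n} 1/i. Values are kept at full
precision internally and rounded only at write-out (5 decimals).

## Neutrality tests

Tajima's D uses the standard constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂); it
is undefined (an error, not silently zero) for S = 0 and requires n ≥ 4.
Fu's Fs is computed from the Ewens sampling distribution
P(K=k) = |s(n,k)| θᵏ / (θ)ₙ with unsigned Stirling numbers of the first
kind evaluated by a log-space row recurrence (|s(364, k)| overflows doubles
by hundreds of orders of magnitude), θ̂ = Π (Tajima's estimator, Fu's own
choice), and S′ = P(K ≥ k_obs); Fs = ln(S′/(1−S′)). Boundary cases
(k_obs = 1, S′ numerically 0 or 1) raise a guarded error naming the
boundary.

Significance is simulation-based only: constant-size coalescent replicates
at θ = Π, left tail, with the (r+1)/(B+1) estimator; replicates on which a
statistic is undefined are dropped and counted, with a warning above 10%.
The classical convention that Fs is significant at the 0.05 level when
p < 0.02 is exposed alongside the raw p; a raw p ≤ 0.05 cut-off for Fs is
liberal (measured rejection ≈ 0.08 on stationary data at n = 30), which is
precisely the behaviour Fu's convention corrects for. Default replicate
count is 1000 (CLI flag for 10 000). The acceptance suite verifies the
0.05-level type-I error of both decision rules (p ≤ 0.05 for D, p < 0.02
for Fs) within binomial 99% bounds over 1000 stationary datasets
(n=30, θ=5, B=199) — parametric calibration with θ estimated from the data
is approximate, and this test is the evidence that the approximation is
adequate at study-like sizes.

## Mismatch distributions and demographic fitting

The sudden-expansion expected distribution is
F̂ᵢ(θ) = θⁱ/(θ+1)ⁱ⁺¹ at equilibrium and

    Fᵢ(τ,θ₀,θ₁) = F̂ᵢ(θ₁) + e^{−τ(θ₁+1)/θ₁} Σ_{j≤i} τ^{i−j}/(i−j)! (F̂ⱼ(θ₀) − F̂ⱼ(θ₁))

evaluated with log-space Poisson weights (τ can be large) and the analytic
θ₁ → 0 limit. The spatial-expansion model treats a within-deme pair in an
infinite island array (demes of size θ, scaled migration M, ancestral deme
of size θ seeding the array τ mutational units ago): coalescence before τ
contributes regularised incomplete-gamma terms; survival to the ancestral
phase contributes a Poisson(τ) mixture of the ancestral equilibrium. Both
are truncated at d_max = (largest observed difference + 5) and renormalised;
truncated mass is negligible at the parameter scales involved.

Fitting minimises the plain SSD between observed and expected relative
frequencies with bounded Nelder–Mead from a deterministic multi-start grid
(τ from the histogram mean; θ₀ ∈ {0.01, 1}; θ₁ ∈ {10, 100}; bounds
τ ∈ [0, 50], θ ∈ [0, 10⁵]); the returned optimum is never uphill of any
start. θ₁ estimates at the upper bound are flagged as effectively infinite,
mirroring the "inf" entries of the software lineage this follows. A
compiled (numba) objective and simplex driver accelerate the bootstrap hot
loop; the numpy/scipy route remains as the reference implementation and
automatic fallback, and agreement between the two is asserted in tests.

**Identifiability and the star variant.** The SSD objective is nearly flat
in θ₁ above ≈100, so the free fit frequently runs θ₁ to the bound; this is
a property of the estimator, not a numerical failure. `fit_expansion(...,
star=True)` fixes θ₁ at its effectively infinite limit — the classical
large-expansion assumption — with a denser (τ, θ₀) start grid including the
method-of-moments point (θ₀ = √max(v−m, 0), τ = m − θ₀). The star variant
is the stable estimator, and the one whose goodness-of-fit bootstrap is
well calibrated (below).

Harpending's raggedness is r = Σ_{i=1}^{d+1} (xᵢ − xᵢ₋₁)² with x_{d+1} = 0:
a single spike at class 0 gives r = 1; a uniform distribution over ten
classes gives 0.01 (only the trailing boundary term survives).

**Parametric bootstrap.** Goodness of fit simulates B coalescent datasets
under the fitted parameters with the observed n and L, refits each
(warm-started at the parent estimates for the free fit; with the same
deterministic grid for the star fit), and reports p = #{statistic ≥
observed}/B — the raw-proportion convention — plus 5–95% percentile
intervals of the refitted parameters. Spatial-model bootstraps use a
25-deme island array as the finite stand-in for the infinite-island
expectation. Failed replicates are dropped and counted (warning above
10%).

Calibration of the double bootstrap was measured directly (the acceptance
suite repeats a reduced version): with the star fit, SSD p-values on data
simulated from the fitted model are approximately uniform. With the free
3-parameter fit they are **anti-conservative** whenever θ̂₁ lands far from
the generating value (the bootstrap null under a boundary θ₁ is much
narrower than under a moderate θ₁), and p ≈ 0 arises on well-fitting data.
Users wanting a decision-grade goodness-of-fit test should use the star
variant; the free fit is for Table-style parameter reporting. Residual
calibration error of the star variant comes from sampling noise in (τ̂, θ̂₀)
interacting with the mild τ-dependence of the SSD null and is small but not
zero at n = 100, B = 200.

## AMOVA and Φ statistics

The metric is the squared mutational-difference distance (haplotype-level
molecular variance); the 0/1 "different haplotype" metric behind
`use_distances=False` reproduces conventional frequency-based F-statistics.
Sums of squared deviations are partitioned within/among populations (and
among groups for the three-level design); variance components come from the
method-of-moments equations with the standard unequal-sample-size
coefficients; negative components are reported as computed. Permutation
schemes: individuals anywhere (Φ_ST), individuals within groups (Φ_SC),
whole populations among groups (Φ_CT); p = (r+1)/(B+1) counting ties as
exceedances (the tie-inclusive convention keeps the test valid; for tiny
populations ties against the observed partition are non-negligible and the
minimal attainable p is correspondingly larger). Pairwise Φ_ST applies the
two-level machinery to every pair and equals the two-population AMOVA
exactly. No multiple-testing correction by default; sequential Bonferroni
(Holm) is provided.

## Statistical-parsimony network

The parsimony connection probability for j observed differences over L
sites is defined as the probability that the j differences arose from
exactly j substitutions (no superimposed changes anywhere), under a
Jukes–Cantor finite-sites model with the pairwise divergence given a
uniform prior on the p-distance:

    P(j, L) = [∫₀^¾ λ(q)ʲ e^{−Lλ(q)} dq] / [∫₀^¾ qʲ(1−q)^{L−j} dq],
    λ(q) = −(3/4) ln(1 − 4q/3)

The numerator reduces to j!/(L + 4/3)^{j+1} by substituting λ for q; the
denominator is an incomplete Beta function. A dense Simpson-quadrature
oracle of the same two integrals is kept in the package and equality is a
test contract. The 95% connection limit for a 554-bp fragment is 6 steps —
deliberately more conservative than the ~9 steps of the interactive
program this replaces, whose published estimator involves additional
approximations; the limit is also exposed as a direct argument for users
who want a specific value.

Construction joins haplotype pairs in non-decreasing distance order
(ties: higher endpoint frequencies first, then id order — a deterministic
simplification of the interactive frequency/topology loop-breaking
criteria), inserting d−1 inferred intermediates on a d-step connection with
mutations applied in ascending site order. Cycle-closing connections are
skipped by default (forest output; edges = nodes − components exactly);
`keep_cycles=True` records them as direct annotated edges. The ancestral
haplotype per component maximises the normalised product of frequency and
degree (ties: frequency, then id; flagged). On simulated star expansions
(n=50, τ=3) the designated ancestor matches the true root haplotype in well
over half the replicates (test threshold 60%).

## Coalescent simulator

Time is measured in mutational units of 1/(2u) generations: a pair
coalescing t units ago accumulates Poisson(t) differences, a deme of scaled
size θ = 2Nu coalesces each lineage pair at rate 1/θ, lineages mutate at
rate 1/2 and migrate at rate M/(2θ). This makes the simulator's
(τ, θ₀, θ₁) directly commensurable with the sudden-expansion mismatch
model — datasets simulated at given parameters reproduce the expected
mismatch curve in expectation, which is asserted by test and is the
contract the parametric bootstrap relies on. Sudden expansion switches the
size from θ₁ to θ₀ at τ (θ₀ = 0 collapses the remaining lineages
instantly); exponential growth integrates the rate analytically;
the island model collapses all demes into the ancestral deme at τ (or
never, for the plain equilibrium island model).

Mutation models: infinite sites (each mutation a fresh column; segregating
sites equal mutation events by construction, and exceeding L raises an
error that the bootstrap treats as a failed replicate) and a finite-sites
HKY-like mode (uniform site choice, transition probability
tstv/(tstv+1) = 3.99/4.99 by default, transversions split equally). The
root sequence is all-A; haplotype identity depends only on differences.
For calibration loops, summary (S, Π, K) and mismatch histograms are
computed directly from the genealogy and mutation counts without realising
sequences; the fast paths are verified bit-identical to the alignment route
under shared seeds.

### Study-like fixture

`make_study_like_dataset` emulates the sampling design of a four-region
circum-Antarctic dataset: 364 sequences of 554 bp — EA 227 (subdivided
TA 167 / RS 28 / BR 19 / DS 13), AP 95, WS 29, AI 13 — with EA and AP as
old, diverse sudden expansions (τ = 3.4 and 4.7), WS as a recent shallow
expansion (τ = 0.95), and the island samples drawn as founder subsamples of
the EA and WS genealogies (SSI from EA, BI from WS). Each region carries a
short private stem (1–2 fixed substitutions at disjoint sites) standing in
for regional lineage sorting, which produces study-scale among-region
differentiation (pairwise Φ_ST ≈ 0.1 between EA and the island founders,
0.6–0.7 for the WS and AP contrasts) while the island founders inherit
their source region's stem. Post-expansion sizes (θ₁ = 20, 15, 3) and the
stem lengths were calibrated once so the pooled haplotype count falls in
the 85 ± 25 band across seeds while preserving the regional diversity
ranking (EA ≈ 49 haplotypes, WS ≈ 4 at seed 1). Coordinates and depths are
synthetic anchors with jitter, for interface completeness only.

What the generator does **not** emulate: mutation-rate heterogeneity among
sites, sequencing error, within-region spatial substructure (the real DS
sample is strongly differentiated; the fixture's EA subregions are
exchangeable labels), selection, and recombination (absent from animal
mtDNA anyway). Tests passing on this fixture therefore validate the
statistical machinery under the stated coalescent models, not the
idiosyncrasies of any real dataset.

## Pipeline and reproducibility

`run_all` executes diversity → neutrality → mismatch → structure → network
→ dating from one config. One global seed derives per-stage seeds by
CRC-hashing the stage name, so stages re-run in isolation reproduce the
pipeline outputs; every CSV carries a header comment with the tool version
and a config digest, and `run_log.json` records status, timing and seed per
stage. Stage failures are isolated; dependants (dating needs the mismatch
fits) are marked skipped-dependent.

## Problem sizes used in validation

The full-scale validation experiments run at: 1000 stationary datasets
(n = 30, B = 199) for neutrality calibration; 100 expansion datasets
(n = 100) for τ recovery plus 200 meta-replicates × B = 200 for bootstrap
calibration; 500 panmictic replicates (n = 30, B = 199) for the Φ_ST
type-I error; 2000 replicates for the simulator moment checks; 100
replicates for the ancestral-haplotype benchmark. These sizes keep the
whole suite in the tens of minutes on one core while leaving the binomial
and KS bounds meaningful.

## Known limitations

- Single-locus inference: all uncertainty intervals condition on one
  genealogy; regional parameter estimates (especially θ₁) are weakly
  identified, and CIs from the parametric bootstrap are percentile
  intervals, not profile likelihoods.
- The free 3-parameter mismatch gof bootstrap is anti-conservative when
  θ̂₁ hits its bound (see above); use the star variant for testing.
- The spatial-expansion bootstrap approximates infinite islands with 25
  demes.
- The parsimony connection limit is more conservative than TCS 1.21's; the
  network topology for typical barcode datasets is insensitive to this
  (most connections are ≤ 3 steps), but deep splits may fragment into more
  components.
- The wildcard collapsing policy is order-dependent for pathological
  N-patterns (non-transitive compatibility); the strict policy is the
  reproducible reference.
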