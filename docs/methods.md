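# Methods

This note documents the statistical models implemented in `ranksig`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Rank profiles

Expression is quantified non-parametrically. Within each sample, probes
are ranked by descending intensity (average rank on ties) and scaled to
[0, 1] as `(rank − 1)/(P − 1)`, so 0 is the highest-expressed probe and 1
the lowest; the scaled ranks of one tie-free sample are exactly
{0, 1/(P−1), …, 1}. Sample-set ranks `r` are per-probe means over the
samples of interest; background ranks `r0` are per-series means averaged
with equal series weight, so a large background series does not dominate.

The relative rank is `(r0−r)/r0` when `r < r0` and `(r0−r)/(1−r0)` when
`r > r0`, zero at equality. Degenerate backgrounds take the continuous
limit: at `r0 = 0` only the below branch can fire (denominator 1), at
`r0 = 1` only the above branch — the result always lies in [−1, +1] and is
non-increasing in `r` at fixed `r0`. Because only orderings enter, any
strictly monotone transform of the intensities leaves everything invariant
(property-tested).

Probe-to-gene collapse keeps the probe of **largest magnitude** relative
rank. "Largest" could also be read as signed-largest; magnitude was chosen
for consistency with the differential collapse (maximal-magnitude Z), with
ties broken toward the positive value and then by lexicographic probe ID
for determinism.

Profiles are compared by Spearman ρ over shared keys with the large-sample
null scaling `z = ρ·√(n−1)`; under independence z is approximately standard
normal (tested at n = 5000).

## Differential profiles

The differential statistic is the ordinary two-group linear-fit Z: with
arm sizes n₁, n₂ and pooled variance s²ₚ (n₁+n₂−2 df),
`Z = (mean_t − mean_c) / √(s²ₚ(1/n₁ + 1/n₂))`, reported without any df
correction or moderation. Degenerate inputs are kept finite by a pooled
variance floor of 1e−8 (log2 units²) and a |Z| cap of 40; the cap is
reached only through the floor.

Consequences worth knowing: at 4 vs 4 the null Z is a t(6) variate with
SD √(6/4) ≈ 1.22, not 1; and the maximal-magnitude collapse inflates this
further — the signed max-|t(6)| over the default probe-degeneracy mixture
(70% of genes with one probe, 15% with two, 15% with three) has SD ≈ 1.39
by order-statistics simulation, which the null-calibration test asserts as
the band [1.25, 1.5]. The Z thresholds of 3 ("three standard deviations")
and 5 used downstream are therefore conventional labels on this
uncorrected scale, exactly as reported statistics of this family usually
are.

Two profiles are compared by restricting to keys with |Z| ≥ z_cut in
*both*, tabulating sign agreement into UU/UD/DU/DD, and testing with the
one-sided Fisher exact probability of concordance at least as large —
conditioning on the margins, this is the hypergeometric upper tail of UU.
The one-sided reading was verified against a brute-force hypergeometric
sum before freezing: on the tabulated 64-probe example (UU 28, UD 7,
DU 13, DD 16) the one-sided tail is 3.77e−3 and the two-sided test exceeds
4e−3, so only the one-sided test satisfies the published bound.

Stouffer combination is `(z₁ + z₂)/√2` over shared keys; combining a
profile with itself scales it by √2 exactly.

## Gene-set enrichment

The enrichment statistic is a Kolmogorov–Smirnov variant. With the profile
sorted by descending score (ties broken lexicographically for determinism)
and C_i the count of set members among the top i of M keys:

    D_max = max_i (C_i/N − i/M) ≥ 0,   D_min = min_i (C_i/N − i/M) ≤ 0

computed by an O(N) shortcut over member positions (the running statistic
jumps at member positions and drifts down between them); the shortcut is
tested identical to the full O(M) scan on 1,000 random instances. The
reported statistic is `Z = (D_max + D_min)/σ(N, M)` with

    σ(N, M) = √(β − α·N/M) · N^(−γ),
    α = 0.3274679, β = 0.3327016, γ = 0.491337.

Positive Z means concentration at the top of the ranking. Sets with fewer
than `n_min = 5` members on the profile are skipped — the σ law is not
validated below that size. Under random sets the scaled Z has empirical SD
within 10% of 1 (asserted at M = 5000, N = 50, 200 sets), and
`D_max + D_min` is close to normal (|skewness| < 0.2 at N = 50).

### Monte-Carlo calibration

`calibrate_null` re-derives the constants: for each N on a grid it draws
uniform N-subsets of {1…M}, records the empirical SD of `D_max + D_min`,
estimates γ as the negated slope of log SD on log N, then fits (α, β) by
a linear fit of SD²·N^(2γ) against N/M refined by nonlinear least squares
of the σ form with γ fixed.

The staging matters. γ is identifiable on its own only where N/M is small
(the amplitude factor is then nearly constant); β and γ trade off along a
near-flat ridge (dβ/dγ ≈ 2β·⟨ln N⟩ on the grid), so a free three-parameter
fit identifies neither, and the amplitude is measured conditional on an
exponent. `scripts/acceptance.py` therefore reports γ from the dilute grid
(M = 10,000, N ≤ 200, 2,000 replicates per point) and β from the dense
grid (M = 2,000, N up to M/2) with γ pinned at the law's published
exponent — the quantity the dilute grid validates. These grid sizes keep
the whole script at a few seconds on one CPU.

## Connectivity and TFCEPs

A query signature (disjoint up/down gene sets) is crossed with each bank
signature into UU/UD/DU/DD and scored
`sign(UU+DD−UD−DU) · (−log10 p)`, where p is the one-sided hypergeometric
tail **on the side of the observed association**. Using the directional
tail (rather than always the concordance tail) is what makes the score
exactly antisymmetric under up/down swap of either signature and symmetric
in its arguments — both property-tested. The 2×2 is tested on its own
margins; the bank's gene-universe size is retained for documentation only.
A consequence of margin conditioning is that a one-directional overlap
(a single nonzero cell) is uninformative (p = 1, score 0): a useful bank
signature needs both an up and a down side.

TF co-expression profiles are built from a compendium of series: within
each series every gene is standardized against the series' own mean and SD
(≥ 4 samples required; SD floored at 1e−4, the square root of the
differential variance floor), and samples beyond ±`z_dev` (default 2.0 —
the deviation threshold is a free parameter of this method family) are
called ±1. Two genes are co-expressed when their calls agree across the
samples where **both** are called (at least `min_joint = 3`, below which
the Fisher test is vacuous); each TF's signature is its top-k positively
and top-k negatively co-expressed partners (k = 500 by default; partners
must pass p ≤ 0.05 before truncation — lists are not padded), ranked by
ascending directional p with name tie-breaks.

## The synthetic-data generator

All randomness flows from one integer seed through named
`numpy.random.SeedSequence` substreams (one per stage), so adding a stage
never perturbs another's stream and identical configurations are
byte-identical after serialization.

The generator emulates, at desk scale:

* **Experiment** — two cell lines × {vehicle, treated} × 4 replicates;
  per-probe baselines N(8, 2²) on the log2 scale per cell line (only ranks
  matter downstream, so the baseline law is free); planted genes shifted
  by their log2 effect in the treated arms of **both** lines (a shared
  response, which is what makes the cross-context concordance and Stouffer
  stages recoverable); homoscedastic Gaussian noise, default SD 0.25.
  Default planted effects are ±2 log2 units for 30 + 30 genes.
* **Background compendium** — 5 series × 10 samples over the same probe
  universe, each with its own baseline shift; ~2% of probes constitutively
  high and ~2% low in every series (their background ranks sit near 0 and
  1, exercising the degenerate r0 branches).
* **Panel** — 17 rank profiles, one a twin of the core GRP plus bounded
  uniform rank noise (±0.05, clipped), the rest independent uniform
  profiles. Only the core gets a twin, mirroring a margin population that
  matches no reference entity.
* **Drug bank** — planted signatures covering the reference signature with
  a stated concordance fraction (same sign for that fraction of genes,
  flipped for the rest) among size-matched random decoys; 100 signatures
  by default.
* **Co-expression compendium** — 10 series × 30 samples at gene level.
  Each planted module is driven by a sparse latent perturbation: 8% of
  samples carry a ±4 amplitude, module genes load +1, anti-module genes
  −1, private noise SD 0.3; other genes are independent unit-variance
  noise. The sparse-perturbation design reflects how co-expression emerges
  in perturbation compendia, and its defaults are chosen so that a planted
  pair yields ~20+ jointly-called samples (pair p < 1e−4) while perturbed
  samples still clear the deviation threshold (≈ 2.5 SD even for genes
  shared by two modules). Modules may list an anti-module because
  margin-conditioned signature scoring needs partners on both sides (see
  above); the default study plants a mimic TF, a reverser TF and an
  unrelated TF.

What the generator does **not** emulate: probe-level hybridization
artifacts, batch effects, intensity-dependent (heteroscedastic) noise,
correlated gene programs outside the planted modules, and realistic
signature sizes of public drug compendia. Passing planted-truth tests
therefore demonstrates that the algorithms recover what they are designed
to recover under their own stated model — not performance on real arrays.

## Numerical conventions

* Ties: average ranks within samples; lexicographic key tie-breaks in all
  orderings; magnitude ties in collapses resolve toward the positive value
  then lexicographic probe ID.
* Floors/caps: pooled variance ≥ 1e−8, |Z| ≤ 40, deviation-call SD ≥ 1e−4,
  p values floored at 1e−300 before log10.
* Fisher tails come from `scipy.stats.hypergeom`; Spearman from
  `scipy.stats.spearmanr`; amplitude refits from
  `scipy.optimize.curve_fit`.
* Empty 2×2 tables return p = 1 with direction "none" (no error); an empty
  profile∩set intersection is an error (no statistic exists).
* Writers emit `#`-prefixed provenance headers (stage, parameters, seed,
  input digests — never timestamps), so pipeline reruns are digest-
  identical.

## Known limitations

* The Z scale is the uncorrected pooled t; small-sample calibration is
  deliberately not normal (see above). Users who need calibrated tail
  probabilities should moderate or transform externally.
* σ(N, M) is an approximation: its effective log–log exponent on a dilute
  grid measures ≈ 0.49–0.50 depending on the grid, and the calibrator's
  constants are meaningful only jointly, as a parameterization of the law
  on the grid used.
* The margin-conditioned connectivity score cannot rank one-sided
  signatures; banks should carry both up and down lists.
* `enrich_collection` scores sets independently; no multiple-testing
  correction is applied anywhere, by design — rankings, not calibrated
  discovery lists, are the output.
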