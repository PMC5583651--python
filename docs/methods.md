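# Methods

## Scoring model

One sample run is up to 12 genes × 3 replicate wells of crossing-threshold
(C_T) values. Replicates are averaged per gene over non-missing wells;
undetected wells are missing values, never sentinel Cts, because a sentinel
(e.g. 40) would bias the mean. A gene needs at least 2 valid replicates — a
single well has no internal error control — otherwise the sample fails
replicate QC.

The housekeeper mean (HKM) is the arithmetic mean of the three housekeeper
gene means. Normalized target expression is Δ_g = HKM − C̄_g. The sign
convention (higher Δ = higher expression) is isolated in `normalize_targets`
and documented in the panel config so configured coefficients carry matching
signs. Because Δ is a difference of Cts, any plate-wide Ct shift cancels
exactly; this global-shift invariance is asserted by property tests both at
the function level and end to end through simulated plates.

The molecular score is β₀ + Σ β_g Δ_g, optionally clipped to a configured
reporting range (the example panel clips to [0, 15]). The clinical score is a
configured linear combination of molecular score, tumor-size code and
positive-node code; absent covariates yield a missing clinical score and
risk, never an error.

### QC gates

* HKM within the validated window, inclusive at both ends (default [19, 27]).
* Contamination: the control gene amplifies only from genomic DNA; the sample
  is contaminated when ≥ 2 replicates are strictly below Ct 38 ("below"
  reads as strict inequality). Missing control wells count as not-below.
* Any QC failure withholds all scores and records reason codes; a replicate
  range > 1.0 Ct is logged as a warning only.

### Risk dichotomization

The published cutoff pair (≤ 3.3 low / ≥ 3.4 high) implies one-decimal
reporting granularity, so scores are rounded half-away-from-zero to 1 decimal
before comparison, which closes the (3.3, 3.4) gap and makes the
classification total. Rounding goes through `Decimal` on the shortest repr to
avoid binary-float artifacts (3.35 → 3.4).

## Validation statistics

**Concordance.** Lin's CCC with population (1/n) moments,
CCC = 2·cov / (var_x + var_y + (μ_x − μ_y)²). The CI uses Lin's asymptotic
standard error on the Fisher z scale (tanh-backtransformed); the paired mean
difference carries a t-based CI and two-sided p-value. The point estimate is
cross-checked in the tests against an independent brute-force evaluation of
the defining formula on random small vectors.

**Precision.** Pooled SD = √(mean within-group sample variance). The
two-sided 95% interval is `sd·sqrt(df/χ²_{q,df})` with df = number of groups
by default; with 12 groups this maps an SD of 0.21 to (0.15, 0.35). The
alternative pooled convention df = Σ(nᵢ−1) is exposed (`--ci-df pooled`);
the groups convention is the default because it is the more conservative
band for small replicate counts.

**Linearity and efficiency.** Per-gene OLS of replicate-mean Ct on
log₂(concentration) (replicate-mean fitting is the default; each dilution
point contributes one residual). Efficiency = (2^(−1/slope) − 1)·100, the
base-2 form of the standard dilution-curve efficiency; it equals 100% iff the
slope is −1 and is strictly decreasing in |slope|. The linear range is the
widest contiguous window of tested concentrations with R² ≥ 0.95 (default)
for every expression gene, ties broken toward the window including lower
concentrations (the clinically limiting end); at least 3 points are required
for a fit and 4 for a range search. The HKM↔concentration map is the pooled
housekeeper regression, inverted analytically, with input masses reported at
the 45 µL inoculation volume.

**Stability.** Per-sample SD of scores across storage timepoints (≥ 2
required; single-timepoint samples are excluded with a warning); delta scores
are deviations from each sample's own timecourse mean and sum to zero per
sample.

## Synthetic data

The generator works on the Ct scale with additive Gaussian noise, matching
the inter/intra replicate design of a precision study:

* **Dilution series**: Ct(g, c) = intercept_g − log₂(c)/log₂(1 + eff_g/100)
  + N(0, σ_rep). Defaults: 12 two-fold points from 100 ng/µL (down to
  100/2¹¹ ≈ 0.049), 3 replicates, σ_rep = 0.3 Ct — the scale of observed
  per-gene replicate SDs — and per-gene efficiencies spanning 95.9–101.1%.
  Housekeeper intercepts center on 23.6 Ct at 1 ng/µL so the ladder maps to
  HKM ≈ 17–28, placing the validated HKM window strictly inside the tested
  range.
* **Sample batches**: per-sample true HKM uniform on [21, 25]; true
  normalized target expressions uniform with half-width 2.1 around 2.5,
  chosen so example-panel molecular scores span roughly 2–7. Observed Ct =
  truth + per-gene batch effect (σ_batch, redrawn per plate in inter mode,
  shared in intra mode) + per-well noise (σ_rep). Batch effects are per-gene
  rather than plate-global because a global shift cancels in the score.
* **Noise calibration**: the score is linear in the per-gene mean Cts with
  weight −β_g on target g and (Σβ)/3 on each housekeeper, so iid per-gene
  perturbations of SD s give score variance s²·(Σβ² + (Σβ)²/3).
  `well_sd_for_score_sd` inverts this to produce an exact score-level truth
  for recovery experiments.
* **Contamination injection** rewrites the control-gene wells of a Bernoulli
  subset of samples to ≥ 2 replicates below the cutoff; clean samples sit
  above it.
* **Stability time course**: 6 samples × 7 weekly timepoints, true scores
  spread over ~2–7, Gaussian score noise (default SD 0.2).

What the generator does **not** emulate: FFPE degradation chemistry,
amplification-curve shapes (sigmoid fluorescence), plate-position effects,
inter-gene expression correlation, and non-Gaussian outliers. Passing tests
therefore demonstrate the correctness and calibration of the estimators under
the assumed noise model, not the assay's behavior on real tissue.

## Problem sizes and numerical choices

Recovery experiments use the study-scale designs: 12 samples × 3 replicates
for interbatch precision, 20 × 2 for intrabatch, 12-point × 3-replicate
dilution ladders, 6 × 7 stability courses. Seed-replicated summaries
(efficiency medians, R² floors, CI coverage) use 100–500 seeds, enough for
the Monte-Carlo error to be an order of magnitude below the tolerances
asserted. All randomness flows through `numpy.random.default_rng` seeded from
one configured integer; identical configs are bit-reproducible.

Degenerate inputs are errors, not NaNs: CCC with zero variance and equal
means, precision groups with < 2 values, dilution fits with < 3 distinct
concentrations, SDs of a single dilution point or timepoint. Efficiency
requires a negative slope ("non-amplifying fit" otherwise). Report
timestamps live in a single provenance field so determinism checks can
exclude them.

## Known limitations

* The example panel's coefficients, intercepts and clinical weights are
  synthetic; absolute score values in examples are meaningful only relative
  to that panel.
* The intrabatch chi-square interval depends on the df convention and is not
  uniquely determined by the pooled-SD definition alone; the report always
  states the convention used.
* Accuracy comparison matches samples by identifier and drops unmatched ones
  with a logged count; it does not model systematic inter-laboratory bias
  beyond the paired mean difference.
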