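# Methods

This note documents the statistical machinery in `shellbed`, the choices
made where the design was genuinely open, and what the synthetic tests do
and do not demonstrate about real survey data.

## The two-stage (hurdle) model

Abundance of a sessile epifaunal species on a cell grid is modelled as
occurrence × density-given-presence. The occurrence stage is a
gradient-boosted classifier on environmental covariates; the abundance
stage is a gradient-boosted regression of ln(density, ind m⁻²) fitted on
presence sites only, with the averaged out-of-bag occurrence probability
(P_presence) appended as a covariate. The two stages are deliberately fit
separately (no joint zero-inflated likelihood): the processes limiting
where a species settles differ from those limiting how dense it grows, and
the separation lets each stage be validated on its own terms.

Log-scale predictions are recalibrated before use:

* **ROE correction.** OLS of observed on predicted log densities gives
  (a, b); corrected = a + b·pred. On its own training pairs the correction
  is idempotent (slope 1, intercept 0 on re-fit), which the tests assert to
  1e-8. Constant predictions degenerate to (mean, 0) and are flagged.
* **Duan smearing.** D = mean(exp(residual)) over the log-scale residuals
  of the corrected model, the nonparametric estimate of the retransformation
  factor (equals exp(σ²/2) under Normal residuals, which the tests verify
  by simulation). Residuals are taken after the ROE correction — correction
  first, smearing second — and the natural log is used throughout.

Final cell densities are exp(a + b·raw)·D with (a, b, D) averaged over the
bootstrap iterations; counts per cell are density × 100 m².

## Bootstrap 0.632+ validation

All performance numbers come from one engine (`shellbed.bootstrap`). B
bootstrap samples of size n are drawn with replacement (simple, not
stratified); each refitted model is scored on its own sample and on the
omitted (out-of-bag) sites. On a loss scale, with γ the no-information
rate,

    oob′ = min(oob, γ)
    R    = (oob′ − apparent) / (γ − apparent)   clipped to [0, 1]
    w    = 0.632 / (1 − 0.368 R)
    best = (1 − w)·apparent + w·oob′

Gain metrics (AUC, accuracy, TSS, correlations) are mapped to losses as
1 − value and back, keeping a single estimator code path. The `apparent`
anchor is the full-data fit evaluated on itself; per-iteration training
values are also recorded. γ is analytic where possible (0.5 for AUC, 0 for
TSS and correlations), the permutation expectation p(1−q) + (1−p)q for
misclassification, and an all-pairings mean for continuous losses.
Edge conventions are explicit: R = 0 whenever γ ≤ apparent, except
γ = apparent with oob > apparent, which sets R = 1 (maximal overfitting,
logged). Iterations whose OOB set leaves a metric undefined (a missing
class) are excluded from that metric's mean with a logged count.

A note on set sizes: a bootstrap sample contains ≈ n(1 − e⁻¹) ≈ 0.632 n
*unique* sites, so the out-of-bag set holds the complementary ≈ n/e ≈
0.368 n. The tests assert the unique-in-bag count against n(1 − e⁻¹).

Hyperparameter tuning (repeated stratified CV, k = 10 × 10 repeats, AUC for
classification / RMSE for regression) is available per call, but the
pipeline tunes once on the full data and reuses the chosen configuration
across bootstrap iterations. Re-tuning inside every iteration multiplies
cost ~100× for hyperparameters that are, in practice, stable across
resamples of the same survey; the tuning grid is configurable where that
assumption should be revisited.

## Prevalence-matched thresholds

Probabilities become presences at a cut-off t chosen so that the share of
training scores ≥ t equals the observed training prevalence (the midpoint
between the two order statistics that straddle ⌈np⌉, clamped at the
extremes). One t_b is fitted per bootstrap iteration from that iteration's
own scores and prevalence; their mean t̄ thresholds the final full-data
score map, and the spread of {t_b} propagates into the occupied-area
uncertainty of Methods 2 and 3. Matching per-iteration (rather than to the
global prevalence) is deliberate: it lets threshold uncertainty carry
through the estimators.

## Substrate covers

Covers in [0, 1] with point masses at both ends are decomposed into
P(cover = 0), P(cover = 1 | cover > 0) and a logit-scale interior mean —
the same predictive contract as a zero-one-inflated beta (point masses +
interior mean), fitted with boosted components (learning rate 0.05,
stopping iteration by internal validation-set early stopping) rather than a
cyclic distributional-boosting scheme; only the expected cover feeds
downstream, so the interior precision is not modelled. Classification of
the point masses uses a 0.5 probability threshold. Fitting the one-mass
conditionally on cover > 0 guarantees p₀ + p₁ ≤ 1 cell-wise.

## Population estimators and their uncertainties

Zones are five equal partitions of coastal position Y; depth strata are
0–0.5, 0.5–3, 3–6, 6–10 m, half-open below with the 10 m boundary closed.
All areas derive from the masked grid at 100 m² per cell.

* **Method 1** (design-based): N̂ = Σ A_zs·d̄_zs over zone × stratum, zeros
  included; SE² = Σ A²·s²/n (classical stratified sampling). Empty cells
  borrow the depth-stratum mean pooled across zones; n < 2 cells borrow the
  pooled stratum variance (both logged).
* **Method 2**: presence-site mean density d̄⁺_zs times the occupied area
  Â_zs(t_b) averaged over thresholds; SE² sums Â²·Var(d̄⁺) + d̄⁺²·Var_b(Â)
  per stratum (first-order product propagation, independence assumed — an
  approximation stated in reports). Occupied area is averaged before the
  multiplication.
* **Method 3**: S_b = Σ counts over cells scoring ≥ t_b on the final
  corrected count map; N̂ = mean(S_b)/mean(ρ_b), with ρ_b = Σpredicted /
  Σobserved individuals on each iteration's omitted presence sites. The
  SEs entering the first-order ratio propagation are the bootstrap spreads
  sd_b(S) and sd_b(ρ) themselves: iterations re-use the same survey, so the
  spread of a bootstrap statistic estimates its sampling uncertainty, while
  spread/√B would merely measure Monte-Carlo error of the bootstrap mean
  and shrinks arbitrarily with B. (Method 2's Var_b(Â) follows the same
  principle.)

Biomass: B = N̂·w̄ (grams → tonnes), SE(B)² = N̂²SE(w̄)² + w̄²SE(N̂)².

## The synthetic seascape generator

The generator (`shellbed.seascape`) emulates the statistical structure the
analysis assumes, not any real coastline:

* Covariate fields are Gaussian-smoothed white noise (kernel width
  configurable) — the minimal mechanism for realistic spatial gradients.
  Depth trends upward with the in-offshore coordinate; exposure spans
  ~10^2.5–10^5 so the 10⁴ sheltered/exposed split is meaningful; substrate
  covers are zero-one-inflated with P_HARD + P_SOFT ≤ 1.
* Truth is a hurdle process: occurrence ~ Bernoulli(inverse-logit(η)),
  density where present lognormal around a log-linear predictor (σ = 0.6 to
  0.7 by species). The three default species land at prevalences ~0.16 to
  0.35 and mean present densities ~0.7 to 23 ind m⁻², the orders observed
  in shallow-coast bivalve surveys. The mussel analog's density depends
  strongly on hard-substrate cover — a patchy covariate uncorrelated with
  the depth strata — so a large share of within-stratum variance is
  covariate-driven, the regime the model-based estimator is built for.
  Occurrence coefficients are steep, so occupancy is close to deterministic
  given covariates: a sharp niche boundary is the regime in which
  delimiting habitat by a threshold (as Methods 2–3 assume) is a faithful
  description of the world. With very diffuse occupancy those estimators
  acquire an intrinsic selection bias (cells above the threshold are
  counted at full conditional density) that no calibration ratio can see.
* Surveys: counts are Poisson(density × sampled area) — the simplest
  observation model consistent with density = count/area; quadrats (1 m²,
  0–0.5 m band) shrink to 0.25 m² above 100 ind m⁻² (the switch density is
  a configurable guess); camera tows sample 16 m² at 0.5–10 m. Sites are
  allocated to the four estimation depth strata proportionally to stratum
  area (floor 25) and drawn uniformly within each stratum, keeping the
  design-based estimator unbiased and survey effort proportional to
  habitat — when sampling intensity is strongly disproportionate to area,
  the site-weighted calibration ratio of Method 3 stops matching the
  area-weighted map total and the estimator inherits that bias.

What passing tests therefore show: on data whose structure matches the
model family (smooth covariate response, sharp niche, Poisson counts,
correct stratification) the chain is consistent, its intervals cover, and
the model-based total is at least as accurate as mean extrapolation. What
they do not show: robustness to spatially correlated sampling, observer
error beyond Poisson noise, niche boundaries that drift along unmeasured
gradients, or mismatched strata — on real data those risks remain and the
reported SEs should be read as lower bounds.

## Problem sizes and numerics

Desk-scale defaults keep every stage exact but small: the recovery study
runs 50 replicates of a 200 × 200 grid (≈ 2.5 km² of marine cells), ~800
sites and B = 25; boosted trees default to 100–150 trees of depth 3,
learning rate 0.1 (substrate: 0.05 with early stopping, cap 2000). B = 100
is the pipeline default for real analyses. Ties in the maximum VIF remove
the later column (determinism); the prevalence threshold uses midpoint
tie-breaking; degenerate inputs (single-class folds, constant predictions,
empty strata, undefined ρ_b) are flagged and logged rather than raised
wherever a defined fallback exists. All randomness in a run derives from a
single seed; identical configurations reproduce byte-identical reports.

A finding worth stating plainly: on these synthetic seascapes both Method 1
and Method 3 are well calibrated (each covers the truth within ±2 reported
SE in ≥90% of replicates), but Method 3 is *not* more accurate in absolute
terms than the design-based Method 1 under a correctly stratified,
representative survey — its calibration ratio is a quotient of heavy-tailed
site sums and carries noise of the same order as the stratified means it
competes with. The practical advantage of the model-based total lies
elsewhere: it localizes abundance within strata (maps, habitat summaries)
and it does not inherit the inflation that mean extrapolation suffers when
sampling is not representative of a stratum. When survey effort is
disproportionate to habitat, the same non-representativeness also biases
the calibration ratio; Method 3 is no safer than its sites are
representative.

## Known limitations

* Rotation direction of the coordinate transform is configurable; +14°
  (counter-clockwise) is the default, and the sign convention matters only
  relative to the orientation of the input grid.
* The bootstrap is simple, not spatial: positive spatial autocorrelation
  between nearby sites makes OOB performance optimistic on real data.
* Method 2's independence assumption between density means and occupied
  area is optimistic when both derive from the same covariates.
* P_SOFT follows the "mud among mobile fractions" convention; the generator
  exposes the raw covers, so the alternative convention can be computed.
* GeoTIFF I/O is not implemented; raster stacks travel as .npz archives
  with a JSON sidecar naming bands and cell size.
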