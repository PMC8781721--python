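# Methods

## Scope and model

The package implements the classical response-surface-methodology chain for
small process-optimization studies: a rotatable central composite design
(CCD), per-response ordinary-least-squares fits of the full second-order
polynomial on coded factors, ANOVA with a replicate-based lack-of-fit test,
standardized-effect (Pareto) rankings, Derringer-style desirability
optimization across responses, and verification statistics. A bioassay
module reduces downstream assay data (linear calibration, inhibition
percentages, IC50, MIC/MBC), and a synthetic-data module generates inputs
with the statistical structure the analysis assumes.

The OLS machinery is delegated to statsmodels; distribution quantiles,
simple regression and curve fitting to scipy. What this package adds is the
domain layer: design construction and coding, the ANOVA partition with pure
error from replicates, the desirability search, and the assay decision
rules.

## Factor coding and the packaged study

Coded levels are always derived from the *actual real run levels* through
the factor axes (temperature center 52.5 °C, half-range 12.5 °C; ethanol
55 ± 25%; solid–liquid ratio 35 ± 15), not from the nominal ±1/±α grid.
For the packaged umbu-peel study the tabulated axial levels are rounded to
instrument precision (74 °C rather than the exact 73.52 °C of coded
+1.68179), so their derived coded values differ slightly from ±α (e.g.
+1.72 for temperature). Because the full quadratic model space is closed
under per-factor affine maps, fitted values and F statistics are identical
whether one regresses on real units or on these derived coded levels; we
fit on coded levels for numerical conditioning and interpretability of
coefficients. This convention — treating the rounded reported levels as
the levels actually run — is what reproduces the study's printed
whole-model F values digit for digit.

## ANOVA conventions

* Whole-model F = MS_model/MS_residual on (p − 1, n − p) df; upper-tail p.
* Pure error pools within-group variation over runs with identical coded
  coordinates (for a CCD, the center replicates); lack of fit is the
  remaining residual variation. Lack of fit is declared non-significant
  iff its p-value exceeds the significance level (default 0.05).
* Coefficient standard errors use the residual mean square of the full
  model (df 7 in the packaged study), not pure-error MS: this is the
  conventional whole-model basis for the Pareto t-values.
* The full 10-term model is always fit; no term selection. Fewer runs than
  terms plus one raises an error rather than silently dropping terms.
* A constant response is reported with R² = 1 and model F = 0 (the
  intercept fits it exactly).

## Desirability optimization

* Default anchors per response: observed minimum (d = 0) and maximum
  (d = 1) over the design runs, linear ramp (s = 1), values clipped into
  [0, 1]. Overall D is the geometric mean; any d = 0 annihilates it.
* Default search region: the box spanned per factor by the design's
  derived coded levels (the region actually explored experimentally).
  A cube, or any explicit box, can be passed instead. On the packaged
  study this region — together with the coding convention above — is what
  reproduces the reported optimum (74 °C, 37% ethanol, 1:38), D = 0.97 and
  all five predicted responses to the printed integer.
* Search: exhaustive vectorized grid at step 0.02 coded units, then a
  shrinking-step coordinate polish to 1e-4. The quadratic D-surface in
  three factors is cheap to enumerate, so the global stage is genuinely
  exhaustive; the polish only sharpens the final digits. Ties between
  equal-D nodes (possible on clipped plateaus) resolve to the smallest
  coded coordinates in factor order, i.e. the lowest temperature, then the
  weakest solvent, then the least solvent volume — the cheapest setting.
* Per-factor 1-D traces of D through the optimum are emitted as the
  numeric equivalent of a desirability profile plot.

## Validation statistics

* Fold-range = max/min of a response over the design, reported at 2
  significant figures.
* Observed-vs-predicted agreement at the optimum is the coefficient of
  variation of the pair: 100·(|o − p|/√2)/((o + p)/2). This two-value
  sample CV is the definition under which all five packaged verification
  pairs fall below the customary 7% bar; replicate-based CVs would need
  raw replicate values, which the packaged study does not carry.

## Bioassay reductions

* Calibration is fit as absorbance-on-concentration and inverted
  (classical calibration); back-calculated concentrations outside the
  standards' range trigger a warning, not an error.
* Inhibition percentages are returned unclipped so the raw reduction is
  preserved; out-of-[0, 100] values warn.
* IC50 defaults to linear interpolation in concentration between the two
  adjacent doses bracketing 50% (first upward crossing), which suits the
  short dose ladders of plate assays; the log-logistic fit (≥ 4 doses) is
  for richer series. Data never crossing 50% raise a not-estimable error
  naming the achievable range.
* MIC: lowest concentration with no visible growth. All-growth plates
  return a not-detected sentinel; no-growth-anywhere plates return the
  lowest tested concentration flagged left-censored rather than exact.
  MBC/MFC apply the same rule to subculture readings.

## Synthetic data

The CCD generator draws y = x'β_true + ε with i.i.d. homoscedastic
Gaussian ε — the minimal error model consistent with the scatter of
replicated center points; heteroscedastic or correlated errors are out of
scope, so passing recovery tests say nothing about those failure modes.
The dose-response generator is an exact log-logistic curve plus Gaussian
noise clipped to [−10, 110]; the microdilution generator is deterministic
(growth strictly below the true MIC). All generators are pure functions of
their arguments including the seed.

Default simulation scales used by the test suite: noise sd 50 on a
realistic phenolics-scale surface with 1000 replicates for the 95%
confidence-interval coverage check (band 93–97%), and noise sd 3 with 100
replicates for IC50 recovery (median error under 15%). These sizes keep
Monte-Carlo error well inside the asserted bands while the whole suite
runs in well under a minute per property.

## Known limitations

* Only rotatable CCDs are constructed (no face-centered, Box–Behnken,
  orthogonal-α or blocked designs).
* No ridge/robust regression, response transformation or term selection;
  no formal prediction intervals at the optimum.
* Desirability supports maximize/minimize/target goals with power ramps
  but not importance weights or Pareto-front methods.
* One printed whole-model F value of the packaged study (FRAP, 7.08) is
  not reproduced by its own data, which yield 7.80 under the convention
  that matches the other four responses exactly; the two agree up to a
  digit transposition and the discrepancy is surfaced, not hidden, in the
  test suite.
* The metabolite annotation table ships as static metadata only; no
  mass-spectrometry processing is implemented.
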