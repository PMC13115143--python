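# Methods

## The model

`freshlabel` implements the inference chain behind colorimetric
("intelligent-label") shelf-life monitoring of shrimp, in which spoilage
is tracked by total volatile basic nitrogen (TVB-N, mg/100 g) and read
out through the color change of a pH-sensitive anthocyanin label.

**First-order spoilage kinetics.** TVB-N accumulates approximately
exponentially during isothermal storage:

    A(t) = A0 · exp(k(T) · t)

The rate constant at each storage temperature is estimated by ordinary
least squares of ln A on t (log-linear OLS). Replicates enter as
individual observations rather than time-point means: for a balanced
design this leaves the point estimate unchanged while preserving the
error structure. R² is reported on the ln-scale regression. A nonlinear
least-squares alternative is deliberately not the default: the log-linear
fit is the field's standard, is exactly specified under the generator's
multiplicative noise, and is the estimator whose outputs feed the
Arrhenius step.

**Arrhenius temperature law.** Rates across temperatures follow
k(T) = k0·exp(−Ea/(R·T)); OLS of ln k on 1/T (kelvin, T = °C + 273.15)
gives the slope −Ea/R and intercept ln k0, with R = 8.314 J/(mol·K).
The kelvin offset 273.15 (not 273) matters: only with 273.15 do the
published validation-table predictions reproduce.

**Remaining shelf-life.** With a spoilage threshold of 30 mg/100 g,

    t_RSL = (ln 30 − ln A) / k(T)

signed: negative once A exceeds the threshold, and the `spoiled` flag is
exactly `remaining_h <= 0`.

**Label calibration.** Label color difference ΔE (CIE76 Euclidean
distance between CIELAB triples) is linearly related to TVB-N,
`tvbn = slope·ΔE + intercept`, fitted by OLS. Composing the calibration
with the shelf-life formula yields the label-based predictor,
`predict_from_label`, which is enforced (and property-tested) to be the
exact composition `remaining_shelf_life ∘ tvbn_from_delta_e`.

## Published-constant preset vs fitted mode

`ShelfLifeModel.published()` carries the study's printed constants
verbatim: k0 = 1.7×10⁹ h⁻¹, exponent −7091.4/T, numerator constant
3.401, calibration 1.43·ΔE + 0.6. Two deliberate quirks:

- The numerator uses the printed rounded 3.401, not ln 30 = 3.40120…;
  the full-precision value changes one tabulated prediction (25.9 →
  26.0 h at 4 °C, ΔE 14.5), so reproducing the published table requires
  the printed constant.
- k0 is 1.7×10⁹ exactly, not exp(21.23) ≈ 1.66×10⁹.

`ShelfLifeModel.from_arrhenius()` is the fitted mode: constants from the
data, full-precision ln(threshold).

Two published validation rows — (10 °C, ΔE 11.3) and (20 °C, ΔE 9.4) —
do not follow from the printed constants (direct evaluation gives 25.8
and 14.3 h vs the printed 26.3 and 14.7). The printed rate constants
likewise do not yield the printed regression line (OLS on the five
rounded k values gives slope ≈ −6988, intercept ≈ 20.93): the original
fit evidently used unrounded intermediates. The package treats the
printed constants as authoritative inputs, never tunes toward the
irreproducible rows, and the tests document the discrepancy rather than
patch it.

## Error metrics and table construction

RE = |pred − obs|/obs × 100%; MAE and RMSE are grouped by exact
temperature equality. For published-table reproduction, predictions are
rounded to 0.1 h *before* computing MAE/RMSE — full-precision
predictions give 4.07/4.43 h at 4 °C instead of the tabulated 4.03/4.40,
so the rounding step is explicit in `build_validation_table`
(`round_to=0.1`, pass `None` for full precision).

## Synthetic data generator

`SimulationConfig` defaults encode the study conditions: Ea = 58 958
J/mol, k0 = 1.7×10⁹ h⁻¹, A0 = 1.39 mg/100 g with between-replicate SD
0.06 (truncated below at 0.5, a plumbing bound), storage at 0/4/12/20/28
°C with the study's sampling schedules (e.g. 20 °C: 0–42 h every 6 h),
three replicates, calibration slope/intercept 1.43/0.6.

Design choices:

- **Noise model**: multiplicative lognormal on TVB-N, σ_ln = 0.05.
  This keeps values positive and makes the log-linear OLS correctly
  specified, so zero-noise recovery is exact and noisy recovery is
  provably consistent. The 5% level is a realistic repeatability for
  micro-diffusion TVB-N assays.
- **Color path**: label color moves along one fixed unit direction in
  Lab space (darker, less red, more yellow), with per-channel Gaussian
  colorimeter noise (SD 0.3). Real labels trace a curved
  red→blue→yellow path; only the scalar ΔE enters the analysis, so a
  straight path is sufficient and this simplification is intentional.
- **ΔE reference**: the generator anchors the color coupling to the
  calibration line's zero point (TVB-N = intercept ⇒ color = fresh
  baseline). Because A0 (1.39) exceeds the calibration intercept (0.6),
  a label deployed at t = 0 already sits ~0.55 ΔE from that zero point,
  so two reference conventions exist and differ by a per-series
  constant: measurement against the fixed fresh baseline (recovers the
  calibration intercept exactly) and against the label's own t = 0
  reading (the only reference available from colorimeter data; recovers
  intercept ≈ A0). `delta_e_series` uses the t = 0 convention;
  `make_validation_design(reference=...)` supports both, defaulting to
  the baseline convention. Whichever convention is used, it must be used
  consistently for calibration and prediction — the pipeline tests
  demonstrate exact self-consistency under the t0 convention.
- **Observed shelf-life**: the validation design defines the observed
  remaining shelf-life as the threshold-crossing time of the noiseless
  true trajectory minus the sampling time. The original experiment's
  measurement procedure for "observed" values is not something the
  generator can emulate, so the published observed values are treated as
  fixture inputs when reproducing the published table, and simulated
  designs are judged on self-consistency instead.
- **Photobleaching**: first-order pigment decay c(t) = c0·exp(−kp·t)
  sampled at 0/6/12/24 h of UV exposure; the default rates 0.1723 h⁻¹
  (unshielded) and 0.0412 h⁻¹ (UV-shielded) are the closed-form rates
  that reach the two published 24 h degradation percentages (98.4% and
  62.8%) in the noiseless limit.

What passing tests show — and do not show — about real data: the
generator's trajectories are exactly first-order with Arrhenius rates,
so parameter-recovery results validate the estimators, not the kinetic
model itself; real shrimp exhibit lag phases, replicate drift, and
temperature-dependent calibration that the generator omits.

## Numerical choices and degenerate inputs

- OLS is delegated to `scipy.stats.linregress`; tests pin it to the
  closed-form covariance/variance slope at 1e−12.
- A constant TVB-N series returns a degenerate fit (k = 0, R² = NaN,
  `degenerate=True`) instead of raising; degenerate fits are excluded
  from the Arrhenius regression, which requires ≥ 3 distinct
  temperatures with k > 0.
- Fewer than 3 distinct time points, mixed temperatures in one series,
  non-positive TVB-N, constant ΔE in calibration, and non-positive
  observed shelf-life are all hard errors.
- Lab lightness is clamped to [0, 100] in the generator; ΔE inversion is
  clamped at 0 for TVB-N below the calibration intercept.
- Seeded streams: all generator randomness derives from
  `numpy.random.default_rng([seed, stream])` with separate stream
  indices for TVB-N noise, color noise, photobleaching and validation
  designs, so outputs are bit-reproducible per seed.

## Problem sizes

Stochastic checks use 100 simulated studies (each: 5 temperatures ×
7–11 time points × 3 replicates) for activation-energy recovery, and
40-seed sweeps for validation-design accuracy; these sizes give stable
medians while keeping the default suite fast.

## Known limitations

- Isothermal only: no temperature-history integration of the shelf-life
  formula.
- The ΔE–TVB-N calibration is assumed temperature-independent, as in
  the source model; the fitted mode inherits that assumption.
- No uncertainty intervals on predictions; the validation metrics (RE,
  MAE, RMSE) are the only accuracy statements.
- CIE76 only; CIEDE2000 and device/illuminant color management are out
  of scope.
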