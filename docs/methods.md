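# Methods

This note records the statistical model behind `procal`, the defaults it
ships, and the design choices made where more than one defensible option
existed.

## Indirect calibration model

The detector is assumed linear in concentration over the working range:
R = S·c (+ b). Oligomer slopes are expressed relative to epicatechin,
RRF_dp = S_dp/S_epi, and samples are quantified as
c = R/(S_epi·RRF_dp), content = c·V·D/m. The model assumes (i) the
response per dp class is already summed over its structural isomers
before entering the pipeline — peak detection and integration are out of
scope; (ii) RRFs are method-specific constants: fluorescence response
depends on the mobile-phase composition at elution, so a table determined
on one chromatographic method must not be reused on another.

### Calibration fitting and zero-forcing

Each (analyte, day, lab) series is fitted by ordinary least squares
(unweighted; the calibration designs this package targets are
homoscedastic enough over 5–100 μg/mL that weighting buys little and
complicates the σ used for LOQ). The residual standard deviation carries
n−2 degrees of freedom, or n−1 for the forced-zero estimator
S = Σxy/Σx².

Forcing through the origin is decided by a two-sided t-test of the free
intercept against its standard error at α = 0.05: forcing is allowed
when the intercept is indistinguishable from zero. A cruder screen
(|b| vs the regression standard error) is computed and logged alongside
for traceability, but the t-test is the operative rule — it is the
statistically defensible formalisation of the same intent (reducing
relative error at the low end of the range). When a fit is exact to
machine precision the intercept is compared against a 1e−8·max(1, S)
round-off threshold instead.

### Lack of fit

Linearity is tested by partitioning the residual sum of squares about
the fitted line into pure error (replicate scatter within levels) and
lack of fit (level means about the line); F = MS_lof/MS_pe on
(m − p, n − m) degrees of freedom, p = 2 (or 1 when forced through
zero), α = 0.05. The test refuses to run without replicated levels or
with fewer levels than parameters + 1 — an explicit error, never a
silent pass.

### LOQ

LOQ = 10σ/S, with σ the residual standard deviation of the calibration
fit (the formula's "standard deviation of the response" is not further
specified; the residual SD is the estimate actually available from the
fit and is logged per series). A separate reporting policy clamps the
LOQ up to the lowest calibration level used for the analyte's RRF —
with samples far above the theoretical LOQ there is no benefit in
claiming sensitivity below the lowest standard run. The shipped ladder
is 5 μg/mL (epicatechin, dp2–dp5), 10 (dp6), 25 (dp7–dp9), 50 (dp10).

## RRF determination

Daily RRFs are ratios of same-day slopes; the reported value is the
arithmetic mean of the daily ratios ("mean of means") with the n−1 RSD
as its between-day dispersion. Pooling all days into one regression per
analyte is also possible; the mean-of-daily convention is the default
because it matches how the dispersion that feeds the uncertainty budget
is defined (RSD of daily values), keeping the point estimate and its
uncertainty on the same footing. Between-lab dispersion u_il(RRF) is
the RSD of lab means; within-lab u_rep(RRF) pools the per-lab RSDs as a
root mean square. RRF lookup never interpolates across dp — the entire
point of per-dp factors is that response per unit mass is not a smooth
knob one may borrow from a neighbouring oligomer.

The between-day RSDs shipped with the reference RRF table are labelled
as computed across daily means; a variant including within-day replicate
spread can be derived from the calibration table directly. Both are
exposed because the convention behind published RRF RSDs is often left
implicit.

## Precision, recovery, bias

One-way (day) ANOVA: s_r² = MS_within; day component
s_d² = max(0, (MS_between − MS_within)/ñ) with ñ the harmonic-mean
replicates per day (exact for balanced layouts); s_ip² = s_r² + s_d².
The truncation at zero is the standard restricted estimator and explains
validation tables where intermediate RSD prints below repeatability RSD:
when day means scatter less than replicate noise predicts, the day
component estimate goes negative and is clamped.

Recovery: per-replicate recovery = 100·(found − mean(unspiked))/added,
averaged over all fortification levels and replicates; u_rec is the SD
of those individual recoveries pooled across levels — deliberately
level-agnostic and conservative. A single-level call gives the
one-point-spike variant.

Control-material bias: u_bias combines, in quadrature, the relative
deviation of the measured mean from the certified value and the
certificate's own relative uncertainty. Where the control material is
analysed defatted, the certified whole-matrix value divides by the
defatted mass fraction first (`to_defatted_basis`).

## Expanded uncertainty

U = k·√(u_rep(RRF)² + u_il(RRF)² + u_r²/n₁ + u_ip²/n₂ + u_bias² +
u_rec²), k = 2 (≈95 % coverage). Every component enters as a percent
relative standard uncertainty; mixing absolute and relative units is
rejected at construction. n₁ (total analyses) and n₂ (days) are required
inputs — they are design choices of the measurement campaign, not
constants of the method. Best-case and worst-case budgets are simply two
evaluations of the same formula under two component sets.

## Stability

For a storage series the reported quantities are delta = value(last) −
value(0 h) and an acceptance half-width = (mean over all timepoints) ×
the analyte's intermediate-precision fraction. The `stable` flag
(|delta| ≤ half-width) is advisory: a delta slightly outside one
intermediate-precision band is a trend worth inspecting, not an
automatic failure, so both numbers are always reported and the flag
never gates a pipeline run.

## Inter-laboratory evaluation

Consensus statistics are the arithmetic mean and n−1 SD of lab means
(this is the convention that reproduces the shipped seven-lab summary
rows); a median/MAD variant is provided but off by default. z-scores use
the same consensus mean and SD, classified |z| ≤ 2 satisfactory,
2 < |z| < 3 doubtful, |z| ≥ 3 unsatisfactory. Centered scores sum to
zero with sample SD 1 by construction, so a z-table is a shape summary,
not extra information beyond the lab values.

The control-sample QC gate scores each laboratory against the
*leave-one-out* consensus of the remaining labs (a Grubbs-style
jackknife z) with a |z| > 3 default policy. Leaving the scored lab out
is essential: with n labs the classical all-in |z| is bounded by
(n−1)/√n — below 3 for any n ≤ 10 — so a gross outlier inflates the SD
enough to mask itself and a plain-SD gate could never fire in a small
round robin. The jackknife also masks inliers (the outlier inflates
every other lab's denominator), so a single planted outlier is excluded
and nothing else is. Exclusion is one round: offenders are removed, the
consensus recomputed once, and the gate stops.

## Synthetic-data generator

The generator emulates the structure the analysis assumes:

- response = c · S_epi · RRF_dp · lab multiplier · day multiplier ·
  (1 + ε), ε ~ N(0, noise_cv). Noise is multiplicative because measured
  dispersions are %RSDs, which are scale-relative. Negative responses
  (unreachable at realistic CVs) are truncated to zero and logged.
- The **lab multiplier is common-mode**: one log-normal (mean-1) draw per
  lab shared by all analytes, modelling detector gain / injection /
  path-length differences. It cancels in same-lab slope ratios, which is
  what makes RRF tables transferable between laboratories in the first
  place. **Day multipliers are per-analyte**, modelling mobile-phase
  sensitivity of each oligomer's fluorescence; they give daily RRFs a
  few-percent spread comparable to reference between-day RSDs.
- Sample, spiking and stability generators push true contents (mg/g)
  through the inverse of the quantification formula, so noise-free
  generation composed with quantification is the identity to machine
  precision — the pipeline's core invariant.
- Optional adsorption loss multiplies the concentration by
  (1 − coeff·surface) per analyte before response generation, emulating
  the loss of oligomers to glass surfaces during serial dilution. No
  published coefficient exists, so the default is 0 and the parameter is
  a scenario knob, not a calibrated constant.

Defaults (chosen once as a realistic rendering of the validation
design): S_epi = 20 response units per μg/mL (arbitrary detector scale —
quantification is invariant to it), 8 levels over 5–100 μg/mL,
3 replicates/level, 3 days, 1 lab, noise_cv = 0.02, day_effect_cv =
0.02, lab_effect_cv = 0.05; true RRFs are the shipped reference table.
The default sample profile is the procyanidin-rich extract composition
of the shipped stability series.

What the generator does **not** emulate: chromatographic artifacts
(co-elution, integration error, retention drift), detector saturation,
carry-over, heteroscedasticity beyond proportional noise, and
correlations between analytes within an injection beyond the shared day
multiplier. Passing tests therefore demonstrate correctness of the
statistical pipeline under its stated model, not robustness of the
analytical chemistry to those artifacts.

## Numerical and policy choices

- α = 0.05 for the intercept and lack-of-fit tests.
- Below-LOQ results are flagged, retained in per-analyte output, and
  excluded from class totals (logged each time).
- Variance components truncate at zero; pure-error mean squares of zero
  make the lack-of-fit test error out rather than divide by zero.
- Report rounding: one decimal for mg/g and %RSD, two for z-scores.
- CSV everywhere: UTF-8, header row, "." decimals; a decimal comma is
  rejected with a remediation hint rather than silently misparsed.
- Problem sizes in the test suite and acceptance script (e.g. 20
  replicate simulations for Monte-Carlo standard errors, 200 days × 10
  replicates for variance-component recovery, 100 seeds for the
  planted-outlier screen) were sized to make the statistical assertions
  sharp at interactive runtimes.

## Known limitations

- The monomer class is quantified as a single pool; catechin and
  epicatechin are not resolved by the underlying separation.
- Published per-analyte z-score tables cannot be reconstructed from
  published per-lab class totals (per-dp lab values are not public);
  the z-score implementation follows the formula exactly and is
  verified by its algebraic properties instead.
- The uncertainty budget covers the six listed components only; no
  bottom-up GUM treatment of balances and volumetrics is attempted.
- Single-lab simulations cannot inform u_il(RRF); between-lab terms
  require at least two lab tables, and the estimator errors out rather
  than report a vacuous zero.
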