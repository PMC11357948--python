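# Methods

## Model

Total height at age `t` (decimal years since birth) is `T(t) = QES(t) + P(t)`
with `QES = E + Q_stopped`. The model clock starts `c0` years before birth
(`t0`, about six weeks after conception), so model time is `t + c0`.

**E (infancy).** `E(t) = Emax · (1 − exp(−(t + c0)/(thetaE · Etsc)))`.
A saturating exponential: with the defaults it has passed 95% of its
plateau before age 2.

**P (pubertal spurt).** A Richards sigmoid in normalized time
`u = (t − AgeP50)/Ptsc`:

    p(t) = (1 + exp(−(k·u + w50)))^(−nu),     w50 = −ln(0.5^(−1/nu) − 1)

shifted so that `p(AgeP50) = 0.5` exactly for any asymmetry `nu`, and
`P(t) = Pmax · p(t)`. The steepness `k` is not free: it is calibrated so
that the gap between 50% and 5% of the spurt is `p50_p5_gap` years at unit
time scale. The inverse `age_at_p_fraction` is closed-form, which makes
milestone extraction (`AgeP5`, `AgeP95`, `AgeP99`, `AgeP100`) exact; tests
nevertheless verify it against a dense-grid oracle. The age of peak
P-velocity sits at fraction `(nu/(nu+1))^nu` of the spurt — before
`AgeP50` whenever `nu > 1`, which reproduces the observed ordering
AgeT_PHV < AgeP_PHV < AgeP50 in cohort-typical parameters.

**Q and S (basic growth and stop).** Un-stopped Q velocity declines
linearly from `t0` to zero at age `tQ`; the height scale is normalized so
the un-braked plateau equals `Qmax`. The stop multiplies Q velocity by
`1 − S(t)` with `S` a unit sigmoid of width `sS` centred at `AgeP100`, tying
growth cessation to completion of the spurt. The stopped-Q height — the
integral of a linear velocity times a sigmoid — has a closed form in the
softplus and dilogarithm functions (`scipy.special.spence`), evaluated with
a large-argument inversion branch for stability; tests compare it with
adaptive quadrature to ~1e−8 cm.

**AgeT_PHV.** Height velocity declines monotonically from infancy, so the
pubertal peak of total velocity is an interior local maximum. It is located
on a fine grid over the pubertal window and refined by bounded scalar
minimisation; when no interior peak exists (negligible `Pmax`) the value is
NaN, mirroring subjects without a detectable total-curve PHV.

### Shape constants (shared across subjects)

| constant | default | units | role |
|---|---|---|---|
| `c0` | 0.65 | y | prenatal offset of the model clock |
| `thetaE` | 0.6 | y | E saturation scale (plateau before age 2) |
| `tQ` | 17.0 | y | age where un-stopped Q velocity reaches zero |
| `nu` | 1.3 | – | P asymmetry; >1 puts PHV before AgeP50 |
| `sS` | 0.5 | y | width of the stop sigmoid |
| `pEnd` | 0.999 | – | fraction operationalizing "AgeP100" |
| `p50_p5_gap` | 2.22 | y | AgeP50−AgeP5 gap calibrating k |

`tQ = 17` was chosen so that cohort-mean basic pubertal gain (QESpubgain)
lands near 16 cm, the scale observed in the reference cohort; `pEnd = 0.999`
makes `Ppubgain` capture ≥ 85% of `Pmax` (an asymptotic sigmoid needs a
cutoff for "100%"). The sum `Emax + Qmax + Pmax` of cohort-mean height
scales deliberately exceeds mean adult height; how stop-losses are
attributed among the printed "gain due to" scales is left open, and `Qmax`
here is defined as the un-braked plateau.

## Per-subject fitting

Ordinary (unweighted) least squares on height in cm — the simplest
defensible criterion; a weighting hook remains in the config. The model is
linear in `(Emax, Qmax, Pmax)` at fixed `(Etsc, Ptsc, AgeP50)`, so a coarse
grid over `AgeP50 × Ptsc` (0.5 y × {0.7, 1.0, 1.4}) with a non-negative
linear solve per node seeds ≥ 5 jittered starts of bounded
trust-region-reflective least squares (height scales in [0, 200] cm, time
scales in [0.5, 2], AgeP50 in [7, 17]); the best-loss start wins. Jitter is
seeded (default 1990) and fits are deterministic given the seed and
invariant to measurement order.

Preconditions: ≥ 8 distinct measurements spanning [2, 15] y with ≥ 2 after
13 y (all configurable). QC drops exact duplicate rows and rejects —
without auto-fixing — series shrinking > 1 cm between consecutive visits;
with 0.3 cm noise this rejects just under 1% of synthetic subjects, almost
always from noise at the adult plateau.

Identifiability: for the default 23-visit schedule at 0.3 cm noise, the
Cramér–Rao bound gives sd(AgeP50̂) ≈ 0.068 y; the estimator attains
≈ 0.064 y with negligible bias, i.e. it is essentially efficient. Tests of
single-subject recovery are therefore framed against the information bound
of the design, while cohort-mean recovery (n = 793) is tested at ±0.05 y.

## Derived variables

Menarcheal age is imputed by report completeness: year+month → exact date
arithmetic to day 15 of the month; year only → July 2; year+stated age →
midpoint of the overlap between the stated year of life and the calendar
year; age only → reported age + 0.193 y (a constant estimated in the source
cohort from dual reporters; it is a fixed rule here, not re-derivable).
Decimal ages use days/365.25. Imputed ages outside [6, 20] y or years
before birth are errors, not silently clamped.

`BMI_max` is the maximum of weight/height² over ages [3.5, 7.0], both ends
inclusive. Midparental height (MPH) is the mean of the parents' height SDS,
with missing parents propagating to every MPH-dependent variable
(complete-case analysis preserves the variable-specific n). Adult height is
`max(Tmax, tallest measurement)`. SDS transforms accept pluggable
age–mean–SD reference tables with linear interpolation and no
extrapolation; the shipped default is cohort-internal (age-free)
standardization, since national reference tables are not redistributable.
Negative postmenarcheal gain — possible as a curve-fit artifact — is
floored at 0 with a warning.

## Regression layer

All association and outcome variables are standardized by their own cohort
SD, so univariable slopes equal Pearson correlations and betas are
comparable. Univariable scans are complete-case per pair and Holm-adjusted
(statsmodels' step-down implementation behind the `holm_adjust` surface).
Multivariable models per clinical milestone use forward/backward stepwise
selection with entry and removal alphas both 0.05 (the significance
convention; thresholds are not otherwise dictated), deterministic
tie-breaks (smallest p, then largest |t|, then name), and report model R²
plus partial R² = (SSE_without − SSE_with)/SSE_without by refitting.
Perfectly collinear candidates — which genuinely arise here, e.g. MPH is
exactly the parental mean and AgeP_PHV is affine in AgeP50 and AgeP5 under
the closed-form model — are dropped later-name-first with a warning.
Candidate sets accumulate across milestones, so explained variance is
non-decreasing on a fixed cohort. For the secondary outcome
(postmenarcheal gain) a multivariable model is only attempted when more
than one variable survives Holm adjustment.

## Synthetic cohort

The generator emulates the study conditions: n = 793 term-born girls;
QEPS parameters drawn from a truncated multivariate normal with published
marginal means/SDs (AgeP50 11.98 (1.00), Etsc 0.99 (0.09), Emax 62.76
(2.83), Qmax 98.51 (7.83), Pmax 12.92 (3.58); Ptsc 1.00 (0.09) so that mean
true AgeP5 = 11.98 − 2.22 = 9.76); visit schedule with seven infancy visits
and annual school-age visits jittered ±0.15 y; 0.3 cm Gaussian height
noise; menarche linked to growth by drawing the achieved P-fraction from
Normal(0.716, 0.188) truncated to (0.02, 0.995) and inverting the subject's
own sigmoid (an age-linked null mode exists); questionnaire reports
degraded to the four completeness modes in the published 285:38:103:367
split; parental heights at 167.19 (6.01) and 181.41 (6.66) cm with 17/793
mothers and 42/793 fathers missing.

Assumptions where no published value exists (labelled as such in the run
manifest): between-parameter correlations default to corr(AgeP50, Ptsc)=0.3
and corr(Qmax, Emax)=0.2, parent–daughter height correlation 0.45 each
(typical familial height correlation), childhood BMI follows a per-subject
parabola around an adiposity rebound at 5.5 (0.8) y with its level
correlated −0.25 with AgeP50, continued linearly after age 8. Note the
prescribed truncation of the menarche P-fraction cuts the upper tail 1.5 SD
above the mean, so the truncated mean is ≈ 0.686 rather than the location
parameter 0.716; tests check the sample mean against the analytic
truncated-normal expectation.

What the generator does **not** emulate: secular trends, ethnic or
socioeconomic heterogeneity, measurement error correlated within observers,
register linkage artifacts, informative missingness, or real covariance
structure among growth parameters. Passing tests therefore demonstrate that
the pipeline is correct and well calibrated under these idealized
conditions, not that effect sizes from real register data would be
reproduced; in particular the headline explained-variance figures of the
reference analysis depend on the restricted cohort and are out of scope.

## Problem sizes and budgets

The test suite runs the full 793-subject generate→render→refit loop once
(seed 1990, ≈ 1 min) and shares it across tests; single-subject recovery
uses 100 noise replicates; stepwise-selection sensitivity uses 20–100
replicates at n = 500–793. The acceptance script performs one full cohort
loop (~1 min).

## Known limitations

- The concrete Q/E/P/S functional forms are this package's own design; the
  original model's population shape functions and six-parameter
  normalization are unpublished, so parameter values are comparable in
  role, not bit-for-bit.
- Cohort-internal SDS differs from national references; SDS-valued
  variables are only defined up to that choice of reference.
- The stepwise procedure inherits the usual caveats of p-value-driven
  selection (post-selection inference is not corrected).
- `year_age` imputation uses the overlap-midpoint reading of "the remaining
  part of the written year at the stated age"; other readings are possible.
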