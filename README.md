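# qeps-puberty

Analysis of pubertal growth and menarche timing with the QEPS growth model,
for researchers in auxology and pediatric epidemiology who want to relate
growth milestones of girls — pubertal onset, midpuberty, peak height
velocity — to menarcheal age and postmenarcheal height gain from sparse
longitudinal height measurements.

## The model

Height-for-age of an individual is decomposed into four functions:

- **Q** (basic): growth from early fetal life with linearly declining
  velocity, halted at the end of puberty by a smooth multiplicative **S**
  stop sigmoid;
- **E** (infancy): a saturating exponential that plateaus around 2 years;
- **P** (puberty): a Richards-type sigmoid capturing the specific pubertal
  spurt, with `QES = E + stopped Q` and total growth `T = QES + P`.

Six individual parameters modify shared shape constants: three height
scales (`Emax`, `Qmax`, `Pmax`, cm), two time scales (`Etsc`, `Ptsc`), and
the midpubertal age `AgeP50`. Because `P` is a normalized sigmoid, every
milestone age — `AgeP5` (pubertal onset, 5% of the spurt), `AgeP50`
(midpuberty), `AgeP95`/`AgeP100` (end of puberty) — is obtained by closed
form inversion, and the achieved spurt percentage at menarche (`P%`), the
pubertal gains (`Tpubgain = Ppubgain + QESpubgain`), and postmenarcheal
height gain follow directly.

The package provides:

- `QEPSGrowthCurve` — a scikit-learn style regressor fitting the six
  parameters per subject by coarse-grid presearch plus bounded multi-start
  nonlinear least squares;
- derived-variable computation — menarcheal-age imputation from
  questionnaire reports of four completeness levels, midparental height,
  childhood `BMI_max`, SDS transforms, milestone sets;
- milestone-wise regression — standardized betas, Holm-adjusted
  univariable scans, forward/backward stepwise models per clinical
  milestone (birth, age 7, pubertal onset, midpuberty) with partial R²;
- a calibrated synthetic-cohort generator (793 term-born girls by default)
  linking menarche to the achieved P-fraction, so the full pipeline is
  testable without access to restricted register data.

## Worked example

Fit one synthetic subject and extract her milestone variables:

```python
from qeps_puberty import (ShapeConstants, GeneratorConfig, generate_cohort,
                          QEPSGrowthCurve, compute_milestones)

consts = ShapeConstants()
measurements, metadata, truth = generate_cohort(
    GeneratorConfig(n_subjects=3, seed=42), consts, seed=42)
sub = measurements[measurements["subject_id"] == "S0000"]

est = QEPSGrowthCurve(consts=consts, seed=42)
est.fit(sub["age_years"], sub["height_cm"])
ms = compute_milestones(est.params_, consts, age_menarche=13.0,
                        measured_heights=sub["height_cm"])
```

which prints (via the obvious f-strings):

```
fitted params: AgeP50=12.98 y, Pmax=9.3 cm, rmse=0.18 cm
pubertal onset (AgeP5):   11.00 y at 154.6 cm
peak height velocity:     12.70 y (total), 12.91 y (P-function)
pubertal gain:            20.5 cm total = 8.9 (P) + 11.6 (QES)
P% at menarche (13.0 y):  50.8%
postmenarcheal gain:      9.8 cm
```

The fit recovered a late-maturing girl (`AgeP50` = 13.0 y vs the cohort
mean of 12.0): her spurt contributes 8.9 cm of the 20.5 cm grown between
pubertal onset and completion, menarche at 13.0 y falls almost exactly at
midpuberty (51% of the spurt achieved), and she has 9.8 cm of growth left
after menarche. The residual scatter of 0.18 cm matches the 0.3 cm
measurement noise, given ~23 visits and 6 parameters.

The same stages run from the shell:

```bash
qeps-puberty simulate --seed 1990 --out cohort/
qeps-puberty fit --measurements cohort/measurements.csv --out cohort/fits.csv
qeps-puberty derive --measurements cohort/measurements.csv \
    --metadata cohort/metadata.csv --fits cohort/fits.csv \
    --out cohort/derived.csv
qeps-puberty regress --table cohort/derived.csv --outcome age_menarche \
    --out cohort/reports/
qeps-puberty run --seed 1990 --out run_out/   # everything, with a manifest
```

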