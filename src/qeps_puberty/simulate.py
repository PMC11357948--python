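"""Synthetic cohort generator.

Emulates a community cohort of term-born girls with longitudinal height and
weight measurements from well-baby clinics and school health records, a
recalled menarche report of varying completeness, parental heights, and
birth-register variables.  Marginal distributions default to the published
summaries of the reference cohort (n = 793); the full covariance between
growth parameters is not published, so the default correlation structure is
a documented assumption.

Menarche is linked to growth by drawing the achieved fraction of the
specific pubertal P-function at menarche and inverting it to an age, so the
coupling between pubertal maturation and menarche timing is built into the
generated data; an age-linked mode exists for null testing.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .model import (
    QEPSParams,
    ShapeConstants,
    age_at_p_fraction,
    age_at_p_velocity_peak,
    total_height,
)

__all__ = [
    "GeneratorConfig",
    "draw_parameters",
    "render_measurements",
    "draw_menarche",
    "generate_cohort",
]

_PARAM_ORDER = ("Emax", "Qmax", "Pmax", "Etsc", "Ptsc", "AgeP50")


@dataclass
class GeneratorConfig:
    """Study-condition settings for the synthetic cohort.

    Defaults reproduce the reference cohort's published marginals: parameter
    means/SDs, 0.3 cm measurement noise, the achieved-P-fraction menarche
    model (mean 71.6%, SD 18.8%), the 285:38:103:367 split of menarche
    report modes, and parental height distributions.
    """

    n_subjects: int = 793
    seed: int = 1990
    # QEPS parameter marginals, order Emax, Qmax, Pmax, Etsc, Ptsc, AgeP50
    param_means: tuple = (62.76, 98.51, 12.92, 0.99, 1.00, 11.98)
    param_sds: tuple = (2.83, 7.83, 3.58, 0.09, 0.09, 1.00)
    # sparse correlation entries between parameters (symmetric, zero default)
    param_corr: dict = field(
        default_factory=lambda: {("AgeP50", "Ptsc"): 0.3, ("Qmax", "Emax"): 0.2}
    )
    param_lower: tuple = (40.0, 50.0, 0.0, 0.5, 0.5, 7.2)
    param_upper: tuple = (90.0, 140.0, 30.0, 2.0, 2.0, 16.8)
    noise_sd: float = 0.3
    infancy_visits: tuple = (0.1, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0)
    school_visit_start: float = 3.0
    school_visit_stop: float = 18.0
    visit_jitter: float = 0.15
    # menarche model
    menarche_mode: str = "p_linked"  # or "age_linked"
    p_at_menarche_mean: float = 0.716
    p_at_menarche_sd: float = 0.188
    p_at_menarche_bounds: tuple = (0.02, 0.995)
    age_menarche_mean: float = 12.96
    age_menarche_sd: float = 1.32
    report_mode_counts: dict = field(
        default_factory=lambda: {
            "year_month": 285,
            "year_only": 38,
            "year_age": 103,
            "age_only": 367,
        }
    )
    # parental heights
    mother_height_mean: float = 167.19
    mother_height_sd: float = 6.01
    father_height_mean: float = 181.41
    father_height_sd: float = 6.66
    parent_child_corr: float = 0.45
    mother_missing_frac: float = 17 / 793  # 776 of 793 have maternal height
    father_missing_frac: float = 42 / 793  # 751 of 793 have paternal height
    # birth-register variables
    gestational_age_mean_weeks: float = 40.15
    gestational_age_sd_weeks: float = 1.32
    gestational_age_bounds: tuple = (36.29, 42.86)
    birth_length_mean: float = 50.09
    birth_length_sd: float = 2.05
    birth_weight_mean: float = 3.53
    birth_weight_sd: float = 0.50
    birth_size_child_corr: float = 0.25
    # childhood BMI trajectory: level + curvature*(age - rebound)^2
    bmi_level_mean: float = 15.6
    bmi_level_sd: float = 1.4
    bmi_rebound_mean: float = 5.5
    bmi_rebound_sd: float = 0.8
    bmi_curvature_mean: float = 0.15
    bmi_curvature_sd: float = 0.05
    bmi_agep50_corr: float = -0.25
    weight_noise_sd: float = 0.15
    birth_year: int = 1990

    def __post_init__(self):
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if sum(self.report_mode_counts.values()) != self.n_subjects:
            # rescale the published split to the requested cohort size
            total = sum(self.report_mode_counts.values())
            modes = list(self.report_mode_counts)
            scaled = {
                m: int(round(self.report_mode_counts[m] * self.n_subjects / total))
                for m in modes
            }
            scaled[modes[-1]] += self.n_subjects - sum(scaled.values())
            self.report_mode_counts = scaled

    def covariance(self) -> np.ndarray:
        sds = np.asarray(self.param_sds)
        corr = np.eye(6)
        idx = {name: i for i, name in enumerate(_PARAM_ORDER)}
        for (a, b), rho in self.param_corr.items():
            corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
        if np.min(np.linalg.eigvalsh(corr)) < -1e-10:
            raise ValueError("parameter correlation matrix is not PSD")
        return corr * np.outer(sds, sds)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["param_corr"] = {f"{a}:{b}": v for (a, b), v in self.param_corr.items()}
        return d


def _truncated_mvn(mean, cov, lower, upper, n, rng, max_rounds=200):
    """Multivariate normal with row-wise rejection outside the box bounds."""
    out = np.empty((n, len(mean)))
    filled = 0
    for _ in range(max_rounds):
        draw = rng.multivariate_normal(mean, cov, size=n - filled)
        ok = np.all((draw >= lower) & (draw <= upper), axis=1)
        kept = draw[ok]
        out[filled : filled + kept.shape[0]] = kept
        filled += kept.shape[0]
        if filled == n:
            return out
    raise RuntimeError("truncated sampling failed to fill within bound")


def draw_parameters(config: GeneratorConfig, rng: np.random.Generator):
    """Draw per-subject QEPS parameters and the associated truth table."""
    mean = np.asarray(config.param_means, dtype=float)
    cov = config.covariance()
    draws = _truncated_mvn(
        mean, cov, config.param_lower, config.param_upper, config.n_subjects, rng
    )
    params = [QEPSParams.from_array(row) for row in draws]
    truth = pd.DataFrame(draws, columns=[f"true_{p}" for p in _PARAM_ORDER])
    truth.insert(0, "subject_id", [f"S{i:04d}" for i in range(config.n_subjects)])
    return params, truth


def _visit_schedule(config: GeneratorConfig, rng: np.random.Generator):
    base = np.concatenate(
        [
            np.asarray(config.infancy_visits, dtype=float),
            np.arange(
                config.school_visit_start, config.school_visit_stop + 1e-9, 1.0
            ),
        ]
    )
    ages = base + rng.uniform(-config.visit_jitter, config.visit_jitter, base.size)
    ages = np.maximum.accumulate(np.maximum(ages, 0.05) + 0.0)
    # enforce strict increase after jitter
    for i in range(1, ages.size):
        if ages[i] <= ages[i - 1]:
            ages[i] = ages[i - 1] + 0.02
    return ages


def render_measurements(
    params: QEPSParams,
    consts: ShapeConstants,
    config: GeneratorConfig,
    rng: np.random.Generator,
    bmi_coefs=None,
):
    """One subject's measurement series: jittered visits, noisy heights,
    and paired weights following a childhood BMI parabola."""
    ages = _visit_schedule(config, rng)
    true_h = total_height(ages, params, consts)
    heights = true_h + rng.normal(0.0, config.noise_sd, ages.size)
    if bmi_coefs is None:
        bmi_coefs = (config.bmi_level_mean, config.bmi_rebound_mean,
                     config.bmi_curvature_mean)
    level, rebound, curv = bmi_coefs
    # parabola around the adiposity rebound in childhood, continued linearly
    # (C1) after age 8 so adolescent BMI stays physiological
    d = np.minimum(ages, 8.0) - rebound
    bmi = level + curv * d**2
    late = ages > 8.0
    bmi[late] += 2.0 * curv * (8.0 - rebound) * (ages[late] - 8.0)
    weights = bmi * (true_h / 100.0) ** 2
    weights = weights + rng.normal(0.0, config.weight_noise_sd, ages.size)
    return pd.DataFrame(
        {"age_years": ages, "height_cm": heights, "weight_kg": weights}
    )


def draw_menarche(
    params: QEPSParams,
    consts: ShapeConstants,
    config: GeneratorConfig,
    rng: np.random.Generator,
):
    """True menarche age for one subject.

    In the default ``p_linked`` mode the achieved P-fraction at menarche is
    drawn from a truncated normal and inverted through the subject's own P
    sigmoid, building the maturation–menarche coupling into the cohort.  The
    ``age_linked`` mode draws a calendar age independent of growth.
    """
    if config.menarche_mode == "p_linked":
        lo, hi = config.p_at_menarche_bounds
        f = rng.normal(config.p_at_menarche_mean, config.p_at_menarche_sd)
        while not lo < f < hi:
            f = rng.normal(config.p_at_menarche_mean, config.p_at_menarche_sd)
        return float(age_at_p_fraction(f, params, consts)), float(f)
    if config.menarche_mode == "age_linked":
        a = rng.normal(config.age_menarche_mean, config.age_menarche_sd)
        while not 8.0 < a < 17.5:
            a = rng.normal(config.age_menarche_mean, config.age_menarche_sd)
        from .model import p_fraction

        return float(a), float(p_fraction(a, params, consts))
    raise ValueError(f"unknown menarche mode {config.menarche_mode!r}")


def _degrade_report(mode, birth_date, age_menarche):
    """Turn a true menarche age into the questionnaire fields of one mode."""
    event = birth_date + dt.timedelta(days=age_menarche * 365.25)
    whole_age = int(np.floor(age_menarche))
    if mode == "year_month":
        return {"menarche_year": event.year, "menarche_month": event.month,
                "menarche_reported_age": np.nan}
    if mode == "year_only":
        return {"menarche_year": event.year, "menarche_month": np.nan,
                "menarche_reported_age": np.nan}
    if mode == "year_age":
        return {"menarche_year": event.year, "menarche_month": np.nan,
                "menarche_reported_age": whole_age}
    if mode == "age_only":
        return {"menarche_year": np.nan, "menarche_month": np.nan,
                "menarche_reported_age": whole_age}
    raise ValueError(f"unknown report mode {mode!r}")


def generate_cohort(
    config: GeneratorConfig | None = None,
    consts: ShapeConstants | None = None,
    seed: int | None = None,
):
    """Generate a full cohort.

    Returns ``(measurements, metadata, truth)`` data frames.  Measurements
    are long-format (subject_id, age_years, height_cm, weight_kg); metadata
    is one row per subject with birth, parental, and menarche-report fields;
    truth holds the generating parameters and derived true milestone ages.
    """
    config = config or GeneratorConfig()
    consts = consts or ShapeConstants()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    params_list, truth = draw_parameters(config, rng)
    n = config.n_subjects
    z = _standardized_columns(truth)

    # parental heights share a genetic score with the daughter's height scales
    g = (z["Emax"] + z["Qmax"]) / np.sqrt(
        2.0 + 2.0 * config.param_corr.get(("Qmax", "Emax"), 0.0)
    )
    rho = config.parent_child_corr
    mix = np.sqrt(max(1.0 - rho**2, 0.0))
    mother = config.mother_height_mean + config.mother_height_sd * (
        rho * g + mix * rng.standard_normal(n)
    )
    father = config.father_height_mean + config.father_height_sd * (
        rho * g + mix * rng.standard_normal(n)
    )
    n_mother_missing = int(round(config.mother_missing_frac * n))
    n_father_missing = int(round(config.father_missing_frac * n))
    mother[rng.choice(n, n_mother_missing, replace=False)] = np.nan
    father[rng.choice(n, n_father_missing, replace=False)] = np.nan

    # birth register
    glo, ghi = config.gestational_age_bounds
    ga = np.clip(
        rng.normal(config.gestational_age_mean_weeks, config.gestational_age_sd_weeks, n),
        glo, ghi,
    )
    rb = config.birth_size_child_corr
    bmix = np.sqrt(1.0 - rb**2)
    bl = config.birth_length_mean + config.birth_length_sd * (
        rb * g + bmix * rng.standard_normal(n)
    )
    bw = config.birth_weight_mean + config.birth_weight_sd * (
        0.6 * (bl - config.birth_length_mean) / config.birth_length_sd
        + np.sqrt(1 - 0.36) * rng.standard_normal(n)
    )
    bw = np.clip(bw, 1.5, 6.0)

    # childhood BMI coefficients, level anti-correlated with pubertal timing
    rho_b = config.bmi_agep50_corr
    level = config.bmi_level_mean + config.bmi_level_sd * (
        rho_b * z["AgeP50"] + np.sqrt(1 - rho_b**2) * rng.standard_normal(n)
    )
    rebound = rng.normal(config.bmi_rebound_mean, config.bmi_rebound_sd, n)
    curv = np.abs(rng.normal(config.bmi_curvature_mean, config.bmi_curvature_sd, n))

    birth_dates = [
        dt.date(config.birth_year, 1, 1) + dt.timedelta(days=int(d))
        for d in rng.integers(0, 365, n)
    ]

    modes = np.concatenate(
        [np.repeat(m, c) for m, c in config.report_mode_counts.items()]
    )
    rng.shuffle(modes)

    meas_frames = []
    meta_rows = []
    truth_extra = []
    for i, params in enumerate(params_list):
        sid = f"S{i:04d}"
        df = render_measurements(
            params, consts, config, rng, bmi_coefs=(level[i], rebound[i], curv[i])
        )
        df.insert(0, "subject_id", sid)
        meas_frames.append(df)

        age_m, frac_m = draw_menarche(params, consts, config, rng)
        report = _degrade_report(modes[i], birth_dates[i], age_m)
        meta_rows.append(
            {
                "subject_id": sid,
                "birth_date": birth_dates[i].isoformat(),
                "gestational_age_days": round(ga[i] * 7.0, 1),
                "birth_length_cm": round(bl[i], 1),
                "birth_weight_kg": round(bw[i], 3),
                "mother_height_cm": round(mother[i], 1) if np.isfinite(mother[i]) else np.nan,
                "father_height_cm": round(father[i], 1) if np.isfinite(father[i]) else np.nan,
                "menarche_mode": modes[i],
                **report,
            }
        )
        truth_extra.append(
            {
                "true_age_menarche": age_m,
                "true_p_at_menarche": frac_m,
                "true_agep5": age_at_p_fraction(0.05, params, consts),
                "true_agep_phv": age_at_p_velocity_peak(params, consts),
            }
        )

    measurements = pd.concat(meas_frames, ignore_index=True)
    metadata = pd.DataFrame(meta_rows)
    truth = pd.concat([truth, pd.DataFrame(truth_extra)], axis=1)
    return measurements, metadata, truth


def _standardized_columns(truth: pd.DataFrame) -> dict:
    z = {}
    for p in _PARAM_ORDER:
        col = truth[f"true_{p}"].to_numpy()
        z[p] = (col - col.mean()) / col.std(ddof=1)
    return z
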