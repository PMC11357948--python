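"""Subject-level derived variables.

Covers menarcheal-age imputation from questionnaire reports of varying
completeness, midparental height, childhood BMI, SDS transforms against
pluggable age references (default: cohort-internal standardization), and the
QEPS milestone quantities: milestone ages and heights, pubertal gains, the
achieved P-fraction at menarche, and postmenarcheal height gain.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    QEPSParams,
    ShapeConstants,
    age_at_p_fraction,
    age_at_p_velocity_peak,
    age_at_total_velocity_peak,
    eval_components,
    p_fraction,
    total_height,
)

__all__ = [
    "MenarcheReport",
    "MilestoneSet",
    "SDSReference",
    "impute_menarche_age",
    "mph_sds",
    "diffh_mph",
    "bmi_max",
    "to_sds",
    "adult_height",
    "pubertal_gains",
    "menarche_growth_vars",
    "compute_milestones",
    "derive_table",
    "MILESTONE_GROUPS",
    "DAYS_PER_YEAR",
]

DAYS_PER_YEAR = 365.25

#: fixed offset (years) added to a whole-year age-only menarche report,
#: derived in the source cohort from girls who reported both date and age
AGE_ONLY_OFFSET = 0.193

_MODES = ("year_month", "year_only", "year_age", "age_only")


@dataclass(frozen=True)
class MenarcheReport:
    """A questionnaire menarche report in one of four completeness modes."""

    mode: str
    birth_date: dt.date
    year: int | None = None
    month: int | None = None
    reported_age: float | None = None

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        need = {
            "year_month": ("year", "month"),
            "year_only": ("year",),
            "year_age": ("year", "reported_age"),
            "age_only": ("reported_age",),
        }[self.mode]
        for f in need:
            if getattr(self, f) is None:
                raise ValueError(f"mode {self.mode!r} requires field {f!r}")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError("month must be in 1..12")
        if self.reported_age is not None and not 8 <= self.reported_age <= 20:
            raise ValueError("reported_age must be in [8, 20]")


def _decimal_age(event: dt.date, birth: dt.date) -> float:
    return (event - birth).days / DAYS_PER_YEAR


def _add_years(date: dt.date, years: int) -> dt.date:
    try:
        return date.replace(year=date.year + years)
    except ValueError:  # Feb 29 in a non-leap target year
        return date.replace(year=date.year + years, day=28)


def impute_menarche_age(report: MenarcheReport) -> float:
    """Decimal menarcheal age (years) from a questionnaire report.

    * ``year_month`` — exact date arithmetic from the birth date to the
      middle (day 15) of the recorded month;
    * ``year_only`` — likewise, to the middle (July 2) of the recorded year;
    * ``year_age`` — midpoint of the overlap between the stated-age year of
      life and the recorded calendar year;
    * ``age_only`` — the reported whole-year age plus 0.193 years.
    """
    birth = report.birth_date
    if report.year is not None and report.year < birth.year:
        raise ValueError(
            f"menarche year {report.year} precedes birth year {birth.year}"
        )
    if report.mode == "year_month":
        age = _decimal_age(dt.date(report.year, report.month, 15), birth)
    elif report.mode == "year_only":
        age = _decimal_age(dt.date(report.year, 7, 2), birth)
    elif report.mode == "year_age":
        a = int(report.reported_age)
        lo = max(_add_years(birth, a), dt.date(report.year, 1, 1))
        hi = min(_add_years(birth, a + 1), dt.date(report.year + 1, 1, 1))
        if hi <= lo:
            raise ValueError(
                f"stated age {a} and year {report.year} do not overlap for a "
                f"birth date of {birth.isoformat()}"
            )
        mid = lo + (hi - lo) / 2
        age = _decimal_age(mid, birth)
    else:  # age_only
        age = float(report.reported_age) + AGE_ONLY_OFFSET
    if not 6.0 <= age <= 20.0:
        raise ValueError(f"imputed menarcheal age {age:.2f} outside [6, 20] years")
    return age


def mph_sds(mother_sds: float, father_sds: float) -> float:
    """Midparental height in SDS: the parental mean; NaN if a parent is missing."""
    if not (np.isfinite(mother_sds) and np.isfinite(father_sds)):
        return float("nan")
    return 0.5 * (mother_sds + father_sds)


def diffh_mph(height_sds: float, mph: float) -> float:
    """Child height SDS at a milestone minus midparental height SDS."""
    if not (np.isfinite(height_sds) and np.isfinite(mph)):
        return float("nan")
    return height_sds - mph


def bmi_max(measurements: pd.DataFrame, lo: float = 3.5, hi: float = 7.0) -> float:
    """Highest BMI (kg/m^2) between ``lo`` and ``hi`` years, both inclusive.

    ``measurements`` needs columns ``age_years``, ``height_cm``,
    ``weight_kg``.  An empty window yields NaN.
    """
    m = measurements
    win = m[(m["age_years"] >= lo) & (m["age_years"] <= hi)]
    win = win.dropna(subset=["height_cm", "weight_kg"])
    if win.empty:
        return float("nan")
    bmi = win["weight_kg"].to_numpy() / (win["height_cm"].to_numpy() / 100.0) ** 2
    return float(np.max(bmi))


@dataclass(frozen=True)
class SDSReference:
    """Age-dependent reference: strictly increasing ages with mean and SD."""

    variable: str
    ages: tuple
    means: tuple
    sds: tuple

    def __post_init__(self):
        a = np.asarray(self.ages, dtype=float)
        s = np.asarray(self.sds, dtype=float)
        if a.size < 2 or np.any(np.diff(a) <= 0):
            raise ValueError("reference ages must be strictly increasing")
        if np.any(s <= 0):
            raise ValueError("reference SDs must be positive everywhere")


def to_sds(value: float, age: float, ref: SDSReference) -> float:
    """Standard deviation score against an age reference, interpolating
    linearly between grid nodes; ages outside the grid give NaN (no
    extrapolation)."""
    a = np.asarray(ref.ages, dtype=float)
    if not a[0] <= age <= a[-1]:
        return float("nan")
    mean = np.interp(age, a, np.asarray(ref.means, dtype=float))
    sd = np.interp(age, a, np.asarray(ref.sds, dtype=float))
    return (value - mean) / sd


def cohort_sds(values: pd.Series) -> pd.Series:
    """Cohort-internal (age-free) standardization of one derived variable."""
    v = values.astype(float)
    sd = v.std(ddof=1)
    if not sd > 0:
        raise ValueError(f"column {values.name!r} has zero spread")
    return (v - v.mean()) / sd


def adult_height(tmax: float, measured_heights) -> float:
    """Adult height: the model estimate, or the tallest measurement if it
    exceeds the model estimate."""
    measured = np.asarray(measured_heights, dtype=float)
    if measured.size == 0:
        return float(tmax)
    return float(max(tmax, np.nanmax(measured)))


def pubertal_gains(params: QEPSParams, consts: ShapeConstants) -> dict:
    """Height gains over the pubertal window [AgeP5, AgeP100] by component.

    ``tpubgain = ppubgain + qespubgain`` holds identically because the total
    curve is the sum of its components; ``deltapubgain`` is their difference.
    """
    a5 = age_at_p_fraction(0.05, params, consts)
    a100 = age_at_p_fraction(consts.pEnd, params, consts)
    c5 = eval_components(a5, params, consts)
    c100 = eval_components(a100, params, consts)
    pp = c100.P - c5.P
    qes = c100.QES - c5.QES
    return {
        "tpubgain": c100.T - c5.T,
        "ppubgain": pp,
        "qespubgain": qes,
        "deltapubgain": pp - qes,
    }


def menarche_growth_vars(
    params: QEPSParams,
    consts: ShapeConstants,
    age_menarche: float,
    adult_height_cm: float,
) -> dict:
    """Menarche-linked growth quantities.

    Achieved P-percentage and model height at menarche, postmenarcheal gain
    (floored at zero with a warning, as a curve-fit artifact can place the
    model height at menarche above measured adult height), and the durations
    from pubertal-onset landmarks to menarche and onward.
    """
    if not np.isfinite(age_menarche):
        keys = (
            "age_menarche p_percent_menarche t_agemenarche postmenarcheal_gain "
            "dur_p5_to_menarche dur_pphv_to_menarche dur_menarche_to_p95 "
            "dur_menarche_to_p99"
        ).split()
        return {k: float("nan") for k in keys}
    t_men = float(total_height(age_menarche, params, consts))
    gain = adult_height_cm - t_men
    if gain < 0:
        warnings.warn(
            f"negative postmenarcheal gain {gain:.2f} cm floored at 0", RuntimeWarning
        )
        gain = 0.0
    a5 = age_at_p_fraction(0.05, params, consts)
    a95 = age_at_p_fraction(0.95, params, consts)
    a99 = age_at_p_fraction(0.99, params, consts)
    aphv = age_at_p_velocity_peak(params, consts)
    return {
        "age_menarche": float(age_menarche),
        "p_percent_menarche": 100.0 * float(p_fraction(age_menarche, params, consts)),
        "t_agemenarche": t_men,
        "postmenarcheal_gain": gain,
        "dur_p5_to_menarche": age_menarche - a5,
        "dur_pphv_to_menarche": age_menarche - aphv,
        "dur_menarche_to_p95": a95 - age_menarche,
        "dur_menarche_to_p99": a99 - age_menarche,
    }


@dataclass(frozen=True)
class MilestoneSet:
    """All derived ages, heights, gains, and durations for one subject."""

    ageP5: float
    ageP50: float
    ageP95: float
    ageP99: float
    ageP100: float
    agePPHV: float
    ageTPHV: float
    T_ageP5: float
    T_ageP50: float
    T_ageP95: float
    T_ageP99: float
    T_ageP100: float
    T_agePPHV: float
    T_ageTPHV: float
    T_ageMenarche: float
    Tmax: float
    Tpubgain: float
    Ppubgain: float
    QESpubgain: float
    Deltapubgain: float
    Pmax: float
    p_percent_menarche: float
    dur_P5_to_menarche: float
    dur_PPHV_to_menarche: float
    dur_menarche_to_P95: float
    dur_menarche_to_P99: float
    postmenarcheal_gain: float


def compute_milestones(
    params: QEPSParams,
    consts: ShapeConstants,
    age_menarche: float = float("nan"),
    measured_heights=(),
    plateau_age: float = 30.0,
) -> MilestoneSet:
    """Assemble the full milestone set for one fitted subject."""
    fracs = {"P5": 0.05, "P50": 0.5, "P95": 0.95, "P99": 0.99, "P100": consts.pEnd}
    ages = {k: age_at_p_fraction(f, params, consts) for k, f in fracs.items()}
    ages["PPHV"] = age_at_p_velocity_peak(params, consts)
    ages["TPHV"] = age_at_total_velocity_peak(params, consts)
    heights = {
        k: float(total_height(a, params, consts)) if np.isfinite(a) else float("nan")
        for k, a in ages.items()
    }
    tmax = float(total_height(plateau_age, params, consts))
    ah = adult_height(tmax, measured_heights)
    gains = pubertal_gains(params, consts)
    men = menarche_growth_vars(params, consts, age_menarche, ah)
    return MilestoneSet(
        ageP5=ages["P5"],
        ageP50=ages["P50"],
        ageP95=ages["P95"],
        ageP99=ages["P99"],
        ageP100=ages["P100"],
        agePPHV=ages["PPHV"],
        ageTPHV=ages["TPHV"],
        T_ageP5=heights["P5"],
        T_ageP50=heights["P50"],
        T_ageP95=heights["P95"],
        T_ageP99=heights["P99"],
        T_ageP100=heights["P100"],
        T_agePPHV=heights["PPHV"],
        T_ageTPHV=heights["TPHV"],
        T_ageMenarche=men["t_agemenarche"],
        Tmax=tmax,
        Tpubgain=gains["tpubgain"],
        Ppubgain=gains["ppubgain"],
        QESpubgain=gains["qespubgain"],
        Deltapubgain=gains["deltapubgain"],
        Pmax=params.Pmax,
        p_percent_menarche=men["p_percent_menarche"],
        dur_P5_to_menarche=men["dur_p5_to_menarche"],
        dur_PPHV_to_menarche=men["dur_pphv_to_menarche"],
        dur_menarche_to_P95=men["dur_menarche_to_p95"],
        dur_menarche_to_P99=men["dur_menarche_to_p99"],
        postmenarcheal_gain=men["postmenarcheal_gain"],
    )


def cohort_summary(table: pd.DataFrame) -> dict:
    """Cohort-level counts and percentages of menarche timing landmarks.

    Reports how many girls reached menarche before midpuberty (AgeP50) and
    before the P-function velocity peak, with percentages on the 0-100 scale
    computed as 100 * count / n over subjects with both quantities known.
    """
    out = {}
    for landmark, col in [("agep50", "agep50"), ("agep_phv", "agep_phv")]:
        sub = table[["age_menarche", col]].dropna()
        n = len(sub)
        count = int((sub["age_menarche"] < sub[col]).sum())
        out[f"n_menarche_before_{landmark}"] = count
        out[f"pct_menarche_before_{landmark}"] = 100.0 * count / n if n else float("nan")
    out["n"] = int(len(table))
    return out


#: assignment of regression candidate variables to clinical milestones, in
#: chronological order; later milestones add to (never repeat) earlier ones
MILESTONE_GROUPS = {
    "birth": [
        "mother_height_sds",
        "father_height_sds",
        "mph_sds",
        "gestational_age_weeks",
        "birth_length_sds",
        "birth_weight_sds",
    ],
    "childhood7y": [
        "etsc",
        "emax_sds",
        "qmax_sds",
        "bmi_max_sds",
        "height_7y_sds",
        "diffh_mph_7y",
    ],
    "pubertal_onset": [
        "t_agep5_sds",
        "diffh_mph_p5",
        "agep5",
    ],
    "midpuberty": [
        "t_agep50_sds",
        "diffh_mph_p50",
        "agep50",
        "agep_phv",
        "aget_phv",
    ],
}

OUTCOMES = ("age_menarche", "postmenarcheal_gain")


def _report_from_row(row) -> MenarcheReport:
    def _opt(v, cast):
        return None if pd.isna(v) else cast(v)

    return MenarcheReport(
        mode=row["menarche_mode"],
        birth_date=dt.date.fromisoformat(row["birth_date"]),
        year=_opt(row.get("menarche_year"), int),
        month=_opt(row.get("menarche_month"), int),
        reported_age=_opt(row.get("menarche_reported_age"), float),
    )


def derive_table(
    fitted_params: dict,
    metadata: pd.DataFrame,
    measurements: pd.DataFrame,
    consts: ShapeConstants | None = None,
) -> pd.DataFrame:
    """Build the one-row-per-subject derived-variable table.

    ``fitted_params`` maps subject_id to :class:`QEPSParams`; ``metadata``
    and ``measurements`` follow the cohort CSV schemas.  SDS columns use
    cohort-internal standardization (the shipped default reference).
    """
    consts = consts or ShapeConstants()
    meas_by_subject = dict(tuple(measurements.groupby("subject_id", sort=False)))
    rows = []
    for _, meta in metadata.iterrows():
        sid = meta["subject_id"]
        if sid not in fitted_params:
            continue
        params = fitted_params[sid]
        sub = meas_by_subject.get(sid, pd.DataFrame(columns=measurements.columns))
        try:
            age_men = impute_menarche_age(_report_from_row(meta))
        except ValueError:
            age_men = float("nan")
        ms = compute_milestones(
            params, consts, age_men, sub["height_cm"].to_numpy()
        )
        ah = adult_height(ms.Tmax, sub["height_cm"].to_numpy())
        rows.append(
            {
                "subject_id": sid,
                "mother_height_cm": meta["mother_height_cm"],
                "father_height_cm": meta["father_height_cm"],
                "gestational_age_weeks": meta["gestational_age_days"] / 7.0,
                "birth_length_cm": meta["birth_length_cm"],
                "birth_weight_kg": meta["birth_weight_kg"],
                "etsc": params.Etsc,
                "emax": params.Emax,
                "qmax": params.Qmax,
                "pmax": params.Pmax,
                "bmi_max": bmi_max(sub),
                "height_7y": float(total_height(7.0, params, consts)),
                "t_agep5": ms.T_ageP5,
                "agep5": ms.ageP5,
                "t_agep50": ms.T_ageP50,
                "agep50": ms.ageP50,
                "agep_phv": ms.agePPHV,
                "aget_phv": ms.ageTPHV,
                "agep95": ms.ageP95,
                "t_agep95": ms.T_ageP95,
                "tpubgain": ms.Tpubgain,
                "ppubgain": ms.Ppubgain,
                "qespubgain": ms.QESpubgain,
                "deltapubgain": ms.Deltapubgain,
                "adult_height": ah,
                "p_percent_menarche": ms.p_percent_menarche,
                "t_agemenarche": ms.T_ageMenarche,
                "dur_p5_to_menarche": ms.dur_P5_to_menarche,
                "dur_pphv_to_menarche": ms.dur_PPHV_to_menarche,
                "dur_menarche_to_p95": ms.dur_menarche_to_P95,
                "dur_menarche_to_p99": ms.dur_menarche_to_P99,
                "age_menarche": age_men,
                "postmenarcheal_gain": ms.postmenarcheal_gain,
            }
        )
    table = pd.DataFrame(rows)

    # cohort-internal SDS transforms
    for src, dst in [
        ("mother_height_cm", "mother_height_sds"),
        ("father_height_cm", "father_height_sds"),
        ("birth_length_cm", "birth_length_sds"),
        ("birth_weight_kg", "birth_weight_sds"),
        ("emax", "emax_sds"),
        ("qmax", "qmax_sds"),
        ("bmi_max", "bmi_max_sds"),
        ("height_7y", "height_7y_sds"),
        ("t_agep5", "t_agep5_sds"),
        ("t_agep50", "t_agep50_sds"),
        ("adult_height", "adult_height_sds"),
    ]:
        table[dst] = cohort_sds(table[src])
    table["mph_sds"] = [
        mph_sds(m, f)
        for m, f in zip(table["mother_height_sds"], table["father_height_sds"])
    ]
    for hs, dst in [
        ("height_7y_sds", "diffh_mph_7y"),
        ("t_agep5_sds", "diffh_mph_p5"),
        ("t_agep50_sds", "diffh_mph_p50"),
        ("adult_height_sds", "diffh_mph_adult"),
    ]:
        table[dst] = [
            diffh_mph(h, m) for h, m in zip(table[hs], table["mph_sds"])
        ]
    return table
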