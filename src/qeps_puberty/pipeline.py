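"""Pipeline orchestration: simulate -> fit -> derive -> regress -> report.

Each stage reads and writes delimited text tables (CSV, ISO dates, decimal
years) and records its inputs, outputs, and their SHA-256 checksums in a run
manifest, so any stage can be reproduced in isolation.  Outputs are
byte-identical for a fixed seed and configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .derive import MILESTONE_GROUPS, derive_table
from .fit import CoverageError, QEPSGrowthCurve
from .model import QEPSParams, ShapeConstants
from .regress import analyze_postmenarcheal_gain, forest_plot, milestone_models
from .simulate import GeneratorConfig, generate_cohort

__all__ = [
    "RunConfig",
    "run_pipeline",
    "validate_table",
    "fit_cohort",
    "MEASUREMENTS_SCHEMA",
    "METADATA_SCHEMA",
]

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.6f"

MEASUREMENTS_SCHEMA = {
    "subject_id": {"kind": "str", "required": True},
    "age_years": {"kind": "float", "min": 0.0, "max": 25.0, "required": True},
    "height_cm": {"kind": "float", "min": 30.0, "max": 220.0, "required": True},
    "weight_kg": {"kind": "float", "min": 1.0, "max": 150.0, "required": False},
}

METADATA_SCHEMA = {
    "subject_id": {"kind": "str", "required": True},
    "birth_date": {"kind": "str", "required": True},
    "gestational_age_days": {"kind": "float", "min": 150, "max": 320, "required": True},
    "birth_length_cm": {"kind": "float", "min": 30, "max": 65, "required": True},
    "birth_weight_kg": {"kind": "float", "min": 0.5, "max": 7, "required": True},
    "mother_height_cm": {"kind": "float", "min": 120, "max": 220, "required": False},
    "father_height_cm": {"kind": "float", "min": 120, "max": 230, "required": False},
    "menarche_mode": {"kind": "str", "required": True},
    "menarche_year": {"kind": "float", "required": False},
    "menarche_month": {"kind": "float", "min": 1, "max": 12, "required": False},
    "menarche_reported_age": {"kind": "float", "min": 8, "max": 20, "required": False},
}


def validate_table(path, schema) -> tuple[bool, list[str]]:
    """Check a CSV against a column schema; returns (ok, violation list)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # unreadable / malformed
        raise OSError(f"cannot read table {path}: {exc}") from exc
    violations = []
    for col, rule in schema.items():
        if col not in df.columns:
            if rule.get("required", False):
                violations.append(f"{path.name}: missing required column {col!r}")
            continue
        series = df[col]
        if rule["kind"] == "float":
            coerced = pd.to_numeric(series, errors="coerce")
            bad = series.notna() & coerced.isna()
            if bad.any():
                violations.append(
                    f"{path.name}: column {col!r} has {int(bad.sum())} "
                    "non-numeric values"
                )
            vals = coerced.dropna()
            if "min" in rule and (vals < rule["min"]).any():
                violations.append(
                    f"{path.name}: column {col!r} below minimum {rule['min']}"
                )
            if "max" in rule and (vals > rule["max"]).any():
                violations.append(
                    f"{path.name}: column {col!r} above maximum {rule['max']}"
                )
        if rule.get("required", False) and series.isna().all():
            violations.append(f"{path.name}: required column {col!r} is empty")
    return (len(violations) == 0, violations)


def fit_cohort(
    measurements: pd.DataFrame,
    consts: ShapeConstants | None = None,
    seed: int = 1990,
    **fit_kwargs,
):
    """Fit every subject in a long-format measurement table.

    Returns ``(params_by_subject, fit_table)``; subjects whose series fail
    the coverage preconditions are excluded and flagged in the fit table.
    """
    consts = consts or ShapeConstants()
    params_by_subject: dict[str, QEPSParams] = {}
    rows = []
    for sid, sub in measurements.groupby("subject_id", sort=True):
        est = QEPSGrowthCurve(consts=consts, seed=seed, **fit_kwargs)
        try:
            est.fit(sub["age_years"].to_numpy(), sub["height_cm"].to_numpy())
        except CoverageError as exc:
            log.warning("subject %s not fitted: %s", sid, exc)
            rows.append({"subject_id": sid, "fitted": False, "reason": str(exc)})
            continue
        params_by_subject[sid] = est.params_
        rows.append(
            {
                "subject_id": sid,
                "fitted": True,
                "reason": "",
                "emax": est.params_.Emax,
                "qmax": est.params_.Qmax,
                "pmax": est.params_.Pmax,
                "etsc": est.params_.Etsc,
                "ptsc": est.params_.Ptsc,
                "agep50": est.params_.AgeP50,
                "rmse": est.rmse_,
                "n_used": est.n_used_,
                "converged": est.converged_,
                "n_starts_tried": est.n_starts_tried_,
            }
        )
    return params_by_subject, pd.DataFrame(rows)


@dataclasses.dataclass
class RunConfig:
    """Everything one pipeline run needs, serializable to/from YAML."""

    out_dir: str = "run_out"
    seed: int = 1990
    consts: ShapeConstants = dataclasses.field(default_factory=ShapeConstants)
    generator: GeneratorConfig = dataclasses.field(default_factory=GeneratorConfig)
    alpha: float = 0.05
    fit_seed: int = 1990

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "consts" in raw:
            kwargs["consts"] = ShapeConstants(**raw.pop("consts"))
        if "generator" in raw:
            gen = raw.pop("generator")
            corr = gen.pop("param_corr", None)
            if corr is not None:
                gen["param_corr"] = {
                    tuple(k.split(":")): v for k, v in corr.items()
                }
            kwargs["generator"] = GeneratorConfig(**gen)
        kwargs.update(raw)
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path):
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages in order, writing a checksummed manifest.

    Any stage failure raises with the stage named; partial outputs are left
    in place for inspection.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "shape_constants": config.consts.to_dict(),
        "generator": config.generator.to_dict(),
        "stages": {},
        "note": "synthetic cohort; generator correlations are assumptions",
    }

    stage = "simulate"
    try:
        log.info("stage %s: shape constants %s", stage, config.consts.to_dict())
        measurements, metadata, truth = generate_cohort(
            config.generator, config.consts, seed=config.seed
        )
        paths = {
            "measurements": out / "measurements.csv",
            "metadata": out / "metadata.csv",
            "truth": out / "truth.csv",
        }
        _write_csv(measurements, paths["measurements"])
        _write_csv(metadata, paths["metadata"])
        _write_csv(truth, paths["truth"])
        manifest["stages"][stage] = {
            "outputs": {k: _sha256(p) for k, p in paths.items()}
        }

        stage = "validate"
        for path, schema in [
            (paths["measurements"], MEASUREMENTS_SCHEMA),
            (paths["metadata"], METADATA_SCHEMA),
        ]:
            ok, violations = validate_table(path, schema)
            if not ok:
                raise ValueError("; ".join(violations))

        stage = "fit"
        params, fit_table = fit_cohort(
            measurements, config.consts, seed=config.fit_seed
        )
        fit_path = out / "fits.csv"
        _write_csv(fit_table, fit_path)
        manifest["stages"][stage] = {"outputs": {"fits": _sha256(fit_path)}}

        stage = "derive"
        derived = derive_table(params, metadata, measurements, config.consts)
        derived_path = out / "derived.csv"
        _write_csv(derived, derived_path)
        manifest["stages"][stage] = {"outputs": {"derived": _sha256(derived_path)}}

        stage = "regress"
        reports = milestone_models(derived, "age_menarche", alpha=config.alpha)
        gain_vars = [
            v for g in MILESTONE_GROUPS.values() for v in g
        ] + ["age_menarche", "tpubgain"]
        gain_uni, gain_multi = analyze_postmenarcheal_gain(derived, gain_vars)
        report_paths = {}
        for rep in reports:
            p = out / f"model_age_menarche_{rep.milestone}.csv"
            _write_csv(rep.table.assign(model_r2=rep.model_r2, n=rep.n), p)
            report_paths[rep.milestone] = _sha256(p)
        p = out / "univariable_postmenarcheal_gain.csv"
        _write_csv(gain_uni.table, p)
        report_paths["postmenarcheal_gain_univariable"] = _sha256(p)
        summary = {
            "age_menarche": {
                rep.milestone: {
                    "r2": rep.model_r2,
                    "selected": rep.selected,
                    "n": rep.n,
                }
                for rep in reports
            },
            "postmenarcheal_gain": {
                "n_holm_significant": int(
                    (gain_uni.table.get("p_holm", pd.Series(dtype=float)) < config.alpha).sum()
                ),
                "multivariable_run": gain_multi is not None,
            },
        }
        (out / "regression_summary.json").write_text(
            json.dumps(summary, indent=2, default=float)
        )
        manifest["stages"][stage] = {"outputs": report_paths}

        stage = "report"
        forest_plot(reports, out / "forest_age_menarche.png")
        manifest["stages"][stage] = {"outputs": {}}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
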