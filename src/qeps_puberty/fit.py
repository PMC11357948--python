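"""Per-subject estimation of QEPS parameters from longitudinal height data.

The model is linear in its three height scales (``Emax``, ``Qmax``, ``Pmax``)
once the time scales and ``AgeP50`` are fixed, so the fit proceeds in two
stages: a coarse grid over ``(AgeP50, Ptsc)`` with a non-negative linear
solve for the height scales at each node, followed by bounded nonlinear
least squares from several jittered restarts seeded for reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, nnls
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .model import (
    QEPSParams,
    ShapeConstants,
    _e_height,
    _q_braked_height,
    p_fraction,
    total_height,
)

__all__ = [
    "HeightMeasurement",
    "FitResult",
    "CoverageError",
    "QEPSGrowthCurve",
    "presearch_grid",
    "fit_qeps",
]


class CoverageError(ValueError):
    """Measurement series too sparse or ill-spanned to identify the model."""


@dataclass(frozen=True)
class HeightMeasurement:
    """A single height observation: age in years, height in cm."""

    age: float
    height: float

    def __post_init__(self):
        if not 0.0 <= self.age <= 25.0:
            raise ValueError(f"age {self.age} outside [0, 25] years")
        if not 30.0 <= self.height <= 220.0:
            raise ValueError(f"height {self.height} outside [30, 220] cm")


@dataclass(frozen=True)
class FitResult:
    """Outcome of one per-subject fit."""

    params: QEPSParams
    rmse: float
    n_used: int
    converged: bool
    n_starts_tried: int


# parameter vector order: Emax, Qmax, Pmax, Etsc, Ptsc, AgeP50
_LOWER = np.array([0.0, 0.0, 0.0, 0.5, 0.5, 7.0])
_UPPER = np.array([200.0, 200.0, 200.0, 2.0, 2.0, 17.0])


def _design(ages, etsc, ptsc, agep50, consts):
    """Unit-scale component basis: heights are linear in (Emax, Qmax, Pmax)."""
    unit_time = QEPSParams(1.0, 0.0, 0.0, etsc, ptsc, agep50)
    e = _e_height(ages, unit_time, consts)
    q = _q_braked_height(ages, QEPSParams(0.0, 1.0, 0.0, etsc, ptsc, agep50), consts)
    p = p_fraction(ages, unit_time, consts)
    return np.column_stack([e, q, p])


def presearch_grid(
    ages,
    heights,
    consts: ShapeConstants | None = None,
    *,
    agep50_grid=None,
    ptsc_grid=(0.7, 1.0, 1.4),
    etsc: float = 1.0,
    top_m: int = 5,
):
    """Coarse-grid presearch over (AgeP50, Ptsc) with a non-negative linear
    solve for the height scales at each node.

    Returns the ``top_m`` candidate parameter vectors sorted by residual sum
    of squares (best first).  Deterministic for fixed input.
    """
    consts = consts or ShapeConstants()
    ages = np.asarray(ages, dtype=float)
    heights = np.asarray(heights, dtype=float)
    if agep50_grid is None:
        agep50_grid = np.arange(8.0, 16.01, 0.5)
    candidates = []
    for agep50 in agep50_grid:
        for ptsc in ptsc_grid:
            X = _design(ages, etsc, ptsc, agep50, consts)
            scales, _ = nnls(X, heights)
            resid = heights - X @ scales
            sse = float(resid @ resid)
            candidates.append(
                (sse, np.array([*scales, etsc, ptsc, agep50], dtype=float))
            )
    candidates.sort(key=lambda c: (c[0], tuple(c[1])))
    return [vec for _, vec in candidates[:top_m]]


def _qc_series(ages, heights, max_shrink_cm: float):
    """Drop exact duplicate rows; reject implausible negative growth."""
    order = np.lexsort((heights, ages))
    ages, heights = ages[order], heights[order]
    keep = np.ones(ages.size, dtype=bool)
    keep[1:] = (np.diff(ages) != 0) | (np.diff(heights) != 0)
    ages, heights = ages[keep], heights[keep]
    shrink = -np.diff(heights)
    if np.any(shrink > max_shrink_cm):
        i = int(np.argmax(shrink))
        raise CoverageError(
            f"height decreases by {shrink[i]:.1f} cm between ages "
            f"{ages[i]:.2f} and {ages[i + 1]:.2f}; series rejected"
        )
    return ages, heights


class QEPSGrowthCurve(BaseEstimator, RegressorMixin):
    """Fit an individual QEPS growth curve to (age, height) observations.

    Parameters
    ----------
    consts : ShapeConstants, optional
        Shared shape constants; defaults are used when omitted.
    n_starts : int
        Number of local optimisations launched from jittered presearch
        candidates (the best candidate is always tried unjittered).
    seed : int
        Seed for the start-point jitter; fits are deterministic given it.
    min_points : int
        Minimum number of distinct measurements required.
    required_span : tuple of float
        The series must contain a measurement at or before the first element
        and at or after the second (years).
    min_late_points, late_age : int, float
        At least ``min_late_points`` measurements after ``late_age`` years
        are required so that adult height is identified.
    max_shrink_cm : float
        Maximum tolerated height decrease between consecutive visits before
        the series is rejected as inconsistent.

    Attributes
    ----------
    params_ : QEPSParams
        Best-fit individual parameters.
    rmse_ : float
        Root-mean-square height residual in cm.
    n_used_ : int
        Number of measurements used after QC.
    converged_ : bool
        Whether the winning local optimisation reported convergence.
    n_starts_tried_ : int
        Local optimisations actually launched.
    """

    def __init__(
        self,
        consts: ShapeConstants | None = None,
        n_starts: int = 5,
        seed: int = 1990,
        min_points: int = 8,
        required_span: tuple = (2.0, 15.0),
        min_late_points: int = 2,
        late_age: float = 13.0,
        max_shrink_cm: float = 1.0,
    ):
        self.consts = consts
        self.n_starts = n_starts
        self.seed = seed
        self.min_points = min_points
        self.required_span = required_span
        self.min_late_points = min_late_points
        self.late_age = late_age
        self.max_shrink_cm = max_shrink_cm

    def _consts(self) -> ShapeConstants:
        return self.consts if self.consts is not None else ShapeConstants()

    def _validate_coverage(self, ages):
        lo, hi = self.required_span
        if ages.size < self.min_points:
            raise CoverageError(
                f"need >= {self.min_points} measurements, got {ages.size}"
            )
        if ages.min() > lo or ages.max() < hi:
            raise CoverageError(
                f"measurements must span [{lo}, {hi}] y; "
                f"got [{ages.min():.2f}, {ages.max():.2f}]"
            )
        if np.sum(ages > self.late_age) < self.min_late_points:
            raise CoverageError(
                f"need >= {self.min_late_points} measurements after "
                f"{self.late_age} y"
            )

    def fit(self, X, y):
        """Fit the curve.  X: ages in years, shape (n,) or (n, 1); y: cm."""
        ages = np.asarray(X, dtype=float).reshape(-1)
        heights = np.asarray(y, dtype=float).reshape(-1)
        if ages.shape != heights.shape:
            raise ValueError("ages and heights must have equal length")
        if not (np.all(np.isfinite(ages)) and np.all(np.isfinite(heights))):
            raise ValueError("ages and heights must be finite")
        consts = self._consts()
        ages, heights = _qc_series(ages, heights, self.max_shrink_cm)
        self._validate_coverage(ages)

        candidates = presearch_grid(ages, heights, consts, top_m=self.n_starts)
        rng = np.random.default_rng(self.seed)
        jitter_scale = np.array([2.0, 2.0, 1.5, 0.05, 0.1, 0.3])

        def residuals(theta):
            return total_height(ages, QEPSParams.from_array(theta), consts) - heights

        starts = [candidates[0]]
        for i in range(1, self.n_starts):
            base = candidates[min(i, len(candidates) - 1)]
            starts.append(base + rng.normal(0.0, jitter_scale))

        best = None
        n_tried = 0
        for x0 in starts:
            x0 = np.clip(x0, _LOWER + 1e-9, _UPPER - 1e-9)
            x0[3:5] = np.maximum(x0[3:5], 0.5 + 1e-9)
            try:
                res = least_squares(
                    residuals,
                    x0,
                    bounds=(_LOWER, _UPPER),
                    x_scale=[10.0, 10.0, 5.0, 0.1, 0.1, 1.0],
                    ftol=1e-12,
                    xtol=1e-12,
                    gtol=1e-12,
                    method="trf",
                )
            except Exception:  # pragma: no cover - optimizer pathologies
                continue
            n_tried += 1
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError("all optimisation starts failed")

        self.params_ = QEPSParams.from_array(best.x)
        self.rmse_ = float(np.sqrt(2.0 * best.cost / ages.size))
        self.n_used_ = int(ages.size)
        self.converged_ = bool(best.status > 0)
        self.n_starts_tried_ = n_tried
        if not self.converged_:
            warnings.warn("QEPS fit did not converge on any start", RuntimeWarning)
        return self

    def predict(self, X):
        """Predicted total height (cm) at the given ages."""
        check_is_fitted(self, "params_")
        ages = np.asarray(X, dtype=float).reshape(-1)
        return total_height(ages, self.params_, self._consts())

    def result_(self) -> FitResult:
        check_is_fitted(self, "params_")
        return FitResult(
            params=self.params_,
            rmse=self.rmse_,
            n_used=self.n_used_,
            converged=self.converged_,
            n_starts_tried=self.n_starts_tried_,
        )


def fit_qeps(measurements, consts: ShapeConstants | None = None, **config) -> FitResult:
    """Functional wrapper: fit one subject's series of measurements.

    ``measurements`` is a sequence of :class:`HeightMeasurement` or
    ``(age, height)`` pairs; keyword arguments are forwarded to
    :class:`QEPSGrowthCurve`.
    """
    pairs = [
        (m.age, m.height) if isinstance(m, HeightMeasurement) else (m[0], m[1])
        for m in measurements
    ]
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise CoverageError("no measurements supplied")
    est = QEPSGrowthCurve(consts=consts, **config)
    est.fit(arr[:, 0], arr[:, 1])
    return est.result_()
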