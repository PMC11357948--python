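"""QEPS growth model: component functions, velocities, and milestone inversion.

The model decomposes height-for-age of an individual into four functions:

* ``Q`` — basic growth from early fetal life with linearly declining velocity,
  halted by a smooth multiplicative stop ``S``;
* ``E`` — an exponential component capturing rapid infancy growth that
  plateaus around 2 years of age;
* ``P`` — a specific pubertal spurt, a Richards-type sigmoid in age;
* ``S`` — a unit sigmoid "brake" on ``Q`` centred at the end of the pubertal
  spurt.

``QES = E + stopped Q`` is the basic growth curve and ``T = QES + P`` the
total growth curve.  Six individual parameters (three height scales, two time
scales, and the midpubertal age ``AgeP50``) modify shared shape constants to
give an individual growth curve from birth to adult height.

Ages are decimal years since birth; internally the model clock starts at
``t0 = -c0`` (about six weeks after conception), so model time is
``age + c0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit, spence

__all__ = [
    "ShapeConstants",
    "QEPSParams",
    "ComponentHeights",
    "p_fraction",
    "eval_components",
    "eval_velocity",
    "age_at_p_fraction",
    "age_at_p_velocity_peak",
    "age_at_total_velocity_peak",
]

_PI2_6 = math.pi**2 / 6.0


def _softplus(y):
    return np.logaddexp(0.0, y)


def _dilog_neg_exp(y):
    """Li2(-exp(y)), stable for any real y."""
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    small = y <= 30.0
    out[small] = spence(1.0 + np.exp(y[small]))
    big = ~small
    if np.any(big):
        yb = y[big]
        # inversion formula Li2(-z) = -pi^2/6 - ln(z)^2/2 - Li2(-1/z)
        out[big] = -_PI2_6 - 0.5 * yb**2 - spence(1.0 + np.exp(-yb))
    return out


@dataclass(frozen=True)
class ShapeConstants:
    """Shared (population) shape constants of the QEPS model.

    Parameters
    ----------
    c0 : float
        Prenatal offset in years: the model clock starts ``c0`` years before
        birth (around six weeks post-conception).
    thetaE : float
        E-function saturation time scale (years).  With the default, E has
        reached more than 95% of its plateau by age 2.
    tQ : float
        Age (years) at which the un-stopped Q velocity would decline to zero.
    nu : float
        Richards asymmetry of the P sigmoid (> 0).  ``nu > 1`` puts the peak
        P velocity slightly before ``AgeP50``, as observed in cohort data.
    sS : float
        Width (years) of the S stop sigmoid.
    pEnd : float
        P fraction operationally defining ``AgeP100`` (an asymptotic sigmoid
        needs a cutoff for "100%").
    p50_p5_gap : float
        Cohort-mean gap ``AgeP50 - AgeP5`` in years (at unit time scale) used
        to calibrate the P steepness ``k``.
    """

    c0: float = 0.65
    thetaE: float = 0.6
    tQ: float = 17.0
    nu: float = 1.3
    sS: float = 0.5
    pEnd: float = 0.999
    p50_p5_gap: float = 2.22

    def __post_init__(self):
        for name in ("c0", "thetaE", "tQ", "nu", "sS", "p50_p5_gap"):
            if not getattr(self, name) > 0:
                raise ValueError(f"ShapeConstants.{name} must be strictly positive")
        if not 0.5 < self.pEnd < 1.0:
            raise ValueError("ShapeConstants.pEnd must lie in (0.5, 1)")

    # -- derived steepness of the P sigmoid ---------------------------------
    def _w(self, p):
        """Unit-steepness Richards abscissa of fraction p."""
        p = np.asarray(p, dtype=float)
        return -np.log(np.power(p, -1.0 / self.nu) - 1.0)

    @property
    def k(self) -> float:
        """P steepness, calibrated so AgeP50 - AgeP5 = p50_p5_gap at Ptsc=1."""
        return float(self._w(0.5) - self._w(0.05)) / self.p50_p5_gap

    @property
    def phv_fraction(self) -> float:
        """P fraction achieved at the peak of the P velocity."""
        return (self.nu / (self.nu + 1.0)) ** self.nu

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ShapeConstants":
        return cls(**d)


@dataclass(frozen=True)
class QEPSParams:
    """Six individual growth parameters.

    ``Emax``, ``Qmax``, ``Pmax`` are height scales in cm (adult height gain
    contributed by E, the un-stopped Q plateau, and the total specific
    pubertal gain).  ``Etsc`` and ``Ptsc`` are dimensionless time-scale
    multipliers (about 1), and ``AgeP50`` the age in years at 50% of P.
    """

    Emax: float
    Qmax: float
    Pmax: float
    Etsc: float
    Ptsc: float
    AgeP50: float

    def __post_init__(self):
        if self.Emax < 0 or self.Qmax < 0 or self.Pmax < 0:
            raise ValueError("height scales Emax, Qmax, Pmax must be >= 0")
        if self.Etsc <= 0 or self.Ptsc <= 0:
            raise ValueError("time scales Etsc, Ptsc must be > 0")
        if not 5.0 < self.AgeP50 < 20.0:
            raise ValueError("AgeP50 must lie in (5, 20) years")

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.Emax, self.Qmax, self.Pmax, self.Etsc, self.Ptsc, self.AgeP50]
        )

    @classmethod
    def from_array(cls, a) -> "QEPSParams":
        return cls(*[float(v) for v in a])


@dataclass(frozen=True)
class ComponentHeights:
    """Heights (cm) of each model component at one age."""

    E: float
    Q: float
    QES: float
    P: float
    T: float


def _check_age(age, consts: ShapeConstants, allow_prenatal: bool = False):
    age = np.asarray(age, dtype=float)
    if not np.all(np.isfinite(age)):
        raise ValueError("age must be finite")
    if not allow_prenatal and np.any(age < -consts.c0):
        raise ValueError(f"age must be >= -c0 = {-consts.c0} (model origin t0)")
    return age


def p_fraction(age, params: QEPSParams, consts: ShapeConstants):
    """Normalized P sigmoid: fraction of the specific pubertal gain achieved.

    Strictly increasing in age, 0.5 at ``AgeP50`` by construction of the
    shifted Richards shape.
    """
    age = _check_age(age, consts, allow_prenatal=True)
    z = consts.k * (age - params.AgeP50) / params.Ptsc + float(consts._w(0.5))
    # (1 + e^-z)^-nu written as exp(-nu*softplus(-z)) for overflow safety
    return np.exp(-consts.nu * _softplus(-z))


def _p_velocity(age, params: QEPSParams, consts: ShapeConstants):
    """dP/dage in cm/year (analytic)."""
    age = np.asarray(age, dtype=float)
    z = consts.k * (age - params.AgeP50) / params.Ptsc + float(consts._w(0.5))
    # d/dz (1+e^-z)^-nu = nu (1-sigmoid(z)) (1+e^-z)^-nu
    sig = expit(z)
    base = np.exp(-consts.nu * _softplus(-z))
    return params.Pmax * consts.nu * base * (1.0 - sig) * consts.k / params.Ptsc


def _e_height(age, params, consts):
    tau = consts.thetaE * params.Etsc
    return params.Emax * (1.0 - np.exp(-(np.asarray(age) + consts.c0) / tau))


def _e_velocity(age, params, consts):
    tau = consts.thetaE * params.Etsc
    return params.Emax / tau * np.exp(-(np.asarray(age) + consts.c0) / tau)


def _q_vel_unbraked(age, params, consts):
    L = consts.tQ + consts.c0
    v = (2.0 * params.Qmax / L) * (1.0 - (np.asarray(age) + consts.c0) / L)
    return np.maximum(v, 0.0)


def _stop_center(params: QEPSParams, consts: ShapeConstants) -> float:
    """The S brake is centred at AgeP100 (growth stops as puberty completes)."""
    return age_at_p_fraction(consts.pEnd, params, consts)


def _q_braked_height(age, params: QEPSParams, consts: ShapeConstants):
    """Stopped-Q height: integral from t0 of (linear velocity) x (1 - S).

    The integrand is (b + m t) * sigmoid((A - t)/s) on [-c0, min(age, tQ)],
    which has a closed form in softplus and the dilogarithm.
    """
    age = np.asarray(age, dtype=float)
    if params.Qmax == 0.0:
        return np.zeros_like(age)
    L = consts.tQ + consts.c0
    m = -2.0 * params.Qmax / L**2
    b = 2.0 * params.Qmax / L + m * consts.c0  # b + m*t == qvel(t)
    A = _stop_center(params, consts)
    s = consts.sS

    def anti(t):
        y = (A - t) / s
        sp = _softplus(y)
        g = y * sp + _dilog_neg_exp(y)
        return -s * ((b + m * A) * sp - m * s * g)

    upper = np.minimum(age, consts.tQ)
    return anti(upper) - anti(np.full_like(age, -consts.c0))


def _q_braked_velocity(age, params, consts):
    A = _stop_center(params, consts)
    one_minus_s = expit(-(np.asarray(age) - A) / consts.sS)
    return _q_vel_unbraked(age, params, consts) * one_minus_s


def eval_components(age, params: QEPSParams, consts: ShapeConstants):
    """Evaluate E, Q (stopped), QES, P, and total T heights in cm.

    Scalar age returns :class:`ComponentHeights`; an array returns a dict of
    arrays with the same keys.
    """
    scalar = np.isscalar(age) or np.ndim(age) == 0
    a = _check_age(age, consts)
    E = _e_height(a, params, consts)
    Q = _q_braked_height(a, params, consts)
    P = params.Pmax * p_fraction(a, params, consts)
    QES = E + Q
    T = QES + P
    if scalar:
        return ComponentHeights(
            E=float(E), Q=float(Q), QES=float(QES), P=float(P), T=float(T)
        )
    return {"E": E, "Q": Q, "QES": QES, "P": P, "T": T}


def total_height(age, params: QEPSParams, consts: ShapeConstants):
    """Total T-function height in cm (vectorized fast path for fitting)."""
    a = np.asarray(age, dtype=float)
    return (
        _e_height(a, params, consts)
        + _q_braked_height(a, params, consts)
        + params.Pmax * p_fraction(a, params, consts)
    )


def eval_velocity(age, params: QEPSParams, consts: ShapeConstants):
    """Height velocities in cm/year per component and total (analytic)."""
    scalar = np.isscalar(age) or np.ndim(age) == 0
    a = _check_age(age, consts)
    vE = _e_velocity(a, params, consts)
    vQ = _q_braked_velocity(a, params, consts)
    vP = _p_velocity(a, params, consts)
    out = {"E": vE, "Q": vQ, "QES": vE + vQ, "P": vP, "T": vE + vQ + vP}
    if scalar:
        return {key: float(val) for key, val in out.items()}
    return out


def age_at_p_fraction(frac, params: QEPSParams, consts: ShapeConstants):
    """Inverse of :func:`p_fraction`: the unique age at which the given
    fraction of the specific pubertal gain is achieved."""
    f = np.asarray(frac, dtype=float)
    if np.any(~((f > 0.0) & (f < 1.0))):
        raise ValueError("frac must lie strictly in (0, 1)")
    age = params.AgeP50 + params.Ptsc * (consts._w(f) - consts._w(0.5)) / consts.k
    return float(age) if np.ndim(frac) == 0 else age


def age_at_p_velocity_peak(params: QEPSParams, consts: ShapeConstants) -> float:
    """Age of peak P-function velocity (AgeP_PHV).

    For a Richards sigmoid the inflection sits at fraction
    ``(nu/(nu+1))**nu``, before the midpoint when ``nu > 1``.
    """
    return age_at_p_fraction(consts.phv_fraction, params, consts)


def age_at_total_velocity_peak(params: QEPSParams, consts: ShapeConstants) -> float:
    """Age of the pubertal peak of total height velocity (AgeT_PHV).

    Height velocity declines monotonically from infancy, so the pubertal
    spurt shows up as an interior *local* maximum of total velocity.  The
    declining Q contribution pulls this peak slightly before the P-function's
    own peak.  The peak is located on a fine grid spanning the pubertal
    window and refined by bounded scalar optimisation; ``nan`` is returned
    when no interior peak exists (e.g. a negligible spurt), mirroring
    subjects for whom a total-curve PHV is undetectable.
    """
    from scipy.optimize import minimize_scalar

    lo = max(age_at_p_fraction(0.05, params, consts) - 2.0, 2.0)
    hi = age_at_p_fraction(consts.pEnd, params, consts)
    grid = np.linspace(lo, hi, 600)
    v = eval_velocity(grid, params, consts)["T"]
    interior = (v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:])
    idx = np.nonzero(interior)[0] + 1
    if idx.size == 0:
        return float("nan")
    i = int(idx[np.argmax(v[idx])])
    res = minimize_scalar(
        lambda t: -eval_velocity(float(t), params, consts)["T"],
        bounds=(grid[i - 1], grid[i + 1]),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)
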