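"""Power-law bottom-concentration model for sludge thickening.

The bottom concentration of a thickening test is modeled as

    X_d(t_s) = a * t_s**b

with ``t_s`` the thickening time in minutes, ``a`` the concentration at
t_s = 1 min (g/L) and ``b`` a dimensionless exponent.  The module provides
the calibration of (a, b) from a measured curve, forward prediction with a
mass-balance floor at the initial concentration, the sludge-blanket height
via the mass balance x * X_d = x0 * X0, the relative sensitivity of the
prediction to ``b``, and the return-sludge concentration X_r = k * X_d.

Units: time in minutes, concentrations in g/L, heights in m throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import optimize, stats

from .errors import (
    DomainError,
    FitWarning,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "ThickeningCurve",
    "PowerLawFit",
    "ReturnSludgeSpec",
    "Prediction",
    "fit_power_law",
    "predict_bottom_concentration",
    "sludge_height",
    "sensitivity_to_b",
    "return_concentration",
]


@dataclass(frozen=True)
class ThickeningCurve:
    """Measured bottom-concentration time series from a thickening test.

    Parameters
    ----------
    times : sequence of float
        Sampling times in minutes, strictly increasing, >= 0.
    concentrations : sequence of float
        Bottom concentrations in g/L, all > 0.
    plant_id : str
        Label of the originating plant/test.
    X0 : float, optional
        Initial (blanket) concentration in g/L.
    x0 : float, optional
        Initial blanket height in m.
    """

    times: np.ndarray
    concentrations: np.ndarray
    plant_id: str = ""
    X0: float | None = None
    x0: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if t.ndim != 1 or c.ndim != 1 or t.size != c.size:
            raise ValidationError("times and concentrations must be 1-D and equal length")
        if t.size and np.any(np.diff(t) <= 0):
            idx = int(np.argmax(np.diff(t) <= 0)) + 1
            raise ValidationError(f"times must be strictly increasing (row {idx})")
        if t.size and t[0] < 0:
            raise ValidationError("times must be >= 0")
        if np.any(c <= 0) or not np.all(np.isfinite(c)):
            raise ValidationError("all concentrations must be finite and > 0")
        if self.X0 is not None and self.X0 <= 0:
            raise ValidationError("X0 must be > 0")
        if self.x0 is not None and self.x0 <= 0:
            raise ValidationError("x0 must be > 0")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class PowerLawFit:
    """Calibrated power-law thickening model X_d = a * t_s**b.

    ``a`` is the bottom concentration at t_s = 1 min (g/L); ``b`` is
    dimensionless.  ``r_squared`` and ``p_value`` are computed on the
    fitting scale (log-log by default, see :func:`fit_power_law`).
    """

    a: float
    b: float
    r_squared: float
    p_value: float
    n_points: int
    scale: str = "log-log"
    warnings_: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValidationError("a must be > 0")
        if self.n_points < 3:
            raise ValidationError("n_points must be >= 3")

    def predict(self, t_s: float) -> float:
        """Evaluate a * t_s**b (no floor; see predict_bottom_concentration)."""
        return float(self.a * float(t_s) ** self.b)


class Prediction(NamedTuple):
    """A bottom-concentration prediction with its mass-balance clamp flag."""

    value: float
    clamped: bool

    def __float__(self) -> float:  # allow float(pred)
        return float(self.value)


@dataclass(frozen=True)
class ReturnSludgeSpec:
    """Return-sludge recycle factor ``k`` with its withdrawal method.

    Scraping fixes k = 0.7; suction allows k in [0.5, 0.7]; ``method=None``
    skips the method constraint and only requires k in (0, 1].
    """

    k: float
    method: str | None = "scrape"

    def __post_init__(self) -> None:
        if not (0.0 < self.k <= 1.0):
            raise ValidationError("k must be in (0, 1]")
        if self.method is None:
            return
        if self.method == "scrape":
            if abs(self.k - 0.7) > 1e-12:
                raise ValidationError("scrape withdrawal requires k = 0.7")
        elif self.method == "suction":
            if not (0.5 <= self.k <= 0.7):
                raise ValidationError("suction withdrawal requires k in [0.5, 0.7]")
        else:
            raise ValidationError(f"unknown withdrawal method: {self.method!r}")


def fit_power_law(curve: ThickeningCurve, refine: bool = False) -> PowerLawFit:
    """Fit X_d = a * t_s**b to a thickening curve.

    The fit is linear least squares of ln(X_d) on ln(t_s) (exact under
    multiplicative noise); points at t_s = 0 are excluded since the power
    law is degenerate there.  R² and the two-sided slope p-value are
    reported on the log-log scale.  With ``refine=True`` a nonlinear
    least-squares pass on the original scale, initialized from the
    log-log fit, replaces (a, b); diagnostics stay log-log.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 usable points with t_s > 0.
    """
    mask = curve.times > 0
    t = curve.times[mask]
    x = curve.concentrations[mask]
    if t.size < 3:
        raise InsufficientDataError(
            f"need >= 3 points with t_s > 0, got {t.size}"
        )
    res = stats.linregress(np.log(t), np.log(x))
    a = float(np.exp(res.intercept))
    b = float(res.slope)
    r2 = float(res.rvalue**2)
    p = float(res.pvalue)
    if math.isnan(p):  # zero-variance response (perfectly flat series)
        p = 1.0
    scale = "log-log"
    if refine:
        popt, _ = optimize.curve_fit(
            lambda tt, aa, bb: aa * tt**bb, t, x, p0=[a, b], maxfev=10000
        )
        a, b = float(popt[0]), float(popt[1])
        scale = "log-log+nls"
    notes: list[str] = []
    if not (0.0 <= b < 1.0):
        notes.append(f"exponent b={b:.4g} outside physically expected [0, 1)")
        warnings.warn(notes[-1], FitWarning, stacklevel=2)
    if t.size == 3:
        notes.append("p-value from a 1-dof t-test (n=3); fragile")
    return PowerLawFit(
        a=a, b=b, r_squared=r2, p_value=p, n_points=int(t.size),
        scale=scale, warnings_=tuple(notes),
    )


def predict_bottom_concentration(
    fit: PowerLawFit, t_s: float, X0: float | None = None
) -> Prediction:
    """Predict the bottom concentration a * t_s**b in g/L.

    If ``X0`` is given it acts as a floor: the mass balance forbids a
    bottom concentration below the initial concentration, so predictions
    under X0 are clamped to X0 and flagged.

    Raises
    ------
    DomainError
        If t_s < 1 min (below the model's calibrated time scale).
    """
    if t_s < 1.0:
        raise DomainError(f"t_s must be >= 1 min, got {t_s}")
    value = fit.predict(t_s)
    if X0 is not None:
        if X0 <= 0:
            raise ValidationError("X0 must be > 0")
        if value < X0:
            return Prediction(float(X0), True)
    return Prediction(value, False)


def sludge_height(fit: PowerLawFit, x0: float, X0: float, t_s: float) -> float:
    """Sludge blanket height x = x0 * X0 / X_d(t_s) in m.

    Mass balance: x * X_d = x0 * X0 holds exactly; with the X0 floor the
    height never exceeds x0.
    """
    if x0 <= 0:
        raise ValidationError("x0 must be > 0")
    pred = predict_bottom_concentration(fit, t_s, X0=X0)
    return float(x0 * X0 / pred.value)


def sensitivity_to_b(fit: PowerLawFit, t_s: float) -> float:
    """Relative sensitivity S = (dX_d/db) * (b / X_d) = b * ln(t_s).

    S quantifies the error in X_d from using an ensemble-mean exponent;
    it vanishes at t_s = 1 and grows logarithmically with time.
    """
    if t_s < 1.0:
        raise DomainError(f"t_s must be >= 1 min, got {t_s}")
    return float(fit.b * math.log(t_s))


def return_concentration(X_d: float, spec: ReturnSludgeSpec) -> float:
    """Return-sludge concentration X_r = k * X_d in g/L."""
    if X_d <= 0:
        raise ValidationError("X_d must be > 0")
    return float(spec.k * X_d)
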