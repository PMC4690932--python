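"""Hindered and compression settling velocities, compression-onset
detection, the integrated piecewise settling law, and solids-flux analysis.

Velocity conventions
--------------------
Interface heights are in m and times in minutes, so raw curve slopes are
m/min; every *public* velocity in this module is reported in m/h (the
field convention for Vesilind parameters).  The compression law

    v_cs(t_s) = (b*x0*X0/a) * t_s**(-1-b)            (time form)
    v_cs(X)   = (b*x0*X0/a) * (X/a)**(-(1+b)/b)      (concentration form)

is the exact derivative of the mass-balance blanket height
x = x0*X0/(a*t_s**b); the two forms are algebraically identical through
X = a*t_s**b.

The integrated model is piecewise: Vesilind v0*exp(-n*X) for X <= X_c and
the compression law above X_c.  No continuity condition is imposed at X_c;
the branch jump is reported, not hidden.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    BoundaryMinimumWarning,
    DomainError,
    InsufficientDataError,
    NoIntersectionError,
    NoLinearZoneError,
    NoOnsetError,
    ValidationError,
)

__all__ = [
    "BatchSettlingCurve",
    "VesilindFit",
    "CompressionLaw",
    "OnsetEstimate",
    "IntegratedSettlingModel",
    "FluxCurve",
    "LimitingFlux",
    "extract_hindered_velocity",
    "fit_vesilind",
    "compression_velocity",
    "compression_velocity_at_time",
    "detect_compression_onset",
    "integrated_velocity",
    "branch_crossover",
    "flux_curve",
    "limiting_flux",
]

MIN_PER_H = 60.0  # m/min -> m/h

#: Linearity threshold for accepting a hindered-zone window.
HINDERED_R2_MIN = 0.95
#: Minimum number of points in any tangent-fit window.
MIN_WINDOW = 4
#: Fraction of the log-time span used for the compression tangent.
COMPRESSION_TAIL_FRACTION = 0.25
#: Minimum angle (radians) between tangents for a detectable onset.
MIN_TANGENT_ANGLE = 0.05


@dataclass(frozen=True)
class BatchSettlingCurve:
    """Interface height vs time from one batch settling test.

    ``height_tol`` is the absolute tolerance (m) allowed for transient
    height increases due to measurement noise.
    """

    times: np.ndarray
    heights: np.ndarray
    X0: float
    x0: float
    plant_id: str = ""
    height_tol: float = 0.02

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        h = np.asarray(self.heights, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "heights", h)
        if t.ndim != 1 or h.ndim != 1 or t.size != h.size:
            raise ValidationError("times and heights must be 1-D and equal length")
        if t.size and np.any(np.diff(t) <= 0):
            idx = int(np.argmax(np.diff(t) <= 0)) + 1
            raise ValidationError(f"times must be strictly increasing (row {idx})")
        if self.X0 <= 0 or self.x0 <= 0:
            raise ValidationError("X0 and x0 must be > 0")
        if np.any(h <= 0):
            raise ValidationError("heights must be > 0")
        if np.any(h > self.x0 + self.height_tol):
            raise ValidationError("heights must not exceed initial height x0")
        rises = np.diff(h) > self.height_tol
        if np.any(rises):
            idx = int(np.argmax(rises)) + 1
            raise ValidationError(
                f"heights increase by more than height_tol at row {idx}"
            )

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class VesilindFit:
    """Hindered-settling law v = v0 * exp(-n * X); v0 in m/h, n in L/g."""

    v0: float
    n: float
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if self.v0 <= 0 or self.n <= 0:
            raise ValidationError("v0 and n must be > 0")

    def velocity(self, X) -> float:
        """Hindered settling velocity in m/h at concentration X (g/L)."""
        return self.v0 * np.exp(-self.n * np.asarray(X, dtype=float))


@dataclass(frozen=True)
class CompressionLaw:
    """Compression settling velocity law derived from the thickening fit.

    Carries (a, b) of the thickening power law plus the test's initial
    blanket height x0 (m) and concentration X0 (g/L).
    """

    a: float
    b: float
    x0: float
    X0: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.x0, self.X0) <= 0:
            raise ValidationError("all CompressionLaw fields must be > 0")
        if self.b >= 1:
            raise ValidationError("b must be < 1")

    @property
    def prefactor(self) -> float:
        """b*x0*X0/a, the velocity scale in m/min."""
        return self.b * self.x0 * self.X0 / self.a

    @property
    def exponent(self) -> float:
        """Magnitude of the concentration exponent, (1+b)/b."""
        return (1.0 + self.b) / self.b


@dataclass(frozen=True)
class OnsetEstimate:
    """Compression-onset location from the bisector-of-tangents method."""

    t_c: float
    X_c: float
    h_c: float
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class IntegratedSettlingModel:
    """Piecewise settling law: Vesilind below X_c, compression above."""

    vesilind: VesilindFit
    compression: CompressionLaw
    X_c: float

    def __post_init__(self) -> None:
        if self.X_c <= 0:
            raise ValidationError("X_c must be > 0")

    @property
    def jump_at_onset(self) -> float:
        """Hindered minus compression velocity at X_c (m/h); the branch
        discontinuity, reported rather than rescaled away."""
        vh = float(self.vesilind.velocity(self.X_c))
        vc = compression_velocity(self.compression, self.X_c, enforce_domain=False)
        return vh - vc


def _best_linear_window(
    t: np.ndarray, h: np.ndarray, r2_min: float = HINDERED_R2_MIN
) -> tuple[int, int, float, float, float]:
    """Best-R² early window (start in first third, length >= 4).

    Returns (start, stop, slope, intercept, r2); stop is exclusive.
    R² is rounded to 6 decimals for comparison so that noiseless curves
    (many exactly-linear windows) tie-break toward the longest window.
    """
    n = t.size
    if n < MIN_WINDOW + 2:
        raise InsufficientDataError(f"need >= {MIN_WINDOW + 2} points, got {n}")
    max_start = max(1, n // 3)
    best = None
    for start in range(max_start):
        for stop in range(start + MIN_WINDOW, n + 1):
            tw, hw = t[start:stop], h[start:stop]
            res = stats.linregress(tw, hw)
            r2 = res.rvalue**2 if not math.isnan(res.rvalue) else 0.0
            # perfectly flat windows have r=nan; treat as non-linear-zone
            if r2 < r2_min:
                continue
            key = (round(r2, 6), stop - start)
            if best is None or key > best[0]:
                best = (key, (start, stop, float(res.slope), float(res.intercept), float(r2)))
    if best is None:
        raise NoLinearZoneError(
            f"no early window of >= {MIN_WINDOW} points reaches R² >= {r2_min}"
        )
    return best[1]


def extract_hindered_velocity(curve: BatchSettlingCurve) -> float:
    """Hindered settling velocity (m/h) from the early linear segment.

    Searches contiguous windows starting within the first third of the
    record (min length 4) and keeps the longest one with R² >= 0.95; the
    velocity is minus its slope, converted to m/h.

    Raises
    ------
    NoLinearZoneError
        If no window passes the linearity threshold.
    """
    if len(curve) < 6:
        raise InsufficientDataError("need >= 6 points for hindered-zone search")
    _, _, slope, _, _ = _best_linear_window(curve.times, curve.heights)
    if slope >= 0:
        raise NoLinearZoneError("early linear segment does not settle (slope >= 0)")
    return float(-slope * MIN_PER_H)


def fit_vesilind(points: Sequence[tuple[float, float]]) -> VesilindFit:
    """Fit v = v0 * exp(-n * X) to (initial concentration, velocity) pairs.

    Least squares of ln(v) on X; X in g/L, v in m/h.
    """
    pts = [(float(x), float(v)) for x, v in points]
    if len(pts) < 3:
        raise InsufficientDataError(f"need >= 3 points, got {len(pts)}")
    X = np.array([p[0] for p in pts])
    v = np.array([p[1] for p in pts])
    if np.any(v <= 0):
        raise ValidationError("velocities must be > 0")
    if np.unique(X).size < 3:
        raise InsufficientDataError("need >= 3 distinct concentrations")
    res = stats.linregress(X, np.log(v))
    if res.slope >= 0:
        raise ValidationError("velocity does not decrease with concentration")
    return VesilindFit(
        v0=float(np.exp(res.intercept)),
        n=float(-res.slope),
        r_squared=float(res.rvalue**2),
    )


def compression_velocity(
    law: CompressionLaw, X: float, enforce_domain: bool = True
) -> float:
    """Compression settling velocity (m/h) at concentration X (g/L).

    v = (b*x0*X0/a) * (X/a)**(-(1+b)/b), converted m/min -> m/h.
    Strictly decreasing in X.  The law is only physical in the compression
    zone (X >= X0); pass ``enforce_domain=False`` to evaluate the bare
    algebraic form below X0 (used by branch-selection code and identity
    checks).
    """
    if X <= 0:
        raise DomainError(f"X must be > 0, got {X}")
    if enforce_domain and X < law.X0:
        raise DomainError(
            f"X={X} below compression zone (X0={law.X0}); "
            "pass enforce_domain=False for the bare algebraic form"
        )
    return float(law.prefactor * (X / law.a) ** (-law.exponent) * MIN_PER_H)


def compression_velocity_at_time(law: CompressionLaw, t_s: float) -> float:
    """Compression settling velocity (m/h) at thickening time t_s (min).

    v = (b*x0*X0/a) * t_s**(-1-b), converted m/min -> m/h.  Identical to
    ``compression_velocity`` evaluated at X = a * t_s**b.
    """
    if t_s < 1.0:
        raise DomainError(f"t_s must be >= 1 min, got {t_s}")
    return float(law.prefactor * t_s ** (-1.0 - law.b) * MIN_PER_H)


def detect_compression_onset(curve: BatchSettlingCurve) -> OnsetEstimate:
    """Locate the hindered-to-compression transition on a settling curve.

    Graphical construction: fit the hindered tangent (longest early linear
    window) and the compression tangent (OLS line over the final 25% of
    the record in log-time, min 4 points); intersect the two tangents;
    draw the interior angle bisector in normalized coordinates
    (t/t_max, h/x0) — angles are not affine-invariant, so the aspect
    ratio must be pinned — and intersect the bisector with the
    interpolated curve.  The onset concentration follows from the mass
    balance X_c = x0*X0/h_c.

    Raises
    ------
    NoOnsetError
        Missing hindered or compression zone, or tangents (near) parallel.
    NoIntersectionError
        Bisector does not meet the curve inside the record.
    """
    t, h = curve.times, curve.heights
    if len(curve) < 8:
        raise InsufficientDataError("need >= 8 points for onset detection")
    try:
        hs, he, h_slope, h_icpt, h_r2 = _best_linear_window(t, h)
    except NoLinearZoneError as exc:
        raise NoOnsetError(f"no hindered zone: {exc}") from exc
    if h_slope >= 0:
        raise NoOnsetError("early segment does not settle; no hindered zone")

    # compression tangent: points in the last 25% of the log-time span
    pos = t > 0
    tp = t[pos]
    log_lo, log_hi = math.log(tp[0]), math.log(tp[-1])
    cut = log_hi - COMPRESSION_TAIL_FRACTION * (log_hi - log_lo)
    tail = pos & (t >= math.exp(cut))
    if tail.sum() < MIN_WINDOW:
        tail = np.zeros_like(pos)
        tail[-MIN_WINDOW:] = True
    res = stats.linregress(t[tail], h[tail])
    c_slope, c_icpt = float(res.slope), float(res.intercept)

    # normalized coordinates: u = t/t_max, w = h/x0
    t_max, x0 = float(t[-1]), curve.x0
    mh = h_slope * t_max / x0  # hindered tangent slope in (u, w)
    mc = c_slope * t_max / x0
    dh = np.array([-1.0, -mh])  # along hindered tangent, back toward t=0
    dc = np.array([1.0, mc])  # along compression tangent, forward in time
    dh /= np.linalg.norm(dh)
    dc /= np.linalg.norm(dc)
    angle = math.acos(float(np.clip(np.dot(dh, dc), -1.0, 1.0)))
    # parallel rays (angle ~ pi) mean a single straight line: no onset
    if abs(math.pi - angle) < MIN_TANGENT_ANGLE:
        raise NoOnsetError("tangents are (near) parallel; no compression zone")

    # tangent intersection (vertex) in raw coordinates
    denom = h_slope - c_slope
    t_v = (c_icpt - h_icpt) / denom
    h_v = h_icpt + h_slope * t_v
    u_v, w_v = t_v / t_max, h_v / x0

    bis = dh + dc
    norm = np.linalg.norm(bis)
    if norm < 1e-12:
        raise NoOnsetError("degenerate bisector (opposed tangent rays)")
    bis /= norm

    u_grid = t / t_max
    w_grid = h / x0

    if abs(bis[0]) < 1e-9:
        # vertical bisector: onset at the vertex abscissa
        t_c = float(t_v)
        if not (t[0] <= t_c <= t[-1]):
            raise NoIntersectionError("vertex abscissa outside the record")
        h_c = float(np.interp(t_c, t, h))
    else:
        m_b = bis[1] / bis[0]
        # signed gap between the curve and the bisector line, along u
        def gap(u: float) -> float:
            return float(np.interp(u, u_grid, w_grid) - (w_v + m_b * (u - u_v)))

        us = np.linspace(u_grid[0], u_grid[-1], 2048)
        gs = np.array([gap(u) for u in us])
        sign_change = np.nonzero(np.diff(np.signbit(gs)))[0]
        if sign_change.size == 0:
            near_zero = np.abs(gs) < 1e-10
            if near_zero.any():
                u_c = float(us[int(np.argmin(np.abs(gs)))])
            else:
                raise NoIntersectionError(
                    "bisector does not intersect the curve within the record"
                )
        else:
            # crossing closest to the vertex abscissa
            i = sign_change[int(np.argmin(np.abs(us[sign_change] - u_v)))]
            u_c = float(optimize.brentq(gap, us[i], us[i + 1], xtol=1e-12))
        t_c = u_c * t_max
        h_c = float(np.interp(u_c, u_grid, w_grid)) * x0

    X_c = curve.x0 * curve.X0 / h_c
    return OnsetEstimate(
        t_c=float(t_c),
        X_c=float(X_c),
        h_c=float(h_c),
        diagnostics={
            "hindered_window": (int(hs), int(he)),
            "hindered_slope_m_per_min": h_slope,
            "hindered_r2": h_r2,
            "compression_slope_m_per_min": c_slope,
            "compression_n_points": int(np.count_nonzero(tail)),
            "vertex_t_min": float(t_v),
            "vertex_h_m": float(h_v),
            "tangent_angle_rad": float(angle),
        },
    )


def integrated_velocity(model: IntegratedSettlingModel, X: float) -> float:
    """Piecewise settling velocity (m/h): Vesilind for X <= X_c, the
    compression law for X > X_c.  Branch selection alone gates the
    compression law here (X_c may sit below the law's X0 when the onset
    was re-estimated)."""
    if X <= 0:
        raise DomainError(f"X must be > 0, got {X}")
    if X <= model.X_c:
        return float(model.vesilind.velocity(X))
    return compression_velocity(model.compression, X, enforce_domain=False)


def branch_crossover(
    vesilind: VesilindFit, compression: CompressionLaw,
    lo: float = 0.5, hi: float = 30.0,
) -> float:
    """Concentration (g/L) where the hindered and compression laws agree.

    Using this value as X_c makes the integrated law continuous and
    guarantees the compression branch never exceeds the hindered one
    above X_c (the compression law decays much faster).
    """
    def logdiff(X: float) -> float:
        vh = math.log(vesilind.v0) - vesilind.n * X
        vc = math.log(compression.prefactor * MIN_PER_H) - compression.exponent * math.log(
            X / compression.a
        )
        return vh - vc

    if logdiff(lo) * logdiff(hi) > 0:
        raise DomainError(f"no crossover in [{lo}, {hi}] g/L")
    return float(optimize.brentq(logdiff, lo, hi, xtol=1e-12))


@dataclass(frozen=True)
class FluxCurve:
    """Solids flux (v(X)+u)*X in kg/(m²·h) over a concentration grid,
    for both the integrated and the hindered-only velocity law.

    g/L ≡ kg/m³, so (m/h)·(g/L) is already kg/(m²·h): no numeric factor.
    """

    X: np.ndarray
    flux_integrated: np.ndarray
    flux_hindered: np.ndarray
    underflow_velocity: float


def flux_curve(
    model: IntegratedSettlingModel, u: float, X_grid: Sequence[float]
) -> FluxCurve:
    """Solids flux over a concentration grid for underflow velocity u (m/h)."""
    if u < 0:
        raise ValidationError("underflow velocity must be >= 0")
    X = np.asarray(list(X_grid), dtype=float)
    if X.size == 0:
        raise ValidationError("empty concentration grid")
    if np.any(X <= 0):
        raise ValidationError("concentration grid must be > 0")
    v_int = np.array([integrated_velocity(model, x) for x in X])
    v_hin = model.vesilind.velocity(X)
    return FluxCurve(
        X=X,
        flux_integrated=(v_int + u) * X,
        flux_hindered=(v_hin + u) * X,
        underflow_velocity=float(u),
    )


@dataclass(frozen=True)
class LimitingFlux:
    """Limiting (minimum) applied flux above X_c, for both variants."""

    flux_integrated: float
    X_integrated: float
    flux_hindered: float
    X_hindered: float
    underflow_velocity: float

    @property
    def overestimate_fraction(self) -> float:
        """(F_hindered - F_integrated) / F_integrated, >= 0 whenever the
        hindered-only law dominates above X_c."""
        return (self.flux_hindered - self.flux_integrated) / self.flux_integrated


def limiting_flux(
    model: IntegratedSettlingModel,
    u: float,
    X_max: float = 30.0,
    n_grid: int = 512,
) -> LimitingFlux:
    """Minimum of the applied flux (v(X)+u)*X over X in (X_c, X_max].

    Grid scan followed by bounded scalar minimization (golden/Brent) around
    the grid minimum; computed for the integrated and the hindered-only
    velocity laws so the hindered over-estimation can be reported.
    """
    if u <= 0:
        raise ValidationError("underflow velocity must be > 0 for a limiting flux")
    lo = model.X_c
    if X_max <= lo:
        raise ValidationError("X_max must exceed X_c")
    grid = np.linspace(lo, X_max, n_grid)

    def refine(f) -> tuple[float, float]:
        vals = np.array([f(x) for x in grid])
        i = int(np.argmin(vals))
        if i in (0, len(grid) - 1):
            warnings.warn(
                "flux minimum at the edge of the searched range",
                BoundaryMinimumWarning,
                stacklevel=3,
            )
            return float(vals[i]), float(grid[i])
        res = optimize.minimize_scalar(
            f, bounds=(grid[i - 1], grid[i + 1]), method="bounded",
            options={"xatol": 1e-10},
        )
        return float(res.fun), float(res.x)

    f_int, x_int = refine(lambda x: (integrated_velocity(model, x) + u) * x)
    f_hin, x_hin = refine(lambda x: (float(model.vesilind.velocity(x)) + u) * x)
    return LimitingFlux(
        flux_integrated=f_int,
        X_integrated=x_int,
        flux_hindered=f_hin,
        X_hindered=x_hin,
        underflow_velocity=float(u),
    )
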