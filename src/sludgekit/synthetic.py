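"""Seeded generators for synthetic thickening curves, batch settling
curves, cross-plant panels and floc images.

Every generator is deterministic under a fixed seed and returns the
generated artifact together with its ground truth, so each fitting
operation in the toolkit has a closed-loop recovery test.

Noise models: multiplicative lognormal for concentrations (positivity-
preserving), additive Gaussian for interface heights (instrument-like).
"""

from __future__ import annotations

import math
from typing import NamedTuple, Sequence

import numpy as np

from .errors import PlacementError, ValidationError
from .settling import BatchSettlingCurve
from .svi import PlantRecord
from .thickening import ThickeningCurve

__all__ = [
    "gen_thickening_curve",
    "gen_batch_settling_curve",
    "gen_plant_panel",
    "gen_floc_image_set",
    "FlocImageSet",
]


def gen_thickening_curve(
    a: float,
    b: float,
    n_points: int = 30,
    time_range: tuple[float, float] = (1.0, 90.0),
    noise_level: float = 0.0,
    seed: int | None = 0,
    plant_id: str = "synthetic",
    X0: float | None = None,
    x0: float | None = None,
) -> tuple[ThickeningCurve, dict]:
    """Thickening curve X_d(t) = a * t**b * exp(eps), eps ~ N(0, noise).

    Times are log-spaced over ``time_range`` (power-law information is
    uniform in log time).  Returns (curve, ground_truth).
    """
    if a <= 0 or b < 0:
        raise ValidationError("a must be > 0 and b >= 0")
    if n_points < 3:
        raise ValidationError("n_points must be >= 3")
    lo, hi = time_range
    if not (0 < lo < hi):
        raise ValidationError("time_range must satisfy 0 < lo < hi")
    if noise_level < 0:
        raise ValidationError("noise_level must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.geomspace(lo, hi, n_points)
    eps = rng.normal(0.0, noise_level, n_points) if noise_level > 0 else np.zeros(n_points)
    conc = a * t**b * np.exp(eps)
    curve = ThickeningCurve(
        times=t, concentrations=conc, plant_id=plant_id, X0=X0, x0=x0
    )
    truth = {"a": a, "b": b, "noise_level": noise_level, "seed": seed}
    return curve, truth


def gen_batch_settling_curve(
    v_hindered: float,
    t_star: float,
    b: float,
    x0: float = 1.0,
    X0: float = 6.6,
    t_max: float = 90.0,
    n_points: int = 46,
    noise_level: float = 0.0,
    seed: int | None = 0,
    plant_id: str = "synthetic",
) -> tuple[BatchSettlingCurve, dict]:
    """Two-phase settling curve: hindered line then mass-balance tail.

    h(t) = x0 - v*t for t <= t*, and h(t) = x0*X0/(a*t**b) after, with
    ``a`` solved so the branches meet exactly at t* (height-continuous).
    ``v_hindered`` is in m/min (curve-slope units); the ground truth also
    records it in m/h.  Additive Gaussian noise of sd noise_level * x0.

    Raises
    ------
    ValidationError
        Parameters give non-positive heights at t* (over-settled).
    """
    if v_hindered < 0:
        raise ValidationError("v_hindered must be >= 0")
    if not (0 < t_star < t_max):
        raise ValidationError("t_star must be inside (0, t_max)")
    if not (0 < b < 1):
        raise ValidationError("b must be in (0, 1)")
    h_star = x0 - v_hindered * t_star
    if h_star <= 0:
        raise ValidationError("hindered line reaches zero height before t*")
    # continuity: x0 - v t* = x0 X0 / (a t*^b)
    a = x0 * X0 / (h_star * t_star**b)
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_max, n_points)
    if v_hindered == 0:
        # degenerate: no settling at all, the interface never moves
        h = np.full(n_points, float(x0))
    else:
        h = np.where(t <= t_star, x0 - v_hindered * t, 0.0)
        tail = t > t_star
        h[tail] = x0 * X0 / (a * t[tail] ** b)
    if noise_level > 0:
        h = h + rng.normal(0.0, noise_level * x0, n_points)
        h = np.clip(h, 1e-6, x0)
    tol = max(0.02, 6.0 * noise_level * x0)
    curve = BatchSettlingCurve(
        times=t, heights=h, X0=X0, x0=x0, plant_id=plant_id, height_tol=tol
    )
    truth = {
        "v_hindered_m_per_min": v_hindered,
        "v_hindered_m_per_h": v_hindered * 60.0,
        "t_star": t_star,
        "a": a,
        "b": b,
        "x0": x0,
        "X0": X0,
        "X_star": a * t_star**b,
        "noise_level": noise_level,
        "seed": seed,
    }
    return curve, truth


def gen_plant_panel(
    alpha: float,
    beta: float,
    svis: Sequence[float],
    noise_level: float = 0.0,
    b_mean: float = 0.0465,
    b_spread: float = 0.0,
    seed: int | None = 0,
) -> tuple[list[PlantRecord], dict]:
    """Cross-plant panel with a = alpha*ln(SVI) + beta plus relative noise
    and b ~ N(b_mean, b_spread)."""
    svis = [float(s) for s in svis]
    if any(s <= 0 for s in svis):
        raise ValidationError("all SVI values must be > 0")
    if noise_level < 0 or b_spread < 0:
        raise ValidationError("noise_level and b_spread must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    for i, s in enumerate(svis):
        a_clean = alpha * math.log(s) + beta
        if a_clean <= 0:
            raise ValidationError(f"alpha/beta give non-positive a at SVI={s}")
        eps = rng.normal(0.0, noise_level) if noise_level > 0 else 0.0
        b_i = rng.normal(b_mean, b_spread) if b_spread > 0 else b_mean
        records.append(
            PlantRecord(f"plant{i + 1}", svi=s, a=a_clean * (1.0 + eps), b=b_i)
        )
    truth = {"alpha": alpha, "beta": beta, "b_mean": b_mean, "seed": seed}
    return records, truth


class FlocImageSet(NamedTuple):
    """Synthetic floc field: image, per-blob ground truth, generator spec."""

    image: np.ndarray
    truth: list[dict]
    spec: dict


def _blob_boundary(
    rng: np.random.Generator,
    r0: float,
    roughness: float,
    wavelength_px: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Radial boundary r(theta) = r0 * (1 + roughness * f(theta)).

    f is a random Fourier series normalized to max |f| = 1 whose highest
    harmonic keeps a fixed *spatial* wavelength (``wavelength_px``), so
    larger blobs carry proportionally more wiggles.  That scale coupling
    is what makes the population's area-perimeter slope drop below 2
    (boundary dimension above 1) as roughness grows; scale-invariant
    wiggles would only rescale perimeters and leave the slope at exactly 2.
    Returns (theta, r(theta)).
    """
    k_max = max(3, int(2.0 * math.pi * r0 / wavelength_px))
    n_theta = max(256, 16 * k_max)
    theta = np.linspace(0.0, 2.0 * math.pi, n_theta, endpoint=False)
    if roughness == 0:
        return theta, np.full(n_theta, r0)
    f = np.zeros(n_theta)
    ks = np.arange(2, k_max + 1)
    coeffs = rng.normal(size=(ks.size, 2)) / np.sqrt(ks)[:, None]
    for (ck, sk), k in zip(coeffs, ks):
        f += ck * np.cos(k * theta) + sk * np.sin(k * theta)
    peak = np.abs(f).max()
    if peak > 0:
        f /= peak
    return theta, r0 * (1.0 + roughness * f)


def gen_floc_image_set(
    n_flocs: int = 12,
    radius_range: tuple[float, float] = (8.0, 40.0),
    roughness: float = 0.0,
    image_size: tuple[int, int] = (512, 512),
    n_border: int = 0,
    wavelength_px: float = 3.0,
    seed: int | None = 0,
    max_retries: int = 2000,
) -> FlocImageSet:
    """Raster of non-overlapping rough blobs with per-blob ground truth.

    ``n_border`` extra blobs are deliberately placed straddling the image
    edge (they should be discarded by border-excluding measurement).
    Foreground value 255, background 0 (uint8).

    Raises
    ------
    PlacementError
        Cannot place all interior blobs without overlap within the retry
        budget.
    """
    if not (0.0 <= roughness <= 0.5):
        raise ValidationError("roughness must be in [0, 0.5]")
    r_lo, r_hi = radius_range
    if not (0 < r_lo <= r_hi):
        raise ValidationError("radius_range must satisfy 0 < lo <= hi")
    from skimage.draw import polygon as draw_polygon

    rng = np.random.default_rng(seed)
    H, W = image_size
    img = np.zeros((H, W), dtype=np.uint8)
    placed: list[tuple[float, float, float]] = []  # (row, col, rmax)
    truth: list[dict] = []

    def try_place(border: bool) -> bool:
        for _ in range(max_retries):
            r0 = rng.uniform(r_lo, r_hi)
            rmax = r0 * (1.0 + roughness)
            if border:
                # center on a randomly chosen edge
                edge = rng.integers(4)
                if edge == 0:
                    cr, cc = 0.0, rng.uniform(rmax, W - rmax)
                elif edge == 1:
                    cr, cc = float(H - 1), rng.uniform(rmax, W - rmax)
                elif edge == 2:
                    cr, cc = rng.uniform(rmax, H - rmax), 0.0
                else:
                    cr, cc = rng.uniform(rmax, H - rmax), float(W - 1)
            else:
                margin = rmax + 3.0
                if 2 * margin >= min(H, W):
                    continue
                cr = rng.uniform(margin, H - margin)
                cc = rng.uniform(margin, W - margin)
            ok = all(
                math.hypot(cr - pr, cc - pc) > rmax + prm + 3.0
                for pr, pc, prm in placed
            )
            if not ok:
                continue
            theta, radii = _blob_boundary(rng, r0, roughness, wavelength_px)
            rr = cr + radii * np.sin(theta)
            cc_arr = cc + radii * np.cos(theta)
            poly_r, poly_c = draw_polygon(rr, cc_arr, shape=(H, W))
            img[poly_r, poly_c] = 255
            placed.append((cr, cc, rmax))
            truth.append(
                {
                    "center": (cr, cc),
                    "r0": r0,
                    "roughness": roughness,
                    "touches_border": border,
                    "area_first_order": math.pi * r0**2,
                }
            )
            return True
        return False

    for _ in range(n_flocs):
        if not try_place(border=False):
            raise PlacementError(
                f"could not place {n_flocs} non-overlapping blobs "
                f"(placed {len(placed)})"
            )
    for _ in range(n_border):
        if not try_place(border=True):
            raise PlacementError("could not place border-touching blob")

    spec = {
        "n_flocs": n_flocs,
        "n_border": n_border,
        "radius_range": radius_range,
        "roughness": roughness,
        "image_size": image_size,
        "seed": seed,
    }
    return FlocImageSet(image=img, truth=truth, spec=spec)
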