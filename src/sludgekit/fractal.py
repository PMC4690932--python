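"""Floc fractal morphometry: per-floc measurements from grayscale images
and log-log scaling exponents.

Scaling relations fitted over a floc population:

    A ∝ P**D2        (planar dimension, slope of log A on log P)
    V ∝ P**D3        (volumetric dimension, slope of log V on log P)
    A ∝ P**(2/DB)    (boundary dimension, DB = 2 / slope)

D2 and DB are algebraically coupled when estimated from the same (A, P)
pairs (D2 * DB = 2); they are still reported side by side because field
practice derives them from different perimeter operationalizations, and
``fit_fractal_dimensions`` accepts separate boundary-resolution perimeters
for DB when available.

Volume is not observable from a 2-D image; the default model is the
area-equivalent sphere V = (4/3)π (A/π)^{3/2}, pluggable at measurement
time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from skimage import filters, measure

from .errors import (
    InsufficientDataError,
    InsufficientSpreadError,
    ValidationError,
)

__all__ = [
    "FlocMeasurement",
    "FractalEstimates",
    "SviTrend",
    "measure_flocs",
    "fit_fractal_dimensions",
    "svi_fractal_trend",
]


@dataclass(frozen=True)
class FlocMeasurement:
    """Per-floc area (length²), perimeter (length) and modeled volume
    (length³); units are px-based unless a scale was applied."""

    floc_id: str
    area: float
    perimeter: float
    volume: float

    def __post_init__(self) -> None:
        if min(self.area, self.perimeter, self.volume) <= 0:
            raise ValidationError("area, perimeter and volume must be > 0")
        # isoperimetric inequality P² >= 4πA; 10% slack because smoothed
        # contours of few-pixel regions undershoot the true perimeter
        if self.perimeter**2 < 4.0 * math.pi * self.area * 0.90:
            raise ValidationError(
                f"floc {self.floc_id}: P²={self.perimeter**2:.4g} violates "
                f"the isoperimetric bound 4πA={4 * math.pi * self.area:.4g}"
            )


@dataclass(frozen=True)
class FractalEstimates:
    """Population-level fractal dimensions with regression standard errors."""

    D2: float
    D3: float
    DB: float
    se_D2: float
    se_D3: float
    se_DB: float
    n_flocs: int


@dataclass(frozen=True)
class SviTrend:
    """Signed OLS slopes of each fractal dimension against SVI."""

    slope_D2: float
    slope_D3: float
    slope_DB: float
    p_D2: float
    p_D3: float
    p_DB: float
    n_plants: int


def _contour_perimeter(mask: np.ndarray) -> float:
    """Marching-squares contour length of a binary region mask.

    The raw 0.5-level contour of a binary mask overestimates a disk's
    perimeter by ~7% (pixel staircase), so the contour polygon is
    smoothed with a short circular moving average before its length is
    summed.
    """
    padded = np.pad(mask.astype(float), 2)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return 0.0
    c = max(contours, key=len)
    closed = bool(np.allclose(c[0], c[-1]))
    if closed:
        c = c[:-1]
    n = len(c)
    if n < 4:
        d = np.diff(np.vstack([c, c[:1]]), axis=0)
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))
    d_raw = np.diff(np.vstack([c, c[:1]]), axis=0)
    length_raw = float(np.sum(np.hypot(d_raw[:, 0], d_raw[:, 1])))
    # circular moving average over ~4 px of arc length: removes the
    # pixel staircase (whose runs grow like sqrt(r) on smooth arcs) while
    # leaving genuine boundary structure at larger wavelengths mostly
    # intact
    pts_per_px = n / max(length_raw, 1e-9)
    # cap the window for small closed contours: averaging over a large
    # angular span shrinks the polygon toward its centroid
    win_px = min(4.0, length_raw / 15.0)
    win = max(3, int(round(win_px * pts_per_px)) | 1)
    win = min(win, n if n % 2 else n - 1)
    kernel = np.ones(win) / win
    half = win // 2
    sm = np.column_stack(
        [
            np.convolve(np.r_[c[-half:, i], c[:, i], c[:half, i]], kernel, mode="valid")
            for i in (0, 1)
        ]
    )
    d = np.diff(np.vstack([sm, sm[:1]]), axis=0)
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def _sphere_volume(area: float) -> float:
    r_eq = math.sqrt(area / math.pi)
    return 4.0 / 3.0 * math.pi * r_eq**3


def measure_flocs(
    image: np.ndarray,
    threshold_method: str = "otsu",
    min_area: float = 10.0,
    scale: float = 1.0,
    exclude_border: bool = True,
    volume_model=_sphere_volume,
) -> list[FlocMeasurement]:
    """Segment a grayscale image into flocs and measure (A, P, V).

    Pipeline: global threshold (default Otsu; "mean" also supported, or a
    numeric threshold), 8-connected component labeling, discard
    border-touching components and components below ``min_area`` (px²).
    A is the pixel count, P the marching-squares contour length, V comes
    from ``volume_model(area)``.  ``scale`` (length units per px)
    converts all outputs.

    Returns an empty list (with a warning) when nothing survives the
    filters — an empty field of view is data, not an error.
    """
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise ValidationError("image must be a non-empty 2-D grayscale array")
    if min_area < 4:
        raise ValidationError("min_area must be >= 4 px²")
    if isinstance(threshold_method, (int, float)) and not isinstance(
        threshold_method, bool
    ):
        thresh = float(threshold_method)
    elif threshold_method == "otsu":
        thresh = filters.threshold_otsu(img)
    elif threshold_method == "mean":
        thresh = float(img.mean())
    else:
        raise ValidationError(f"unknown threshold method {threshold_method!r}")
    binary = img > thresh
    labels = measure.label(binary, connectivity=2)
    out: list[FlocMeasurement] = []
    h, w = labels.shape
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        if exclude_border:
            r0, c0, r1, c1 = region.bbox
            if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
                continue
        perim_px = _contour_perimeter(region.image)
        if perim_px <= 0:
            continue
        area = float(region.area) * scale**2
        perim = perim_px * scale
        out.append(
            FlocMeasurement(
                floc_id=f"floc{region.label}",
                area=area,
                perimeter=perim,
                volume=volume_model(area),
            )
        )
    if not out:
        warnings.warn("no flocs survived segmentation filters", UserWarning, stacklevel=2)
    return out


def fit_fractal_dimensions(
    measurements: Sequence[FlocMeasurement],
    boundary_perimeters: Sequence[float] | None = None,
) -> FractalEstimates:
    """Fit D2, D3 and DB over a floc population by log-log OLS.

    D2 = slope(log A ~ log P); D3 = slope(log V ~ log P);
    DB = 2 / slope(log A ~ log P_b) where P_b defaults to P but may be a
    separate boundary-resolution perimeter per floc.

    Raises
    ------
    InsufficientDataError
        Fewer than 5 measurements.
    InsufficientSpreadError
        All perimeters equal (nothing to regress on).
    """
    ms = list(measurements)
    if len(ms) < 5:
        raise InsufficientDataError(f"need >= 5 flocs, got {len(ms)}")
    P = np.array([m.perimeter for m in ms])
    A = np.array([m.area for m in ms])
    V = np.array([m.volume for m in ms])
    if np.unique(P).size < 2:
        raise InsufficientSpreadError("all perimeters equal; no spread to fit")
    if P.max() / P.min() < 10.0:
        warnings.warn(
            "perimeters span less than one decade; slopes may be unstable",
            UserWarning,
            stacklevel=2,
        )
    logP = np.log(P)
    r2 = stats.linregress(logP, np.log(A))
    r3 = stats.linregress(logP, np.log(V))
    if boundary_perimeters is not None:
        Pb = np.asarray(list(boundary_perimeters), dtype=float)
        if Pb.size != len(ms) or np.any(Pb <= 0):
            raise ValidationError("boundary_perimeters must match measurements, > 0")
        rb = stats.linregress(np.log(Pb), np.log(A))
    else:
        rb = r2
    if rb.slope <= 0:
        raise InsufficientSpreadError("non-positive area-perimeter slope; DB undefined")
    DB = 2.0 / rb.slope
    se_DB = 2.0 / rb.slope**2 * rb.stderr  # delta method
    return FractalEstimates(
        D2=float(r2.slope),
        D3=float(r3.slope),
        DB=float(DB),
        se_D2=float(r2.stderr),
        se_D3=float(r3.stderr),
        se_DB=float(se_DB),
        n_flocs=len(ms),
    )


def svi_fractal_trend(
    estimates_by_plant: Sequence[tuple[float, FractalEstimates]],
) -> SviTrend:
    """OLS slope (with p-value) of each fractal dimension against SVI.

    Purely descriptive: signs summarize how morphology tracks
    settleability across plants, with no causal claim.
    """
    pairs = list(estimates_by_plant)
    if len(pairs) < 3:
        raise InsufficientDataError(f"need >= 3 plants, got {len(pairs)}")
    svi = np.array([p[0] for p in pairs], dtype=float)
    slopes = {}
    for name in ("D2", "D3", "DB"):
        y = np.array([getattr(p[1], name) for p in pairs], dtype=float)
        res = stats.linregress(svi, y)
        p_val = float(res.pvalue)
        if math.isnan(p_val):  # constant response
            p_val = 1.0
        slope = float(res.slope)
        if abs(slope) < 1e-15:
            slope = 0.0
        slopes[name] = (slope, p_val)
    return SviTrend(
        slope_D2=slopes["D2"][0],
        slope_D3=slopes["D3"][0],
        slope_DB=slopes["DB"][0],
        p_D2=slopes["D2"][1],
        p_D3=slopes["D3"][1],
        p_DB=slopes["DB"][1],
        n_plants=len(pairs),
    )
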