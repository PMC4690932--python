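"""Cross-plant log-linear link between settleability (SVI) and the
thickening prefactor ``a``:  a = alpha * ln(SVI) + beta.

Two presets ship with the toolkit:

* ``printed`` — the coefficients as published by the upstream calibration
  (alpha = -5.754, beta = 26.862).  These are internally inconsistent with
  the four-plant record table they were said to come from (they predict
  a = 3.37 at SVI = 59.3 where the table lists 11.73), so they are kept
  verbatim but tagged.
* ``refit`` — an ordinary least-squares refit of the four-plant reference
  records, reproducible from printed data.  This is the default preset
  for prediction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    DomainError,
    InsufficientDataError,
    ValidationError,
    ValidityWarning,
)

__all__ = [
    "PlantRecord",
    "SviLinkModel",
    "REFERENCE_PLANTS",
    "REFERENCE_VALIDATION_PLANT",
    "fit_svi_link",
    "predict_a",
    "printed_link_model",
    "refit_link_model",
    "link_model_preset",
]


@dataclass(frozen=True)
class PlantRecord:
    """One plant's settleability record: SVI (mL/g) and fitted (a, b)."""

    plant_id: str
    svi: float
    a: float
    b: float | None = None

    def __post_init__(self) -> None:
        if self.svi <= 0:
            raise ValidationError(f"svi must be > 0, got {self.svi}")
        if self.a <= 0:
            raise ValidationError(f"a must be > 0, got {self.a}")


#: Four-plant reference calibration panel (SVI in mL/g, a in g/L, b unitless).
REFERENCE_PLANTS: tuple[PlantRecord, ...] = (
    PlantRecord("plant1", svi=59.3, a=11.73, b=0.0496),
    PlantRecord("plant2", svi=59.6, a=11.54, b=0.0460),
    PlantRecord("plant3", svi=71.8, a=10.59, b=0.0500),
    PlantRecord("plant4", svi=201.8, a=6.74, b=0.0402),
)

#: Held-out validation plant: SVI 230.5 mL/g, published a = 6.493,
#: initial blanket X0 = 6.600 g/L at x0 = 1 m.
REFERENCE_VALIDATION_PLANT = PlantRecord("plant5", svi=230.5, a=6.493, b=0.0465)

#: Initial blanket conditions of the validation plant's thickening test.
REFERENCE_VALIDATION_X0 = 6.600  # g/L
REFERENCE_VALIDATION_x0 = 1.0  # m


@dataclass(frozen=True)
class SviLinkModel:
    """Log-linear map a = alpha * ln(SVI) + beta with validity metadata.

    ``provenance`` is either ``"printed"`` (as-published coefficients) or
    ``"refit"`` (reproduced from the reference panel); ``log_base`` is
    "e" or "10" — the natural log is the documented form, base 10 is
    exposed only for sensitivity analysis.
    """

    alpha: float
    beta: float
    r_squared: float
    p_value: float
    svi_validity: tuple[float, float]
    xd_validity: tuple[float, float] | None
    mean_b: float | None
    provenance: str = "refit"
    log_base: str = "e"
    note: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.svi_validity
        if not lo < hi:
            raise ValidationError("svi_validity must satisfy lower < upper")

    def _log(self, x: float) -> float:
        return math.log10(x) if self.log_base == "10" else math.log(x)


def fit_svi_link(records, log_base: str = "e") -> SviLinkModel:
    """OLS of a on log(SVI) over plant records.

    ``mean_b`` is the arithmetic mean of the available b values; validity
    ranges are set from the data envelope.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 records, or all SVI values equal.
    """
    records = list(records)
    if len(records) < 3:
        raise InsufficientDataError(f"need >= 3 plant records, got {len(records)}")
    svi = np.array([r.svi for r in records], dtype=float)
    a = np.array([r.a for r in records], dtype=float)
    if np.unique(svi).size < 2:
        raise InsufficientDataError("all SVI values equal; cannot regress")
    logsvi = np.log10(svi) if log_base == "10" else np.log(svi)
    res = stats.linregress(logsvi, a)
    bs = [r.b for r in records if r.b is not None]
    mean_b = float(np.mean(bs)) if bs else None
    p = float(res.pvalue)
    if math.isnan(p):
        p = 1.0
    return SviLinkModel(
        alpha=float(res.slope),
        beta=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=p,
        svi_validity=(float(svi.min()), float(svi.max())),
        xd_validity=None,
        mean_b=mean_b,
        provenance="refit",
        log_base=log_base,
    )


def predict_a(model: SviLinkModel, svi: float) -> float:
    """Predict the thickening prefactor a (g/L) from SVI (mL/g).

    Emits a :class:`ValidityWarning` when SVI falls outside the model's
    calibrated range; raises :class:`DomainError` for svi <= 0.
    """
    if svi <= 0:
        raise DomainError(f"svi must be > 0, got {svi}")
    lo, hi = model.svi_validity
    if not lo <= svi <= hi:
        warnings.warn(
            f"SVI {svi} outside calibrated range [{lo}, {hi}] mL/g",
            ValidityWarning,
            stacklevel=2,
        )
    return float(model.alpha * model._log(svi) + model.beta)


def printed_link_model() -> SviLinkModel:
    """The as-published link model (alpha = -5.754, beta = 26.862).

    Kept verbatim for reference; tagged because the coefficients do not
    reproduce the reference panel they were attributed to.
    """
    return SviLinkModel(
        alpha=-5.754,
        beta=26.862,
        r_squared=0.988,
        p_value=3.02e-4,
        svi_validity=(59.3, 248.4),
        xd_validity=(7.95, 14.81),
        mean_b=0.0465,
        provenance="printed",
        log_base="e",
        note="as-printed coefficients; internally inconsistent with the "
        "four-plant reference panel",
    )


def refit_link_model(log_base: str = "e") -> SviLinkModel:
    """OLS refit of the four-plant reference panel (default preset)."""
    return fit_svi_link(REFERENCE_PLANTS, log_base=log_base)


def link_model_preset(name: str) -> SviLinkModel:
    """Look up a named preset: 'printed' or 'refit'."""
    if name == "printed":
        return printed_link_model()
    if name == "refit":
        return refit_link_model()
    raise DomainError(f"unknown preset {name!r}; expected 'printed' or 'refit'")
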