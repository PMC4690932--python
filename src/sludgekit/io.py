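"""Readers/writers for the toolkit's CSV and JSON dialects plus run
configuration.

CSV dialects (comment lines start with ``#``, decimal point only):

* thickening: header ``time_min,conc_g_L``
* batch settling: header ``time_min,height_m``
* plants: header ``plant_id,svi_mL_g,a,b``
* floc measurements: header ``floc_id,area,perimeter,volume``

Model JSON documents carry explicit units, a provenance tag and the
toolkit version; reading inverts writing exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import FormatError, SchemaError, ValidationError
from .fractal import FlocMeasurement
from .settling import (
    BatchSettlingCurve,
    CompressionLaw,
    IntegratedSettlingModel,
    VesilindFit,
)
from .svi import PlantRecord, SviLinkModel
from .thickening import PowerLawFit, ThickeningCurve

__all__ = [
    "RunConfig",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "read_plants_csv",
    "write_plants_csv",
    "read_floc_csv",
    "write_floc_csv",
    "write_model_json",
    "read_model_json",
]

ALLOWED_UNITS = {
    "time": "min",
    "length": "m",
    "concentration": "g/L",
    "svi": "mL/g",
    "velocity": "m/h",
}

_TS_COLUMNS = {
    "thickening": ("time_min", "conc_g_L"),
    "batch": ("time_min", "height_m"),
}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration (units, recycle, plant metadata)."""

    k: float = 0.7
    method: str = "scrape"
    x0: float | None = None
    X0: float | None = None
    svi: float | None = None
    plant_id: str = ""
    preset: str = "refit"
    seed: int = 0
    verbosity: int = 0
    units: dict = field(default_factory=lambda: dict(ALLOWED_UNITS))

    def __post_init__(self) -> None:
        for key, val in self.units.items():
            if key not in ALLOWED_UNITS:
                raise ValidationError(f"unknown unit key {key!r}")
            if val != ALLOWED_UNITS[key]:
                raise ValidationError(
                    f"unsupported unit {val!r} for {key!r}; expected {ALLOWED_UNITS[key]!r}"
                )
        if self.preset not in ("printed", "refit"):
            raise ValidationError(f"unknown preset {self.preset!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _read_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface as dialect error
        raise FormatError(f"{path}: not parseable as CSV ({exc})") from exc
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def read_timeseries_csv(
    path: str | Path,
    kind: str,
    plant_id: str = "",
    X0: float | None = None,
    x0: float | None = None,
    height_tol: float = 0.02,
):
    """Read a thickening or batch-settling time series.

    ``kind`` is "thickening" or "batch"; batch curves additionally
    require X0 (g/L) and x0 (m) from the caller/config.
    """
    if kind not in _TS_COLUMNS:
        raise ValidationError(f"kind must be 'thickening' or 'batch', got {kind!r}")
    tcol, vcol = _TS_COLUMNS[kind]
    df = _read_csv(path, (tcol, vcol))
    t = df[tcol].to_numpy(dtype=float)
    v = df[vcol].to_numpy(dtype=float)
    if kind == "thickening":
        return ThickeningCurve(
            times=t, concentrations=v, plant_id=plant_id, X0=X0, x0=x0
        )
    if X0 is None or x0 is None:
        raise ValidationError("batch curves require X0 and x0")
    return BatchSettlingCurve(
        times=t, heights=v, X0=X0, x0=x0, plant_id=plant_id, height_tol=height_tol
    )


def write_timeseries_csv(curve, path: str | Path) -> None:
    """Write a curve back to its CSV dialect (full float precision)."""
    path = Path(path)
    if isinstance(curve, ThickeningCurve):
        cols = _TS_COLUMNS["thickening"]
        values = curve.concentrations
    elif isinstance(curve, BatchSettlingCurve):
        cols = _TS_COLUMNS["batch"]
        values = curve.heights
    else:
        raise ValidationError(f"unsupported curve type {type(curve).__name__}")
    df = pd.DataFrame({cols[0]: curve.times, cols[1]: values})
    df.to_csv(path, index=False, float_format="%.17g")


def read_plants_csv(path: str | Path) -> list[PlantRecord]:
    df = _read_csv(path, ("plant_id", "svi_mL_g", "a"))
    records = []
    for _, row in df.iterrows():
        b = row.get("b")
        records.append(
            PlantRecord(
                plant_id=str(row["plant_id"]),
                svi=float(row["svi_mL_g"]),
                a=float(row["a"]),
                b=None if b is None or pd.isna(b) else float(b),
            )
        )
    return records


def write_plants_csv(records, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "plant_id": [r.plant_id for r in records],
            "svi_mL_g": [r.svi for r in records],
            "a": [r.a for r in records],
            "b": [r.b for r in records],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_floc_csv(path: str | Path) -> list[FlocMeasurement]:
    df = _read_csv(path, ("floc_id", "area", "perimeter", "volume"))
    return [
        FlocMeasurement(
            floc_id=str(r["floc_id"]),
            area=float(r["area"]),
            perimeter=float(r["perimeter"]),
            volume=float(r["volume"]),
        )
        for _, r in df.iterrows()
    ]


def write_floc_csv(measurements, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "floc_id": [m.floc_id for m in measurements],
            "area": [m.area for m in measurements],
            "perimeter": [m.perimeter for m in measurements],
            "volume": [m.volume for m in measurements],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# model JSON documents

_MODEL_KINDS = {
    "power_law_fit": PowerLawFit,
    "svi_link_model": SviLinkModel,
    "vesilind_fit": VesilindFit,
    "compression_law": CompressionLaw,
    "integrated_settling_model": IntegratedSettlingModel,
}

_UNITS_BY_KIND = {
    "power_law_fit": {"a": "g/L", "b": "1", "time": "min"},
    "svi_link_model": {"alpha": "g/L per ln(mL/g)", "beta": "g/L", "svi": "mL/g"},
    "vesilind_fit": {"v0": "m/h", "n": "L/g"},
    "compression_law": {"a": "g/L", "b": "1", "x0": "m", "X0": "g/L"},
    "integrated_settling_model": {"velocity": "m/h", "X_c": "g/L"},
}


def _model_payload(model) -> tuple[str, dict]:
    if isinstance(model, PowerLawFit):
        return "power_law_fit", {
            "a": model.a,
            "b": model.b,
            "r_squared": model.r_squared,
            "p_value": model.p_value,
            "n_points": model.n_points,
            "scale": model.scale,
            "warnings": list(model.warnings_),
        }
    if isinstance(model, SviLinkModel):
        return "svi_link_model", {
            "alpha": model.alpha,
            "beta": model.beta,
            "r_squared": model.r_squared,
            "p_value": model.p_value,
            "svi_validity": list(model.svi_validity),
            "xd_validity": None if model.xd_validity is None else list(model.xd_validity),
            "mean_b": model.mean_b,
            "provenance": model.provenance,
            "log_base": model.log_base,
            "note": model.note,
        }
    if isinstance(model, VesilindFit):
        return "vesilind_fit", {
            "v0": model.v0,
            "n": model.n,
            "r_squared": model.r_squared,
        }
    if isinstance(model, CompressionLaw):
        return "compression_law", {
            "a": model.a,
            "b": model.b,
            "x0": model.x0,
            "X0": model.X0,
        }
    if isinstance(model, IntegratedSettlingModel):
        _, ves = _model_payload(model.vesilind)
        _, comp = _model_payload(model.compression)
        return "integrated_settling_model", {
            "vesilind": ves,
            "compression": comp,
            "X_c": model.X_c,
        }
    raise ValidationError(f"unsupported model type {type(model).__name__}")


def write_model_json(model, path: str | Path, provenance: str = "") -> None:
    """Serialize a fitted model with units, provenance and version."""
    kind, payload = _model_payload(model)
    doc = {
        "kind": kind,
        "version": __version__,
        "units": _UNITS_BY_KIND[kind],
        "provenance": provenance or payload.get("provenance", ""),
        "model": payload,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def _build_model(kind: str, payload: dict):
    try:
        if kind == "power_law_fit":
            return PowerLawFit(
                a=payload["a"],
                b=payload["b"],
                r_squared=payload["r_squared"],
                p_value=payload["p_value"],
                n_points=payload["n_points"],
                scale=payload.get("scale", "log-log"),
                warnings_=tuple(payload.get("warnings", ())),
            )
        if kind == "svi_link_model":
            xd = payload["xd_validity"]
            return SviLinkModel(
                alpha=payload["alpha"],
                beta=payload["beta"],
                r_squared=payload["r_squared"],
                p_value=payload["p_value"],
                svi_validity=tuple(payload["svi_validity"]),
                xd_validity=None if xd is None else tuple(xd),
                mean_b=payload["mean_b"],
                provenance=payload["provenance"],
                log_base=payload.get("log_base", "e"),
                note=payload.get("note", ""),
            )
        if kind == "vesilind_fit":
            return VesilindFit(
                v0=payload["v0"], n=payload["n"], r_squared=payload["r_squared"]
            )
        if kind == "compression_law":
            return CompressionLaw(
                a=payload["a"], b=payload["b"], x0=payload["x0"], X0=payload["X0"]
            )
        if kind == "integrated_settling_model":
            return IntegratedSettlingModel(
                vesilind=_build_model("vesilind_fit", payload["vesilind"]),
                compression=_build_model("compression_law", payload["compression"]),
                X_c=payload["X_c"],
            )
    except KeyError as exc:
        raise SchemaError(f"model document missing field {exc}") from exc
    raise SchemaError(f"unknown model kind {kind!r}")


def read_model_json(path: str | Path):
    """Read a model document written by :func:`write_model_json`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: invalid JSON ({exc})") from exc
    for req in ("kind", "units", "model"):
        if req not in doc:
            raise SchemaError(f"{path}: missing required field {req!r}")
    if doc.get("version") != __version__:
        warnings.warn(
            f"{path}: written by version {doc.get('version')!r}, "
            f"reading with {__version__}",
            UserWarning,
            stacklevel=2,
        )
    return _build_model(doc["kind"], doc["model"])
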