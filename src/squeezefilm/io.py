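"""Readers and writers for the package's file dialects.

Force curves travel as CSV with unit-suffixed headers (``time_s``,
``Z_m``, ``h_m``, ``force_N``, ``phase``; ``nm``/``um``/``nN`` suffixes
and a ``separation`` alias are honoured and converted to SI on ingest).
Contact frames travel as 16-bit TIFF or CSV count matrices with the
pixel calibration in a JSON sidecar.  Model parameters travel as JSON
blocks with explicit ``units`` maps.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .afm import CantileverProbe, ForceCurve, RampProtocol
from .analysis import ContactImage
from .film_field import ColumnArrayScene
from .hydrodynamics import FluidMedium, SetaePatch
from .suction_cup import SuctionCup

__all__ = [
    "ParseError",
    "UNIT_FACTORS",
    "read_force_curve_csv",
    "write_force_curve_csv",
    "read_contact_image",
    "write_contact_image",
    "read_pressure_trace_csv",
    "load_config",
    "reference_defaults",
]


class ParseError(ValueError):
    """A file violated the dialect or a container invariant."""


#: SI conversion factors for recognised unit suffixes.
UNIT_FACTORS = {
    "s": 1.0,
    "ms": 1e-3,
    "m": 1.0,
    "mm": 1e-3,
    "um": 1e-6,
    "nm": 1e-9,
    "N": 1.0,
    "mN": 1e-3,
    "uN": 1e-6,
    "nN": 1e-9,
    "Pa": 1.0,
    "kPa": 1e3,
    "m_s": 1.0,
    "um_s": 1e-6,
}

_CHANNEL_ALIASES = {
    "time": "time",
    "t": "time",
    "z": "z",
    "h": "h",
    "separation": "h",
    "force": "force",
    "f": "force",
}


def _resolve_column(name: str) -> tuple[str, float] | None:
    """Map a header like ``force_nN`` to (channel, SI factor)."""
    if name.strip().lower() == "phase":
        return ("phase", 1.0)
    parts = name.strip().split("_")
    base = parts[0].lower()
    if base not in _CHANNEL_ALIASES:
        return None
    unit = "_".join(parts[1:]) if len(parts) > 1 else ""
    if unit and unit not in UNIT_FACTORS:
        raise ParseError(f"column {name!r}: unknown unit suffix {unit!r}")
    return (_CHANNEL_ALIASES[base], UNIT_FACTORS.get(unit, 1.0))


def read_force_curve_csv(path: str | Path) -> ForceCurve:
    """Read a force curve, converting unit-suffixed columns to SI.

    Enforces the container invariants on load: positive actual gap and
    strictly monotone nominal gap within each phase; violations raise a
    ``ParseError`` naming the offending data line.
    """
    path = Path(path)
    df = pd.read_csv(path)
    channels: dict[str, np.ndarray] = {}
    for col in df.columns:
        resolved = _resolve_column(str(col))
        if resolved is None:
            continue
        channel, factor = resolved
        if channel == "phase":
            channels["phase"] = df[col].astype(str).to_numpy()
        else:
            channels[channel] = df[col].to_numpy(dtype=float) * factor
    for required in ("h", "force", "phase"):
        if required not in channels:
            raise ParseError(f"{path.name}: missing required column {required!r}")
    n = len(df)
    if "time" not in channels:
        channels["time"] = np.arange(n, dtype=float)
    if "z" not in channels:
        channels["z"] = channels["h"].copy()

    h = channels["h"]
    if np.any(h <= 0):
        line = int(np.argmax(h <= 0)) + 2  # 1-based, after header
        raise ParseError(f"{path.name}: non-positive separation at line {line}")
    z, phase = channels["z"], channels["phase"]
    for label in np.unique(phase):
        idx = np.nonzero(phase == label)[0]
        dz = np.diff(z[idx])
        if dz.size and not (np.all(dz > 0) or np.all(dz < 0)):
            bad = idx[int(np.argmax(~((dz > 0) if dz[0] > 0 else (dz < 0))))] + 2
            raise ParseError(
                f"{path.name}: nominal gap not strictly monotone in phase "
                f"{label!r} near line {bad}"
            )
    return ForceCurve(
        time=channels["time"], z=z, h=h, force=channels["force"], phase=phase
    )


def write_force_curve_csv(curve: ForceCurve, path: str | Path) -> None:
    """Write a force curve in the canonical SI dialect."""
    curve.to_frame().to_csv(path, index=False)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_contact_image(path: str | Path, pixel_size: float | None = None) -> ContactImage:
    """Read a contact frame from 16-bit TIFF or a CSV count matrix.

    The pixel calibration comes from ``pixel_size`` (m/pixel) or a JSON
    sidecar ``<file>.json`` with key ``pixel_size_m``; 8-bit TIFF input
    is upcast with a warning.
    """
    path = Path(path)
    if pixel_size is None:
        sidecar = _sidecar(path)
        if not sidecar.exists():
            raise ParseError(
                f"{path.name}: no pixel calibration (pass pixel_size or provide "
                f"{sidecar.name})"
            )
        pixel_size = float(json.loads(sidecar.read_text())["pixel_size_m"])
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.dtype == np.uint8:
            warnings.warn(f"{path.name}: 8-bit input upcast to 16-bit counts", stacklevel=2)
            arr = arr.astype(np.uint16)
        arr = arr.astype(float)
    else:
        arr = np.loadtxt(path, delimiter=",", dtype=float)
    return ContactImage(intensity=arr, pixel_size=pixel_size)


def write_contact_image(image: ContactImage, path: str | Path) -> None:
    """Write a frame as 16-bit TIFF (or CSV) plus a calibration sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        counts = np.asarray(image.intensity)
        if counts.max() > np.iinfo(np.uint16).max:
            raise ValueError("counts exceed the 16-bit range")
        tifffile.imwrite(path, np.round(counts).astype(np.uint16))
    else:
        np.savetxt(path, np.asarray(image.intensity), delimiter=",", fmt="%.6g")
    _sidecar(path).write_text(json.dumps({"pixel_size_m": image.pixel_size}))


def read_pressure_trace_csv(path: str | Path) -> pd.DataFrame:
    """Read a chamber-pressure trace (columns ``time_s``, ``pressure_Pa``)."""
    df = pd.read_csv(path)
    out = {}
    for want, unit_default in (("time", "s"), ("pressure", "Pa")):
        match = [c for c in df.columns if str(c).split("_")[0].lower() == want]
        if not match:
            raise ParseError(f"{Path(path).name}: missing {want} column")
        col = match[0]
        parts = str(col).split("_")
        factor = UNIT_FACTORS.get("_".join(parts[1:]), 1.0) if len(parts) > 1 else 1.0
        out[f"{want}_{'s' if want == 'time' else 'Pa'}"] = df[col].to_numpy(float) * factor
    return pd.DataFrame(out)


_BLOCK_TYPES = {
    "fluid": FluidMedium,
    "patch": SetaePatch,
    "probe": CantileverProbe,
    "protocol": RampProtocol,
    "scene": ColumnArrayScene,
    "cup": SuctionCup,
}


def _convert_block(block: dict) -> dict:
    units = block.get("units", {})
    out = {}
    for key, value in block.items():
        if key == "units":
            continue
        if key in units:
            unit = units[key]
            if unit not in UNIT_FACTORS:
                raise ParseError(f"unknown unit {unit!r} for field {key!r}")
            value = value * UNIT_FACTORS[unit]
        out[key] = value
    return out


def load_config(path: str | Path) -> dict:
    """Build model objects from a JSON config of typed blocks.

    Recognised top-level keys: ``fluid``, ``patch``, ``probe``,
    ``protocol``, ``scene``, ``cup``.  Each block maps field names to
    values, with an optional ``units`` map of per-field unit tags
    (converted to SI on ingest).  Unrecognised keys pass through as-is.
    """
    raw = json.loads(Path(path).read_text())
    out: dict = {}
    if "patch" in raw:
        out["patch"] = SetaePatch(**_convert_block(raw["patch"]))
    for key, cls in _BLOCK_TYPES.items():
        if key == "patch" or key not in raw:
            continue
        kwargs = _convert_block(raw[key])
        if key == "probe" and "patch" in out:
            kwargs.setdefault("effective_patch", out["patch"])
        out[key] = cls(**kwargs)
    for key, value in raw.items():
        if key not in _BLOCK_TYPES:
            out[key] = value
    return out


def reference_defaults() -> dict:
    """The ``reference-defaults`` profile: every model object at its
    documented default (AFM lever 0.24 N/m ramped at 4 µm/s over
    1–1000 nm, the reference micro-column scene, the measured cup)."""
    return {
        "fluid": FluidMedium(viscosity=1.0e-3),
        "probe": CantileverProbe(),
        "protocol": RampProtocol(),
        "scene": ColumnArrayScene(),
        "cup": SuctionCup(),
    }
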