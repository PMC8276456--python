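"""Reading and writing localization tables, image stacks and run artifacts.

The native CSV dialect uses the canonical column names (``x``, ``y``,
``z``, ``frame``, ``channel``, ``photons``, ``width_x``, ``width_y``,
``uncertainty_xy``), all distances in nm, frames 0-based.  A
ThunderSTORM-style export (``"x [nm]"`` headers, 1-based frames) is
accepted on read.
"""
from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .model import (KNOWN_COLUMNS, REQUIRED_COLUMNS, ImageStack,
                    LocalizationTable, ParseError, SchemaError)

# ThunderSTORM header -> canonical field.  Distances are exported in nm.
_THUNDERSTORM_MAP = {
    "x": "x",
    "y": "y",
    "z": "z",
    "frame": "frame",
    "intensity": "photons",
    "sigma": "width_x",        # symmetric 2D fit: one sigma for both axes
    "sigma1": "width_x",
    "sigma2": "width_y",
    "uncertainty": "uncertainty_xy",
    "uncertainty_xy": "uncertainty_xy",
    "channel": "channel",
}

_UNIT_RE = re.compile(r"\s*\[[^\]]*\]\s*$")


def _strip_units(name: str) -> str:
    """``"x [nm]"`` -> ``"x"``; quoted headers are unquoted."""
    return _UNIT_RE.sub("", name.strip().strip('"')).strip()


def read_localizations(path, dialect: str = "native",
                       channel: str | None = None) -> LocalizationTable:
    """Read a localization CSV.

    Parameters
    ----------
    path : path-like
    dialect : {"native", "thunderstorm"}
        ``"thunderstorm"`` maps unit-suffixed headers (``"x [nm]"``) onto
        the canonical fields and converts the 1-based frame index to
        0-based.
    channel : str, optional
        Channel label to assign when the file carries none.
    """
    path = Path(path)
    if dialect not in ("native", "thunderstorm", "native_csv",
                       "thunderstorm_csv"):
        raise ValueError(f"unknown dialect '{dialect}'")
    thunder = dialect.startswith("thunderstorm")
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    rename = {}
    for col in df.columns:
        base = _strip_units(col)
        if thunder:
            base = _THUNDERSTORM_MAP.get(base, base)
        if base in KNOWN_COLUMNS:
            rename[col] = base
    df = df.rename(columns=rename)
    df = df[[c for c in KNOWN_COLUMNS if c in df.columns]]

    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(
                f"{path.name}: mandatory column '{col}' is missing")
    if thunder and "width_y" not in df.columns and "width_x" in df.columns:
        df["width_y"] = df["width_x"]

    out = {}
    for col in df.columns:
        if col == "channel":
            out[col] = df[col].astype(str)
            continue
        probe = pd.to_numeric(df[col], errors="coerce")
        bad = probe.isna() & df[col].notna() & (df[col].str.len() > 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path.name}: non-numeric value {df[col].iloc[row]!r} in "
                f"column '{col}', data row {row}")
        # numpy's parser is exact to the ulp (pandas' fast path is not)
        out[col] = df[col].to_numpy(dtype=float)
    frame = out.get("frame")
    if frame is not None:
        if thunder:
            frame = frame - 1  # ThunderSTORM frames are 1-based
        out["frame"] = frame.astype(np.int64)
    res = pd.DataFrame(out)
    if "channel" not in res.columns and channel is not None:
        res["channel"] = str(channel)
    return LocalizationTable(res)


def write_localizations(table: LocalizationTable, path) -> None:
    """Write a table as native CSV; numeric values round-trip exactly."""
    df = table.data
    cols = [c for c in KNOWN_COLUMNS if c in df.columns]
    # 17 significant digits: lossless float64 round trip
    df[cols].to_csv(path, index=False, float_format="%.17g")


def read_image_stack(path, pixel_size: float = 160.0) -> ImageStack:
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return ImageStack(frames=np.asarray(frames), pixel_size=pixel_size)


def write_image_stack(stack: ImageStack, path) -> None:
    tifffile.imwrite(path, np.asarray(stack.frames))
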