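"""Shared domain types for localization-microscopy point clouds.

All coordinates are in nanometres.  A 2D analysis uses (x, y); 3D adds z.
Frames are 0-based integer indices; channels are free label strings
(typically the laser line, e.g. ``"647"``).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class TadstormError(Exception):
    """Base class for all package errors."""


class SchemaError(TadstormError, ValueError):
    """A table is missing a mandatory column or violates an invariant."""


class ParseError(TadstormError, ValueError):
    """A file cell could not be parsed; the message names the row."""


class ConfigError(TadstormError, ValueError):
    """A configuration value is outside the allowed set."""


class GeometryError(TadstormError, ValueError):
    """Degenerate geometry (collinear points, empty hull, ...)."""


class CalibrationError(TadstormError, ValueError):
    """An astigmatism calibration cannot be built or does not cover a z."""


class DriftError(TadstormError, RuntimeError):
    """Drift estimation failed (featureless block, uncovered frame, ...)."""


#: Columns a localization table may carry, in canonical order.
KNOWN_COLUMNS = (
    "x", "y", "z", "frame", "channel", "photons",
    "width_x", "width_y", "uncertainty_xy",
)

#: Columns that must be present.
REQUIRED_COLUMNS = ("x", "y")


@dataclass
class LocalizationTable:
    """A table of single-molecule localizations (one row per detection).

    Wraps a :class:`pandas.DataFrame` whose mandatory columns are ``x`` and
    ``y`` (nm).  Optional columns: ``z`` (nm), ``frame`` (0-based int),
    ``channel`` (str), ``photons``, ``width_x``/``width_y`` (nm, fitted PSF
    sigmas) and ``uncertainty_xy`` (nm).  Row order is stable under
    read/write round-trips.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_arrays(cls, x, y, z=None, frame=0, channel="0", photons=None,
                    width_x=None, width_y=None,
                    uncertainty_xy=None) -> "LocalizationTable":
        x = np.asarray(x, dtype=float)
        cols: dict = {"x": x, "y": np.asarray(y, dtype=float)}
        if z is not None:
            cols["z"] = np.asarray(z, dtype=float)
        cols["frame"] = np.broadcast_to(np.asarray(frame, dtype=np.int64),
                                        x.shape).copy()
        cols["channel"] = np.broadcast_to(np.asarray(channel, dtype=object),
                                          x.shape).copy()
        for name, val in (("photons", photons), ("width_x", width_x),
                          ("width_y", width_y),
                          ("uncertainty_xy", uncertainty_xy)):
            if val is not None:
                cols[name] = np.broadcast_to(
                    np.asarray(val, dtype=float), x.shape).copy()
        return cls(pd.DataFrame(cols))

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"mandatory column '{col}' is missing")
        for col in ("x", "y", "z"):
            if col in df.columns and len(df) and not np.isfinite(
                    df[col].to_numpy(dtype=float)).all():
                raise SchemaError(f"column '{col}' contains non-finite values")
        if "frame" in df.columns and len(df):
            fr = df["frame"].to_numpy()
            if (fr < 0).any():
                raise SchemaError("column 'frame' contains negative indices")
        if "photons" in df.columns and len(df):
            ph = df["photons"].to_numpy(dtype=float)
            if (ph[~np.isnan(ph)] < 0).any():
                raise SchemaError("column 'photons' contains negative counts")
        for col in ("width_x", "width_y"):
            if col in df.columns and len(df):
                w = df[col].to_numpy(dtype=float)
                if (w[~np.isnan(w)] <= 0).any():
                    raise SchemaError(f"column '{col}' must be positive")

    # -- convenience ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def has_z(self) -> bool:
        return "z" in self.data.columns

    def coords(self, dims: str = "2d") -> np.ndarray:
        """Coordinate matrix.  ``dims``: ``"2d"``/``"2d_projected"`` or ``"3d"``."""
        if dims in ("2d", "2d_projected"):
            return self.data[["x", "y"]].to_numpy(dtype=float)
        if dims == "3d":
            if not self.has_z:
                raise SchemaError("table has no z column; cannot do 3d analysis")
            return self.data[["x", "y", "z"]].to_numpy(dtype=float)
        raise ConfigError(f"unknown dims '{dims}' (allowed: 2d, 2d_projected, 3d)")

    def subset(self, indices) -> "LocalizationTable":
        return LocalizationTable(self.data.iloc[np.asarray(indices)]
                                 .reset_index(drop=True))

    def select_channel(self, channel: str) -> "LocalizationTable":
        if "channel" not in self.data.columns:
            raise SchemaError("table has no channel column")
        mask = self.data["channel"].astype(str) == str(channel)
        return LocalizationTable(self.data[mask].reset_index(drop=True))

    def copy(self) -> "LocalizationTable":
        return LocalizationTable(self.data.copy())


@dataclass
class ImageStack:
    """A stack of camera frames.

    ``frames`` has shape (n_frames, n_rows, n_cols); intensities are
    non-negative counts.  ``pixel_size`` is nm per pixel; the centre of
    pixel (0, 0) sits at (pixel_size/2, pixel_size/2) nm, so
    ``nm = (index + 0.5) * pixel_size``.
    """

    frames: np.ndarray
    pixel_size: float = 160.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise SchemaError("frames must be a 3D array (frame, row, col)")
        if self.pixel_size <= 0:
            raise SchemaError("pixel_size must be > 0")
        if len(self.frames) and float(self.frames.min()) < 0:
            raise SchemaError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape
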