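"""Drift correction from fiducial-bead images and dual-channel alignment.

Stage drift is estimated by 2D cross-correlation of block-averaged bead
images against the first block, with parabolic subpixel peak refinement,
then subtracted from localization coordinates with linear interpolation
between block anchors.  Channel registration maps one channel's control
points onto the other by a least-squares translation or affine transform.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .model import DriftError, GeometryError, ImageStack, LocalizationTable


@dataclass
class DriftTrace:
    """Per-block (dx, dy) displacement in nm versus the first block."""

    anchor_frames: np.ndarray     # frame index of each anchor (block center)
    dx: np.ndarray                # nm
    dy: np.ndarray                # nm
    n_frames: int                 # frame range covered: [0, n_frames)

    def __post_init__(self) -> None:
        self.anchor_frames = np.asarray(self.anchor_frames, dtype=float)
        self.dx = np.asarray(self.dx, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        if not (len(self.anchor_frames) == len(self.dx) == len(self.dy)):
            raise ValueError("anchor/dx/dy length mismatch")

    @classmethod
    def zero(cls, n_frames: int) -> "DriftTrace":
        return cls(np.array([0.0, n_frames - 1.0]), np.zeros(2), np.zeros(2),
                   n_frames)

    @classmethod
    def linear(cls, end_dx: float, end_dy: float,
               n_frames: int) -> "DriftTrace":
        """A linear drift reaching (end_dx, end_dy) nm at the last frame."""
        return cls(np.array([0.0, n_frames - 1.0]),
                   np.array([0.0, end_dx]), np.array([0.0, end_dy]), n_frames)

    def at(self, frames):
        """Interpolated (dx, dy) in nm; clamped outside the anchors."""
        frames = np.asarray(frames, dtype=float)
        return (np.interp(frames, self.anchor_frames, self.dx),
                np.interp(frames, self.anchor_frames, self.dy))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": self.anchor_frames,
                             "dx_nm": self.dx, "dy_nm": self.dy})

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path, n_frames: int) -> "DriftTrace":
        df = pd.read_csv(path)
        return cls(df["frame"].to_numpy(), df["dx_nm"].to_numpy(),
                   df["dy_nm"].to_numpy(), n_frames)


def _subpixel_peak(corr) -> tuple:
    """Integer argmax refined by 1D parabolic interpolation per axis."""
    r, c = np.unravel_index(int(np.argmax(corr)), corr.shape)
    out = []
    for axis, idx in ((0, r), (1, c)):
        if 0 < idx < corr.shape[axis] - 1:
            if axis == 0:
                cm, c0, cp = corr[idx - 1, c], corr[idx, c], corr[idx + 1, c]
            else:
                cm, c0, cp = corr[r, idx - 1], corr[r, idx], corr[r, idx + 1]
            denom = cm - 2 * c0 + cp
            delta = 0.5 * (cm - cp) / denom if denom != 0 else 0.0
        else:
            delta = 0.0
        out.append(idx + delta)
    return out[0], out[1]


def estimate_drift(bead_stack: ImageStack,
                   block_size: int = 500) -> DriftTrace:
    """Per-block drift versus block 0 from fiducial bead images."""
    frames = np.asarray(bead_stack.frames, dtype=float)
    n = len(frames)
    n_blocks = n // block_size
    if n_blocks < 2:
        raise DriftError(
            f"need >= 2 blocks of {block_size} frames, movie has {n}")
    ps = bead_stack.pixel_size
    anchors, dxs, dys = [], [], []
    ref = None
    for b in range(n_blocks):
        lo = b * block_size
        hi = n if b == n_blocks - 1 else lo + block_size
        img = frames[lo:hi].mean(axis=0)
        img = img - img.mean()
        if float(np.abs(img).max()) < 1e-9:
            raise DriftError(f"block {b} (frames {lo}-{hi - 1}) is "
                             "featureless; cannot cross-correlate")
        anchors.append((lo + hi - 1) / 2.0)
        if ref is None:
            ref = img
            dxs.append(0.0)
            dys.append(0.0)
            continue
        corr = fftconvolve(img, ref[::-1, ::-1], mode="full")
        pr, pc = _subpixel_peak(corr)
        dr = pr - (img.shape[0] - 1)
        dc = pc - (img.shape[1] - 1)
        dxs.append(dc * ps)
        dys.append(dr * ps)
    return DriftTrace(np.asarray(anchors), np.asarray(dxs), np.asarray(dys),
                      n_frames=n)


def apply_drift(table: LocalizationTable, trace: DriftTrace) -> LocalizationTable:
    """Subtract the interpolated drift from each localization.

    Preserves row order, row count and every non-coordinate column; a zero
    trace is the identity.
    """
    df = table.data
    if "frame" not in df.columns:
        raise DriftError("table has no frame column")
    frames = df["frame"].to_numpy()
    if len(frames) and (frames.min() < 0 or frames.max() >= trace.n_frames):
        raise DriftError(
            f"table frames [{frames.min()}, {frames.max()}] outside the "
            f"drift trace range [0, {trace.n_frames})")
    dx, dy = trace.at(frames)
    out = df.copy()
    out["x"] = out["x"].to_numpy(dtype=float) - dx
    out["y"] = out["y"].to_numpy(dtype=float) - dy
    return LocalizationTable(out)


@dataclass
class ChannelTransform:
    """Least-squares map from channel 2 coordinates onto channel 1 (nm)."""

    mode: str                     # translation | affine
    translation: np.ndarray       # (2,) nm; for affine: the constant term
    matrix: np.ndarray            # (2, 2); identity for translation
    residual: float               # nm RMS over the control points

    def apply(self, points):
        points = np.asarray(points, dtype=float)
        return points @ self.matrix.T + self.translation

    def apply_to_table(self, table: LocalizationTable) -> LocalizationTable:
        out = table.data.copy()
        xy = self.apply(out[["x", "y"]].to_numpy(dtype=float))
        out["x"], out["y"] = xy[:, 0], xy[:, 1]
        return LocalizationTable(out)


def register_channels(reference_points_ch1, reference_points_ch2,
                      mode: str = "translation") -> ChannelTransform:
    """Fit the channel-2 -> channel-1 transform from matched control points."""
    p1 = np.asarray(reference_points_ch1, dtype=float)
    p2 = np.asarray(reference_points_ch2, dtype=float)
    if p1.shape != p2.shape or p1.ndim != 2 or p1.shape[1] != 2:
        raise ValueError("control point lists must be matched (n, 2) arrays")
    if mode == "translation":
        if len(p1) < 1:
            raise ValueError("translation needs >= 1 matched pair")
        t = (p1 - p2).mean(axis=0)
        mat = np.eye(2)
    elif mode == "affine":
        if len(p1) < 3:
            raise GeometryError("affine needs >= 3 matched pairs")
        centered = p2 - p2.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        if sv[-1] < 1e-9 * max(sv[0], 1.0):
            raise GeometryError("control points are collinear; affine "
                                "transform is underdetermined")
        design = np.hstack([p2, np.ones((len(p2), 1))])
        sol, *_ = np.linalg.lstsq(design, p1, rcond=None)
        mat = sol[:2].T
        t = sol[2]
    else:
        raise ValueError(f"unknown mode '{mode}'")
    resid = float(np.sqrt(np.mean(
        np.sum((p2 @ mat.T + t - p1) ** 2, axis=1))))
    return ChannelTransform(mode=mode, translation=t, matrix=mat,
                            residual=resid)
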