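"""Synthetic STORM data with controlled radial structure.

The generator emulates the statistical structure of dual-color STORM data
of chromatin domains (TADs) and replication foci: a TAD is a ~200 nm point
cloud with 10^3--10^4 localizations, carrying ~7 sub-foci of ~30 nm
diameter whose centers sit at a controlled normalized radial position
``d`` (distance from TAD center / TAD radius).  Localization precision is
modeled as isotropic Gaussian noise per axis (~20 nm lateral, ~50 nm
axial).  Optionally a raw movie is rendered: per-frame elliptical-Gaussian
PSFs with astigmatic widths ``wx(z)``, ``wy(z)``, Poisson photon noise,
constant background, stage drift, and a fiducial-bead reference stack.

Every generator is a pure function of (spec, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import CalibrationError, ImageStack, LocalizationTable, SchemaError

PRESETS = {
    # radial placement of foci within the TAD, mirroring the cell-cycle
    # scenarios: homogeneous in G1, peripheral at the G1/S transition,
    # interior as the low-efficiency control
    "g1_uniform": "random",
    "g1s_peripheral": 1.0,
    "interior": 0.2,
}


@dataclass
class TadSpec:
    """One simulated chromatin domain (TAD)."""

    center: tuple = (0.0, 0.0, 0.0)        # nm
    shape: str = "sphere_uniform"          # sphere_uniform|ellipsoid_uniform|gaussian
    radius: float = 200.0                  # nm; sigma for shape="gaussian"
    n_localizations: int = 2500
    precision: tuple = (20.0, 50.0)        # nm (lateral, axial)
    axes: tuple = (1.0, 1.0, 1.0)          # semi-axis scale for ellipsoid
    channel: str = "561"
    n_frames: int = 2000

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.n_localizations < 1:
            raise ValueError("n_localizations must be >= 1")
        if min(self.precision) < 0:
            raise ValueError("precision must be >= 0")
        if self.shape not in ("sphere_uniform", "ellipsoid_uniform", "gaussian"):
            raise ValueError(f"unknown shape '{self.shape}'")


@dataclass
class FocusSpec:
    """Sub-foci (replication origins / initiation sites) inside a TAD.

    ``radial_fraction`` is the planted normalized radial position ``d`` of
    each focus center, or the string ``"random"`` for uniform placement in
    the TAD volume.
    """

    parent: TadSpec
    n_foci: int = 7
    radial_fraction: float | str = 1.0
    focus_diameter: float = 30.0           # nm
    locs_per_focus: int = 300
    channel: str = "647"

    def __post_init__(self) -> None:
        if self.n_foci < 0:
            raise ValueError("n_foci must be >= 0")
        if self.focus_diameter <= 0:
            raise ValueError("focus_diameter must be > 0")


@dataclass
class GroundTruth:
    """Truth accompanying a simulated dataset, for parameter-recovery tests."""

    labels: np.ndarray                     # per-row: -1 = TAD cloud, k >= 0 = focus k
    true_positions: np.ndarray             # (n, 3) noise-free emitter positions, nm
    tad_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    tad_radius: float = 0.0
    focus_centers: np.ndarray | None = None          # (k, 3) nm
    radial_fractions: np.ndarray | None = None       # (k,)
    drift: object | None = None                      # DriftTrace when injected

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        k = 0 if self.focus_centers is None else len(self.focus_centers)
        lab = other.labels.copy()
        lab[lab >= 0] += k
        centers = [c for c in (self.focus_centers, other.focus_centers)
                   if c is not None]
        fracs = [f for f in (self.radial_fractions, other.radial_fractions)
                 if f is not None]
        return GroundTruth(
            labels=np.concatenate([self.labels, lab]),
            true_positions=np.vstack([self.true_positions,
                                      other.true_positions]),
            tad_center=self.tad_center, tad_radius=self.tad_radius,
            focus_centers=np.vstack(centers) if centers else None,
            radial_fractions=np.concatenate(fracs) if fracs else None,
            drift=self.drift or other.drift)


# ---------------------------------------------------------------------------
# sampling primitives

def _isotropic_directions(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def sample_uniform_ball(rng, n, radius=1.0, ndim=3):
    """Uniform samples inside an n-ball (used by the Monte-Carlo nulls too)."""
    d = rng.normal(size=(n, ndim))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / ndim)
    return d * r[:, None]


def _sample_shape(rng, spec: TadSpec) -> np.ndarray:
    n = spec.n_localizations
    if spec.shape == "gaussian":
        return rng.normal(scale=spec.radius, size=(n, 3))
    pts = sample_uniform_ball(rng, n, spec.radius, ndim=3)
    if spec.shape == "ellipsoid_uniform":
        pts = pts * np.asarray(spec.axes, dtype=float)
    return pts


def _emit(rng, true_pos, spec: TadSpec, channel: str) -> LocalizationTable:
    lat, ax = spec.precision
    noisy = true_pos + rng.normal(size=true_pos.shape) * [lat, lat, ax]
    n = len(true_pos)
    return LocalizationTable.from_arrays(
        x=noisy[:, 0], y=noisy[:, 1], z=noisy[:, 2],
        frame=rng.integers(0, spec.n_frames, size=n),
        channel=channel,
        photons=rng.poisson(1000, size=n).astype(float))


# ---------------------------------------------------------------------------
# generators

def simulate_tad(spec: TadSpec, seed: int) -> tuple:
    """Draw a TAD localization cloud.  Deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    true = _sample_shape(rng, spec) + np.asarray(spec.center, dtype=float)
    table = _emit(rng, true, spec, spec.channel)
    truth = GroundTruth(labels=np.full(len(true), -1),
                        true_positions=true,
                        tad_center=np.asarray(spec.center, dtype=float),
                        tad_radius=spec.radius)
    return table, truth


def simulate_foci(spec: FocusSpec, seed: int) -> tuple:
    """Draw sub-foci at controlled radial positions inside the parent TAD."""
    if spec.locs_per_focus < 1:
        raise ValueError("locs_per_focus must be >= 1")
    rng = np.random.default_rng(seed)
    tad = spec.parent
    center = np.asarray(tad.center, dtype=float)
    k = spec.n_foci
    if spec.radial_fraction == "random":
        offsets = sample_uniform_ball(rng, k, tad.radius, ndim=3)
        fracs = np.linalg.norm(offsets, axis=1) / tad.radius
    else:
        d = float(spec.radial_fraction)
        offsets = _isotropic_directions(rng, k) * d * tad.radius
        fracs = np.full(k, d)
    centers = center + offsets

    r_focus = spec.focus_diameter / 2.0
    per = spec.locs_per_focus
    true = np.vstack([c + sample_uniform_ball(rng, per, r_focus, ndim=3)
                      for c in centers]) if k else np.empty((0, 3))
    labels = np.repeat(np.arange(k), per)
    table = _emit(rng, true, tad, spec.channel)
    truth = GroundTruth(labels=labels, true_positions=true,
                        tad_center=center, tad_radius=tad.radius,
                        focus_centers=centers, radial_fractions=fracs)
    return table, truth


def simulate_cell(preset: str = "g1_uniform", seed: int = 0,
                  tad_spec: TadSpec | None = None,
                  n_foci: int = 7, focus_diameter: float = 30.0,
                  locs_per_focus: int = 300) -> tuple:
    """One dual-color 'cell': a TAD cloud (channel 561) plus its foci (647)."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset '{preset}'; "
                         f"allowed: {sorted(PRESETS)}")
    tad_spec = tad_spec or TadSpec()
    fspec = FocusSpec(parent=tad_spec, n_foci=n_foci,
                      radial_fraction=PRESETS[preset],
                      focus_diameter=focus_diameter,
                      locs_per_focus=locs_per_focus)
    ss = np.random.SeedSequence(seed).spawn(2)
    tad_tab, tad_truth = simulate_tad(tad_spec, ss[0])
    foc_tab, foc_truth = simulate_foci(fspec, ss[1])
    import pandas as pd
    table = LocalizationTable(
        pd.concat([tad_tab.data, foc_tab.data], ignore_index=True))
    return table, tad_truth.merge(foc_truth)


# ---------------------------------------------------------------------------
# raw movie rendering

DEFAULT_BEAD_FRACTIONS = ((0.25, 0.3), (0.7, 0.65), (0.4, 0.8))


def simulate_movie(table: LocalizationTable, calibration, drift,
                   photon_mean: float = 3000.0, background: float = 10.0,
                   n_frames: int = 2000, shape: tuple = (64, 64),
                   pixel_size: float = 160.0, seed: int = 0,
                   bead_sigma_px: float = 2.0,
                   bead_photons: float = 50000.0) -> tuple:
    """Render a localization table into a raw camera movie plus bead stack.

    Each localization is drawn in its assigned frame as a pixel-integrated
    elliptical Gaussian whose widths follow the astigmatism calibration at
    its true z; the drift trace displaces both the emitters and the
    fiducial beads.  Returns ``(movie, bead_stack, emitter_records)`` where
    the records carry the per-emitter drawn photon counts.
    """
    from .localize import pixel_integrated_gaussian  # shared PSF model

    rng = np.random.default_rng(seed)
    df = table.data
    if "frame" not in df.columns:
        raise SchemaError("movie rendering requires a frame column")
    frames = df["frame"].to_numpy()
    if frames.max(initial=0) >= n_frames:
        raise SchemaError("table frames exceed n_frames")
    x = df["x"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    z = (df["z"].to_numpy(dtype=float) if "z" in df.columns
         else np.zeros_like(x))
    lo, hi = calibration.z_range
    bad = np.flatnonzero((z < lo) | (z > hi))
    if len(bad):
        raise CalibrationError(
            f"emitter {bad[0]}: z = {z[bad[0]]:.1f} nm outside the "
            f"calibration range [{lo:.1f}, {hi:.1f}] nm")
    wx = calibration.wx(z) / pixel_size   # sigma in px
    wy = calibration.wy(z) / pixel_size
    photons = rng.poisson(photon_mean, size=len(x)).astype(float)

    dx, dy = drift.at(np.arange(n_frames))        # nm, per frame
    expected = np.full((n_frames,) + tuple(shape), float(background),
                       dtype=np.float64)
    # index coords: pixel center i at (i + 0.5) * pixel_size nm
    col = x / pixel_size - 0.5
    row = y / pixel_size - 0.5
    for i in range(len(x)):
        f = int(frames[i])
        _add_spot(expected[f], row[i] + dy[f] / pixel_size,
                  col[i] + dx[f] / pixel_size, wy[i], wx[i], photons[i],
                  pixel_integrated_gaussian)
    movie = ImageStack(rng.poisson(expected).astype(np.float32), pixel_size)

    beads_rc = np.array([(fr * shape[0], fc * shape[1])
                         for fr, fc in DEFAULT_BEAD_FRACTIONS])
    bead_exp = np.full_like(expected, 20.0)
    for f in range(n_frames):
        for br, bc in beads_rc:
            _add_spot(bead_exp[f], br + dy[f] / pixel_size,
                      bc + dx[f] / pixel_size, bead_sigma_px, bead_sigma_px,
                      bead_photons, pixel_integrated_gaussian)
    beads = ImageStack(rng.poisson(bead_exp).astype(np.float32), pixel_size)

    records = {"photons": photons, "wx_px": wx, "wy_px": wy}
    return movie, beads, records


def _add_spot(img, row, col, sr, sc, photons, psf):
    half = int(np.ceil(4 * max(sr, sc))) + 2
    r0 = max(int(np.floor(row)) - half, 0)
    r1 = min(int(np.ceil(row)) + half + 1, img.shape[0])
    c0 = max(int(np.floor(col)) - half, 0)
    c1 = min(int(np.ceil(col)) + half + 1, img.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)
    cc = np.arange(c0, c1)
    img[r0:r1, c0:c1] += photons * psf(rr[:, None], cc[None, :],
                                       row, col, sr, sc)
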