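"""Raw frames -> localization table.

Spot detection (local maxima), axis-aligned elliptical-Gaussian fitting,
and astigmatism-based z assignment.  The fit model integrates the
Gaussian over each pixel (erf form) so that fitted widths are unbiased by
pixelation; the simulator renders with the same model.

The axial position is read off a calibration curve built by imaging
single emitters while scanning the stage in z: the fitted quadratic
curves wx(z)^2, wy(z)^2 cross at exactly one focal point, and a detection
is assigned the z minimizing the conventional sqrt-width distance
D(z) = (sqrt(wx) - sqrt(wx(z)))^2 + (sqrt(wy) - sqrt(wy(z)))^2.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml
from scipy import ndimage, optimize
from scipy.special import erf

from .model import CalibrationError, LocalizationTable


def pixel_integrated_gaussian(rows, cols, row0, col0, sr, sc):
    """Fraction of a unit-volume Gaussian falling in each pixel.

    ``rows``/``cols`` are pixel index coordinates (integer = pixel
    center); the pixel spans +-0.5 around its index.
    """
    fr = 0.5 * (erf((rows + 0.5 - row0) / (np.sqrt(2) * sr))
                - erf((rows - 0.5 - row0) / (np.sqrt(2) * sr)))
    fc = 0.5 * (erf((cols + 0.5 - col0) / (np.sqrt(2) * sc))
                - erf((cols - 0.5 - col0) / (np.sqrt(2) * sc)))
    return fr * fc


# ---------------------------------------------------------------------------
# calibration

@dataclass
class CalibrationCurve:
    """Astigmatism calibration wx(z), wy(z) in nm over a valid z range.

    Stored as quadratic coefficients of the squared widths (the defocus
    model ``w(z) = w0 sqrt(1 + ((z - c)/d)^2)`` is exactly quadratic in
    ``w^2``), which makes each width curve strictly monotone on either
    side of its minimum.
    """

    coeff_x: np.ndarray      # np.polyval coefficients for wx(z)^2, nm^2
    coeff_y: np.ndarray
    z_range: tuple           # (lo, hi) nm

    def __post_init__(self) -> None:
        self.coeff_x = np.asarray(self.coeff_x, dtype=float)
        self.coeff_y = np.asarray(self.coeff_y, dtype=float)
        lo, hi = self.z_range
        if hi <= lo:
            raise CalibrationError("empty z range")
        for name, c in (("wx", self.coeff_x), ("wy", self.coeff_y)):
            if len(c) != 3 or c[0] <= 0:
                raise CalibrationError(
                    f"{name}(z) is not strictly convex over the range; "
                    "widths must vary with z (monotone on either side of "
                    "the minimum)")
        zz = np.linspace(lo, hi, 2001)
        if (np.polyval(self.coeff_x, zz) <= 0).any() or \
           (np.polyval(self.coeff_y, zz) <= 0).any():
            raise CalibrationError("squared widths non-positive inside range")
        diff = self.coeff_x - self.coeff_y
        vals = np.polyval(diff, zz)
        crossings = np.count_nonzero(np.diff(np.sign(vals)) != 0)
        if crossings != 1:
            raise CalibrationError(
                f"wx and wy must be equal at exactly one focal point inside "
                f"the range (found {crossings} crossings)")

    def wx(self, z):
        return np.sqrt(np.polyval(self.coeff_x, z))

    def wy(self, z):
        return np.sqrt(np.polyval(self.coeff_y, z))

    @property
    def focal_z(self) -> float:
        """The z where wx == wy."""
        zz = np.linspace(*self.z_range, 200001)
        d = np.abs(np.polyval(self.coeff_x - self.coeff_y, zz))
        return float(zz[np.argmin(d)])

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {"coeff_x": self.coeff_x.tolist(),
                "coeff_y": self.coeff_y.tolist(),
                "z_range": [float(self.z_range[0]), float(self.z_range[1])]}

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(np.asarray(d["coeff_x"]), np.asarray(d["coeff_y"]),
                   tuple(d["z_range"]))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "CalibrationCurve":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_calibration(z, width_x, width_y) -> CalibrationCurve:
    """Fit the astigmatism curves from a stage-scan width table.

    ``z`` (nm) must contain at least 10 planes spanning the desired range;
    widths are the fitted PSF sigmas (nm) at each plane.
    """
    z = np.asarray(z, dtype=float)
    if len(z) < 10:
        raise CalibrationError(f"need >= 10 z planes, got {len(z)}")
    cx = np.polyfit(z, np.asarray(width_x, dtype=float) ** 2, 2)
    cy = np.polyfit(z, np.asarray(width_y, dtype=float) ** 2, 2)
    return CalibrationCurve(cx, cy, (float(z.min()), float(z.max())))


def z_lookup(width_x: float, width_y: float, calibration: CalibrationCurve,
             cutoff: float = 0.1, grid: float = 1.0):
    """Axial position from fitted widths, or ``None`` when rejected.

    Minimizes D(z) over the calibrated range on a grid of step ``grid``
    nm; detections whose minimal D (sqrt-nm units) exceeds ``cutoff`` are
    rejected.
    """
    if width_x <= 0 or width_y <= 0:
        raise ValueError("widths must be positive")
    lo, hi = calibration.z_range
    zz = np.arange(lo, hi + grid / 2, grid)
    d = ((np.sqrt(width_x) - np.sqrt(calibration.wx(zz))) ** 2
         + (np.sqrt(width_y) - np.sqrt(calibration.wy(zz))) ** 2)
    i = int(np.argmin(d))
    if d[i] > cutoff:
        return None
    return float(zz[i])


# ---------------------------------------------------------------------------
# detection and fitting

def detect_spots(frame, threshold: float, min_separation: int = 3):
    """Local maxima above ``threshold``, non-maximum suppressed.

    Returns a list of (row, col) integer pixel positions.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        return []
    size = 2 * int(min_separation) + 1
    local_max = ndimage.maximum_filter(frame, size=size, mode="nearest")
    mask = (frame == local_max) & (frame > threshold)
    return [tuple(p) for p in np.argwhere(mask)]


@dataclass
class SpotFit:
    """One fitted emitter (axis-aligned elliptical Gaussian + offset)."""

    x: float                 # nm
    y: float                 # nm
    width_x: float           # nm (sigma)
    width_y: float           # nm
    amplitude: float         # peak counts above offset
    offset: float            # counts
    photons: float           # 2*pi*A*sx*sy / gain
    residual_rms: float      # counts
    success: bool = True


def fit_gaussian(patch, initial, pixel_size: float = 1.0,
                 origin=(0, 0), gain: float = 1.0,
                 min_sigma_px: float = 0.3) -> SpotFit:
    """Least-squares elliptical-Gaussian fit of one spot in a patch.

    ``initial`` is the candidate (row, col) in patch coordinates;
    ``origin`` is the patch corner in frame pixel indices, used with
    ``pixel_size`` to express the result in nm.  Failure (non-convergence,
    width collapse below ``min_sigma_px``, vanishing amplitude) is
    reported via ``success=False`` and the spot should be discarded.
    """
    patch = np.asarray(patch, dtype=float)
    nr, nc = patch.shape
    rows = np.arange(nr, dtype=float)[:, None]
    cols = np.arange(nc, dtype=float)[None, :]
    off0 = float(patch.min())
    amp0 = float(patch.max() - off0)
    r0, c0 = float(initial[0]), float(initial[1])

    def model(p):
        row, col, sr, sc, amp, off = p
        return off + amp * 2 * np.pi * sr * sc * pixel_integrated_gaussian(
            rows, cols, row, col, sr, sc)

    def resid(p):
        # Pearson-weighted residuals approximate the Poisson likelihood;
        # unweighted least squares would inflate the centroid variance by
        # ~2x at zero background.  The +1 regularizes empty pixels.
        m = model(p)
        return ((m - patch) / np.sqrt(np.abs(m) + 1.0)).ravel()

    p0 = [r0, c0, 1.3, 1.3, max(amp0, 1e-12), off0]
    lower = [-1.0, -1.0, 0.05, 0.05, 0.0, -np.inf]
    upper = [nr, nc, nr * 2.0, nc * 2.0, np.inf, np.inf]
    try:
        res = optimize.least_squares(resid, p0, bounds=(lower, upper),
                                     xtol=1e-12, ftol=1e-12, gtol=1e-12)
    except Exception:
        return _failed_fit()
    row, col, sr, sc, amp, off = res.x
    ok = (res.success and sr >= min_sigma_px and sc >= min_sigma_px
          and amp > 1e-9)
    rms = float(np.sqrt(np.mean(res.fun ** 2)))
    return SpotFit(
        x=(origin[1] + col + 0.5) * pixel_size,
        y=(origin[0] + row + 0.5) * pixel_size,
        width_x=sc * pixel_size, width_y=sr * pixel_size,
        amplitude=float(amp), offset=float(off),
        photons=float(2 * np.pi * amp * sr * sc / gain),
        residual_rms=rms, success=bool(ok))


def _failed_fit() -> SpotFit:
    return SpotFit(x=np.nan, y=np.nan, width_x=np.nan, width_y=np.nan,
                   amplitude=0.0, offset=0.0, photons=0.0,
                   residual_rms=np.nan, success=False)


def localize_stack(stack, threshold: float, calibration=None,
                   min_separation: int = 3, patch_half: int = 3,
                   gain: float = 1.0, z_cutoff: float = 0.1,
                   z_grid: float = 1.0) -> LocalizationTable:
    """Detect and fit every spot in a movie; optionally assign z.

    Spots whose fit fails, whose patch touches the frame edge, or (with a
    calibration) whose widths sit too far from the calibration curve are
    discarded.
    """
    ps = stack.pixel_size
    recs = {k: [] for k in ("x", "y", "z", "frame", "photons",
                            "width_x", "width_y")}
    for f in range(stack.n_frames):
        frame = stack.frames[f]
        for (r, c) in detect_spots(frame, threshold, min_separation):
            r0, c0 = r - patch_half, c - patch_half
            r1, c1 = r + patch_half + 1, c + patch_half + 1
            if r0 < 0 or c0 < 0 or r1 > frame.shape[0] or c1 > frame.shape[1]:
                continue
            fit = fit_gaussian(frame[r0:r1, c0:c1],
                               (r - r0, c - c0), pixel_size=ps,
                               origin=(r0, c0), gain=gain)
            if not fit.success:
                continue
            z = np.nan
            if calibration is not None:
                z = z_lookup(fit.width_x, fit.width_y, calibration,
                             cutoff=z_cutoff, grid=z_grid)
                if z is None:
                    continue
            recs["x"].append(fit.x)
            recs["y"].append(fit.y)
            recs["z"].append(z)
            recs["frame"].append(f)
            recs["photons"].append(fit.photons)
            recs["width_x"].append(fit.width_x)
            recs["width_y"].append(fit.width_y)
    if calibration is None:
        recs.pop("z")
    kw = {k: np.asarray(v) for k, v in recs.items()}
    frame = kw.pop("frame", np.empty(0, dtype=int))
    return LocalizationTable.from_arrays(
        x=kw.pop("x", np.empty(0)), y=kw.pop("y", np.empty(0)),
        frame=frame.astype(int) if len(frame) else 0,
        channel="0", **kw)
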