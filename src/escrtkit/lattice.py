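"""Filament/lattice geometry from EM images: plot profiles, angles, spacings.

Mirrors how these quantities are measured on negative-stain micrographs of
protein-decorated membrane tubes:

* filament orientation = the smaller angle between the membrane long axis
  and the filament axis (always in [0, 90] degrees);
* interfilament spacing = mean consecutive peak distance in a plot profile
  taken perpendicular to the filament axis;
* outer diameter = distance between the outermost half-maximum edges of the
  filament signal in a profile across the tube;
* membrane curvature = 2 / outer diameter (reciprocal cylinder radius).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import find_peaks

from .io_formats import Micrograph

__all__ = [
    "LineProfile",
    "LatticeMeasurement",
    "InsufficientPeaksError",
    "line_profile",
    "filament_angle",
    "interfilament_spacing",
    "outer_diameter",
    "tube_curvature",
]


class InsufficientPeaksError(ValueError):
    """Fewer detectable peaks than the measurement needs; carries the count."""

    def __init__(self, n_peaks: int):
        self.n_peaks = n_peaks
        super().__init__(f"insufficient peaks: found {n_peaks}, need >= 2")


@dataclass
class LineProfile:
    """Intensity sampled along a segment, optionally averaged across a width."""

    values: np.ndarray
    spacing: float               # sample spacing, in `unit`
    p0: tuple                    # endpoints, in `unit`
    p1: tuple
    width: float = 0.0           # perpendicular averaging width, in `unit`
    unit: str = "A"              # "A" or "nm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) < 3:
            raise ValueError("profile needs >= 3 samples")
        if not self.spacing > 0:
            raise ValueError("sample spacing must be positive")

    def to_nm(self) -> float:
        """Factor converting this profile's unit to nm."""
        return 0.1 if self.unit == "A" else 1.0


@dataclass
class LatticeMeasurement:
    """A single geometry measurement with dispersion and provenance."""

    kind: str                    # angle_deg | spacing_nm | diameter_nm | curvature_per_nm
    value: float
    dispersion: float = float("nan")   # SD where applicable
    n: int = 1                   # number of peaks/gaps/replicates
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.kind == "angle_deg" and not (0 <= self.value <= 90):
            raise ValueError("angle must lie in [0, 90] degrees")
        if self.kind in ("spacing_nm", "diameter_nm") and not self.value > 0:
            raise ValueError(f"{self.kind} must be positive")
        if self.kind == "curvature_per_nm" and self.value < 0:
            raise ValueError("curvature must be >= 0")


def line_profile(micrograph: Micrograph, p0, p1, width_A: float = 0.0) -> LineProfile:
    """Plot profile along the segment p0 -> p1 (Angstrom), bilinear sampling.

    Samples at pixel-size spacing; each sample is the mean over ``width_A``
    perpendicular to the segment.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    px = micrograph.pixel_size_A
    length = float(np.linalg.norm(p1 - p0))
    if length < 3 * px:
        raise ValueError("segment must span at least 3 pixels")
    direction = (p1 - p0) / length
    normal = np.array([-direction[1], direction[0]])
    n = int(length / px) + 1
    s = np.linspace(0.0, length, n)
    n_off = max(int(round(width_A / px)) + 1, 1)
    offsets = (np.linspace(-width_A / 2, width_A / 2, n_off)
               if width_A > 0 else np.array([0.0]))
    pos = (p0[None, None, :] + s[None, :, None] * direction[None, None, :]
           + offsets[:, None, None] * normal[None, None, :])
    vals = map_coordinates(micrograph.pixels.astype(np.float64),
                           [pos[..., 1].ravel() / px, pos[..., 0].ravel() / px],
                           order=1, mode="nearest")
    values = vals.reshape(len(offsets), n).mean(axis=0)
    return LineProfile(values, s[1] - s[0], tuple(p0), tuple(p1), width_A, unit="A")


def filament_angle(membrane_axis_vec, filament_axis_vec) -> float:
    """Smaller angle (degrees) between the membrane axis and a filament axis.

    ``arccos(|u.v|)`` on unit vectors: symmetric, scale- and
    negation-invariant, always in [0, 90].
    """
    u = np.asarray(membrane_axis_vec, dtype=float)
    v = np.asarray(filament_axis_vec, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("axis vectors must be nonzero")
    cosang = abs(float(np.dot(u, v))) / (nu * nv)
    return math.degrees(math.acos(min(cosang, 1.0)))


def _refine_peak(values: np.ndarray, k: int) -> float:
    """Sub-sample peak position by parabolic interpolation around index k."""
    if 0 < k < len(values) - 1:
        y0, y1, y2 = values[k - 1], values[k], values[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            return k + 0.5 * (y0 - y2) / denom
    return float(k)


def interfilament_spacing(profile: LineProfile,
                          min_prominence_frac: float = 0.2) -> LatticeMeasurement:
    """Mean consecutive peak distance of a perpendicular plot profile (nm).

    Peaks must have prominence >= ``min_prominence_frac`` of the profile's
    dynamic range; positions are refined to sub-sample precision by parabolic
    interpolation.  The dispersion is the SD of the gaps, ``n`` their count.
    """
    vals = profile.values
    prom = min_prominence_frac * (vals.max() - vals.min())
    peaks, _ = find_peaks(vals, prominence=prom)
    if len(peaks) < 2:
        raise InsufficientPeaksError(len(peaks))
    pos = np.array([_refine_peak(vals, k) for k in peaks]) * profile.spacing
    gaps = np.diff(pos) * profile.to_nm()
    sd = float(np.std(gaps, ddof=1)) if len(gaps) > 1 else 0.0
    return LatticeMeasurement("spacing_nm", float(np.mean(gaps)), sd, len(gaps))


def outer_diameter(profile: LineProfile) -> LatticeMeasurement:
    """Distance between the outermost half-maximum edges of a profile (nm).

    Baseline is the mean of the outer 10% of samples at each end; the
    threshold is halfway between baseline and maximum; the value is the
    distance between the first and last threshold crossings, linearly
    interpolated between samples.
    """
    vals = profile.values
    n = len(vals)
    k = max(int(0.1 * n), 1)
    baseline = float(np.concatenate([vals[:k], vals[-k:]]).mean())
    vmax = float(vals.max())
    if vmax <= baseline:
        raise ValueError("no signal above baseline")
    imax = int(np.argmax(vals))
    if imax == 0 or imax == n - 1:
        raise ValueError("profile maximum must lie strictly inside the sampled range")
    thr = baseline + 0.5 * (vmax - baseline)
    above = vals >= thr
    if not above.any():
        raise ValueError("signal never crosses the half-maximum threshold")
    first = int(np.argmax(above))
    last = n - 1 - int(np.argmax(above[::-1]))
    if first == 0 or last == n - 1:
        raise ValueError("half-maximum edge lies outside the sampled range")

    def _cross(i_out, i_in):
        y0, y1 = vals[i_out], vals[i_in]
        frac = (thr - y0) / (y1 - y0)
        return i_out + frac * (i_in - i_out)

    left = _cross(first - 1, first)
    right = _cross(last + 1, last)
    width = (right - left) * profile.spacing * profile.to_nm()
    return LatticeMeasurement("diameter_nm", float(width), float("nan"), 1)


def tube_curvature(diameter_nm: float) -> LatticeMeasurement:
    """Membrane curvature of a cylindrical tube: kappa = 2 / diameter (1/nm)."""
    if not diameter_nm > 0:
        raise ValueError("diameter must be positive")
    return LatticeMeasurement("curvature_per_nm", 2.0 / diameter_nm)
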