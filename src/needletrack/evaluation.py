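"""Tracking-image quality metrics.

Resolution is quantified with the bounding-box / maximum-intensity-
projection procedure: a box (default 5x5 mm) is centred on the global
maximum, the box is collapsed to an axial and a lateral profile by
taking maxima along the orthogonal axis, and the full width at half
maximum of each profile is measured sub-pixel: the profile is
band-limited upsampled and the half-maximum crossings located by
linear interpolation on the refined profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import resample_poly

from .geometry import PointSource
from .reconstruction import TrackingImage

__all__ = [
    "ResolutionReport",
    "measure_fwhm",
    "localization_error",
    "count_objects",
]


@dataclass
class ResolutionReport:
    """Per-image resolution summary (lengths in mm)."""

    axial_fwhm_mm: float
    lateral_fwhm_mm: float
    peak_x_mm: float
    peak_z_mm: float
    peak_value: float
    n_objects: int
    axial_saturated: bool = False
    lateral_saturated: bool = False

    def to_dict(self) -> dict:
        return {
            "axial_fwhm_mm": self.axial_fwhm_mm,
            "lateral_fwhm_mm": self.lateral_fwhm_mm,
            "peak_x_mm": self.peak_x_mm,
            "peak_z_mm": self.peak_z_mm,
            "peak_value": self.peak_value,
            "n_objects": self.n_objects,
            "axial_saturated": self.axial_saturated,
            "lateral_saturated": self.lateral_saturated,
        }


def _tie_broken_argmax(pixels: np.ndarray) -> tuple[int, int]:
    # smallest depth index first, then smallest lateral index: C-order argmax
    iz, ix = np.unravel_index(int(np.argmax(pixels)), pixels.shape)
    return int(iz), int(ix)


_UPSAMPLE = 16


def _profile_fwhm(profile: np.ndarray, spacing_mm: float) -> tuple[float, bool]:
    """Sub-pixel FWHM of a 1-D peaked profile.

    The profile is band-limited upsampled (polyphase, 16x) and the two
    half-maximum crossings nearest the peak located by linear
    interpolation on the fine profile.  Plain linear interpolation on
    the raw samples over-estimates narrow (about one-pixel sigma)
    Gaussian widths by several percent because the profile is convex at
    the crossing; the band-limited refinement removes that bias.  If
    the profile never falls below half maximum on one side within the
    window, the window edge is used and the result flagged saturated.
    """
    if profile.size < 4:
        return profile.size * spacing_mm, True
    fine = resample_poly(profile, _UPSAMPLE, 1, padtype="line")
    peak = int(np.argmax(fine))
    half = 0.5 * fine[peak]
    saturated = False

    def crossing(direction: int) -> float:
        prev = peak
        j = peak + direction
        while 0 <= j < fine.size:
            if fine[j] < half:
                f = (fine[prev] - half) / (fine[prev] - fine[j])
                return prev + f * direction
            prev = j
            j += direction
        nonlocal saturated
        saturated = True
        return float(prev)

    left = crossing(-1)
    right = crossing(+1)
    return (right - left) * spacing_mm / _UPSAMPLE, saturated


def measure_fwhm(img: TrackingImage, box_mm: float = 5.0) -> ResolutionReport:
    """Axial/lateral FWHM of the brightest object via box-MIP profiles.

    A ``box_mm`` x ``box_mm`` region centred on the global maximum is
    cropped (clipped at image edges, with a warning); maximum-intensity
    projections give the axial and lateral profiles whose FWHMs are
    returned.  If a profile never crosses half maximum inside the box
    the box width is reported and the corresponding ``*_saturated``
    flag set, with a warning.
    """
    if not img.normalized:
        raise ValueError("measure_fwhm expects a normalized image")
    grid = img.grid
    iz, ix = _tie_broken_argmax(img.pixels)

    hz = int(round(0.5 * box_mm / grid.dz_mm))
    hx = int(round(0.5 * box_mm / grid.dx_mm))
    z_lo, z_hi = iz - hz, iz + hz + 1
    x_lo, x_hi = ix - hx, ix + hx + 1
    if z_lo < 0 or x_lo < 0 or z_hi > grid.nz or x_hi > grid.nx:
        warnings.warn("FWHM bounding box clipped at the image edge", stacklevel=2)
    z_lo, x_lo = max(z_lo, 0), max(x_lo, 0)
    z_hi, x_hi = min(z_hi, grid.nz), min(x_hi, grid.nx)
    box = img.pixels[z_lo:z_hi, x_lo:x_hi]

    axial_profile = box.max(axis=1)
    lateral_profile = box.max(axis=0)
    ax_fwhm, ax_sat = _profile_fwhm(axial_profile, grid.dz_mm)
    lat_fwhm, lat_sat = _profile_fwhm(lateral_profile, grid.dx_mm)
    if ax_sat or lat_sat:
        warnings.warn(
            "profile does not fall below half maximum inside the box; "
            "FWHM reported as the box extent",
            stacklevel=2,
        )
    return ResolutionReport(
        axial_fwhm_mm=ax_fwhm,
        lateral_fwhm_mm=lat_fwhm,
        peak_x_mm=float(grid.x_mm[ix]),
        peak_z_mm=float(grid.z_mm[iz]),
        peak_value=float(img.pixels[iz, ix]),
        n_objects=count_objects(img),
        axial_saturated=ax_sat,
        lateral_saturated=lat_sat,
    )


def localization_error(img: TrackingImage, truth: PointSource) -> float:
    """Euclidean distance (mm) between the image peak pixel centre and
    the true source position."""
    if not img.normalized:
        raise ValueError("localization_error expects a normalized image")
    iz, ix = _tie_broken_argmax(img.pixels)
    dx = float(img.grid.x_mm[ix]) - truth.x_mm
    dz = float(img.grid.z_mm[iz]) - truth.z_mm
    return float(np.hypot(dx, dz))


def count_objects(img: TrackingImage, threshold_db: float = -6.0) -> int:
    """Number of 8-connected components above ``threshold_db`` relative
    to the image peak (amplitude convention: -6 dB is half maximum)."""
    if not img.normalized:
        raise ValueError("count_objects expects a normalized image")
    thr = 10.0 ** (threshold_db / 20.0) * img.pixels.max()
    mask = img.pixels >= thr
    _, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    return int(n)
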