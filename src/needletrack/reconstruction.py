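"""Image reconstruction from one-way channel data.

Two reconstruction routes are provided:

* :func:`reconstruct_fk` — frequency-wavenumber (Stolt) migration.  The
  channel data are Fourier transformed over (t, x), the temporal
  frequency axis is remapped to the axial wavenumber through the
  one-way dispersion relation ``kz = sqrt((w/c)^2 - kx^2)`` with an
  amplitude-preserving Jacobian, evanescent components are zeroed, and
  an inverse transform yields the field on a depth grid.  The full
  sound speed ``c`` (not ``c/2``) is used because propagation is
  one-way, transmitter to probe.
* :func:`reconstruct_das` — brute-force delay-and-sum: each pixel sums
  the element samples at the geometric one-way time of flight.  Slower,
  but transparent; it serves as the independent cross-check for the
  Fourier method.

Both return a raw (bipolar) image; :func:`envelope_normalize` applies
axial Hilbert envelope detection and scales into [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.signal import hilbert

from .acoustics import ChannelData
from .geometry import ImageGrid, element_positions

__all__ = [
    "TrackingImage",
    "reconstruct_fk",
    "reconstruct_das",
    "envelope_normalize",
]


@dataclass
class TrackingImage:
    """2-D tracking image: ``pixels`` is [nz x nx], rows are axial.

    ``normalized`` marks an envelope-detected image scaled into [0, 1]
    with unit maximum.
    """

    pixels: np.ndarray
    grid: ImageGrid
    normalized: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.shape != (self.grid.nz, self.grid.nx):
            raise ValueError(
                f"pixel array shape {self.pixels.shape} does not match grid "
                f"({self.grid.nz}, {self.grid.nx})"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")
        if self.normalized:
            lo, hi = float(self.pixels.min()), float(self.pixels.max())
            if lo < 0 or hi > 1 + 1e-12 or abs(hi - 1.0) > 1e-9:
                raise ValueError("normalized image must lie in [0,1] with max 1")

    def argmax(self) -> tuple[int, int]:
        """(iz, ix) of the global maximum; ties broken by smallest depth,
        then smallest lateral index (C-order argmax)."""
        iz, ix = np.unravel_index(int(np.argmax(self.pixels)), self.pixels.shape)
        return int(iz), int(ix)

    def argmax_mm(self) -> tuple[float, float]:
        """(x, z) in mm of the peak pixel centre."""
        iz, ix = self.argmax()
        return float(self.grid.x_mm[ix]), float(self.grid.z_mm[iz])


def _check_grid(cd: ChannelData, grid: ImageGrid) -> None:
    pitch = cd.geometry.element_pitch_mm
    if grid.dx_mm > pitch * (1 + 1e-9):
        raise ValueError(
            f"grid dx ({grid.dx_mm} mm) coarser than element pitch ({pitch} mm): "
            "lateral Nyquist violated"
        )
    half_ap = 0.5 * cd.geometry.aperture_mm
    x_lo, x_hi, _, _ = grid.extent_mm
    margin = 0.5 * cd.geometry.aperture_mm  # allow a neighbourhood around the aperture
    if x_lo < -half_ap - margin or x_hi > half_ap + margin:
        raise ValueError("grid lateral extent far outside the array aperture")


def reconstruct_fk(cd: ChannelData, grid: ImageGrid) -> TrackingImage:
    """One-way frequency-wavenumber (Stolt) migration onto ``grid``.

    Returns a raw, not-normalized image.  Within the migration the
    natural depth spacing is ``c / fs`` so the axial wavenumber grid
    coincides with ``w / c``; the migrated field is then linearly
    resampled onto the requested pixel grid.
    """
    _check_grid(cd, grid)
    geom = cd.geometry
    c = geom.sound_speed_m_s
    fs = cd.sampling_freq_hz
    dt = 1.0 / fs
    pitch_m = geom.element_pitch_mm * 1e-3

    nt, nx = cd.samples.shape
    nt_pad = int(2 ** np.ceil(np.log2(2 * nt)))
    nx_pad = int(2 ** np.ceil(np.log2(2 * nx)))

    # FFT over time (real) and lateral position
    F = np.fft.rfft(cd.samples, n=nt_pad, axis=0)
    F = np.fft.fft(F, n=nx_pad, axis=1)  # [n_w, nx_pad]

    w = 2 * np.pi * np.fft.rfftfreq(nt_pad, dt)  # >= 0
    kx = 2 * np.pi * np.fft.fftfreq(nx_pad, pitch_m)

    # target axial wavenumber grid: dz = c*dt makes kz_n = w_n / c
    dz_m = c * dt
    kz = 2 * np.pi * np.fft.rfftfreq(nt_pad, dz_m)  # >= 0
    n_kz = kz.size

    KZ = kz[:, None]
    KX = kx[None, :]
    w_map = c * np.sqrt(KZ**2 + KX**2)  # [n_kz, nx_pad]

    dw = w[1] - w[0]
    idx = w_map / dw
    i0 = np.floor(idx).astype(np.int64)
    frac = idx - i0
    valid = i0 < (w.size - 1)
    i0c = np.clip(i0, 0, w.size - 2)

    cols = np.broadcast_to(np.arange(nx_pad)[None, :], i0c.shape)
    G = (1 - frac) * F[i0c, cols] + frac * F[i0c + 1, cols]
    G[~valid] = 0.0

    # amplitude-preserving Jacobian dw/dkz = c * kz / sqrt(kz^2 + kx^2);
    # the kz = 0 row is a zero-measure DC term.
    with np.errstate(divide="ignore", invalid="ignore"):
        jac = c * KZ / np.sqrt(KZ**2 + KX**2)
    jac[0, :] = 0.0
    G = G * jac

    img_full = np.fft.ifft(G, axis=1)
    img_full = np.fft.irfft(img_full, n=nt_pad, axis=0)  # real [nt_pad, nx_pad]

    # physical coordinates of the migrated field
    z_full_mm = (c * cd.t0_s + dz_m * np.arange(nt_pad)) * 1e3
    x0 = element_positions(geom)[0]
    x_full_mm = x0 + geom.element_pitch_mm * np.arange(nx_pad)

    interp = RegularGridInterpolator(
        (z_full_mm, x_full_mm), img_full, bounds_error=False, fill_value=0.0
    )
    Z, X = np.meshgrid(grid.z_mm, grid.x_mm, indexing="ij")
    pixels = interp(np.stack([Z.ravel(), X.ravel()], axis=1)).reshape(grid.nz, grid.nx)
    return TrackingImage(pixels=pixels, grid=grid, normalized=False)


def reconstruct_das(cd: ChannelData, grid: ImageGrid) -> TrackingImage:
    """Delay-and-sum with one-way delays; the brute-force oracle.

    For every pixel p the element samples at ``t = |p - element| / c``
    are summed, with linear interpolation between time samples.
    """
    _check_grid(cd, grid)
    geom = cd.geometry
    c = geom.sound_speed_m_s
    t = cd.times_s
    pos = element_positions(geom)

    Z, X = np.meshgrid(grid.z_mm, grid.x_mm, indexing="ij")
    pixels = np.zeros((grid.nz, grid.nx))
    for i, xe in enumerate(pos):
        r_mm = np.hypot(X - xe, Z)
        tau = r_mm * 1e-3 / c
        pixels += np.interp(tau, t, cd.samples[:, i], left=0.0, right=0.0)
    return TrackingImage(pixels=pixels, grid=grid, normalized=False)


def envelope_normalize(img: TrackingImage) -> TrackingImage:
    """Axial Hilbert-envelope detection followed by scaling to [0, 1].

    The analytic-signal magnitude is taken independently per image
    column (along depth, the temporal direction), then the image is
    divided by its global maximum so the output has unit peak.  Applied
    to an already-normalized image this is the identity, which makes
    the operation idempotent.
    """
    if img.normalized:
        return img
    if not np.any(img.pixels):
        raise ValueError("cannot normalize an all-zero image")
    env = np.abs(hilbert(img.pixels, axis=0))
    env /= env.max()
    env = np.clip(env, 0.0, 1.0)
    # guard against rounding the peak below exactly 1
    env[np.unravel_index(np.argmax(env), env.shape)] = 1.0
    return TrackingImage(pixels=env, grid=img.grid, normalized=True)
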