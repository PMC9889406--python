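"""Forward simulation of one-way point-source transmissions.

A fibre-optic transmitter at (x, z) emits a short pulse at t = 0; every
rectangular element of the linear array records an A-line.  The medium
is homogeneous, lossless, with a uniform sound speed, so each A-line is
the pulse delayed by the one-way time of flight and scaled by 1/r
spherical spreading.  The finite lateral extent of each rectangular
element is modelled by sub-element summation: the element is split into
laterally distributed sub-apertures whose delayed contributions are
averaged, which captures the near-field element response at the depths
of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import gausspulse, hilbert

from .geometry import ArrayGeometry, PointSource, Pulse, element_positions

__all__ = [
    "ChannelData",
    "simulate_channel_data",
    "add_noise",
    "measure_snr",
    "pulse_cutoff_s",
    "min_duration_s",
]


@dataclass
class ChannelData:
    """Received A-lines: ``samples`` is [n_samples x n_elements]."""

    samples: np.ndarray
    sampling_freq_hz: float
    t0_s: float
    geometry: ArrayGeometry

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D [n_samples x n_elements] array")
        if self.samples.shape[1] != self.geometry.n_elements:
            raise ValueError(
                f"samples has {self.samples.shape[1]} element columns, "
                f"geometry declares {self.geometry.n_elements}"
            )
        if self.samples.shape[0] < 1:
            raise ValueError("need at least one time sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.sampling_freq_hz


def pulse_cutoff_s(pulse: Pulse, tpr_db: float = -60.0) -> float:
    """Half-duration after which the pulse envelope is below ``tpr_db``."""
    return float(
        gausspulse(
            "cutoff",
            fc=pulse.center_freq_hz,
            bw=pulse.fractional_bandwidth,
            bwr=-6,
            tpr=tpr_db,
        )
    )


def min_duration_s(src: PointSource, geom: ArrayGeometry, pulse: Pulse) -> float:
    """Shortest record that contains every arrival, incl. the pulse tail."""
    pos = element_positions(geom)
    r_max_mm = float(np.max(np.hypot(pos - src.x_mm, src.z_mm)))
    return r_max_mm * 1e-3 / geom.sound_speed_m_s + pulse_cutoff_s(pulse)


def simulate_channel_data(
    src: PointSource,
    geom: ArrayGeometry,
    pulse: Pulse,
    duration_s: float | None = None,
    n_sub: int = 8,
) -> ChannelData:
    """Simulate noise-free channel data for a single point transmitter.

    Each element's A-line is the sum over ``n_sub`` lateral sub-apertures
    of the transmit pulse delayed by the one-way time of flight
    ``r / c`` and scaled by spherical spreading ``1 / r``.

    Parameters
    ----------
    duration_s : float, optional
        Record length.  Defaults to the shortest duration containing all
        arrivals; an explicit value shorter than that raises ``ValueError``.
    n_sub : int
        Number of sub-apertures per element (>= 1; 8 is ample at the
        depths of interest).
    """
    needed = min_duration_s(src, geom, pulse)
    if duration_s is None:
        duration_s = needed
    elif duration_s < needed:
        raise ValueError(
            f"duration_s={duration_s:.3e} s too short to contain the farthest "
            f"arrival (need >= {needed:.3e} s)"
        )
    if n_sub < 1:
        raise ValueError("n_sub must be >= 1")

    fs = geom.sampling_freq_hz
    c = geom.sound_speed_m_s
    n_samples = int(np.ceil(duration_s * fs))
    t = np.arange(n_samples) / fs

    pos = element_positions(geom)  # [n_el]
    # sub-aperture lateral offsets, symmetric within each element
    offs = ((np.arange(n_sub) + 0.5) / n_sub - 0.5) * geom.element_width_mm
    x_sub = pos[:, None] + offs[None, :]  # [n_el, n_sub]
    r_mm = np.hypot(x_sub - src.x_mm, src.z_mm)  # [n_el, n_sub]
    delay_s = r_mm * 1e-3 / c

    # evaluate the pulse at t - delay for every sub-aperture
    tau = t[None, None, :] - delay_s[:, :, None]  # [n_el, n_sub, n_t]
    wave = gausspulse(tau, fc=pulse.center_freq_hz, bw=pulse.fractional_bandwidth, bwr=-6)
    amp = src.amplitude / r_mm  # 1/r spreading (r in mm; units arbitrary)
    samples = np.einsum("es,est->te", amp / n_sub, wave)
    return ChannelData(samples=samples, sampling_freq_hz=fs, t0_s=0.0, geometry=geom)


def add_noise(cd: ChannelData, target_snr: float, seed: int) -> ChannelData:
    """Add i.i.d. zero-mean Gaussian noise at a requested SNR.

    The noise standard deviation is ``peak|samples| / target_snr``, so
    the SNR convention matches :func:`measure_snr` (peak signal over
    noise standard deviation).  Deterministic given ``seed``.
    """
    if not np.isfinite(target_snr) or target_snr <= 0:
        raise ValueError("target_snr must be a positive finite number")
    peak = float(np.max(np.abs(cd.samples)))
    if peak == 0.0:
        raise ValueError("cannot set an SNR on all-zero channel data")
    sigma = peak / target_snr
    rng = np.random.default_rng(seed)
    noisy = cd.samples + rng.normal(0.0, sigma, size=cd.samples.shape)
    return ChannelData(
        samples=noisy,
        sampling_freq_hz=cd.sampling_freq_hz,
        t0_s=cd.t0_s,
        geometry=cd.geometry,
    )


Window = tuple[int, int] | tuple[tuple[int, int], tuple[int, int]]


def _window_slices(win: Window, cd: ChannelData) -> tuple[tuple[int, int], tuple[int, int]]:
    if len(win) == 2 and all(np.isscalar(v) for v in win):
        t = (int(win[0]), int(win[1]))
        e = (0, cd.geometry.n_elements)
    else:
        t, e = (int(win[0][0]), int(win[0][1])), (int(win[1][0]), int(win[1][1]))
    if not (0 <= t[0] < t[1] <= cd.n_samples and 0 <= e[0] < e[1] <= cd.geometry.n_elements):
        raise ValueError("window out of bounds or empty")
    return t, e


def measure_snr(cd: ChannelData, signal_window: Window, noise_window: Window) -> float:
    """Peak |amplitude| in the signal window over the standard deviation
    in the noise window.

    A window is either a half-open sample range ``(t0, t1)`` on the
    time axis (all elements) or a 2-D range ``((t0, t1), (e0, e1))``
    restricting the elements as well.  Windows must be disjoint and the
    noise window must contain no source arrival.
    """
    (s_t, s_e) = _window_slices(signal_window, cd)
    (n_t, n_e) = _window_slices(noise_window, cd)
    t_overlap = max(s_t[0], n_t[0]) < min(s_t[1], n_t[1])
    e_overlap = max(s_e[0], n_e[0]) < min(s_e[1], n_e[1])
    if t_overlap and e_overlap:
        raise ValueError("signal and noise windows must be disjoint")
    noise_sd = float(np.std(cd.samples[n_t[0] : n_t[1], n_e[0] : n_e[1]]))
    if noise_sd == 0.0:
        raise ValueError("noise window has zero standard deviation")
    return float(np.max(np.abs(cd.samples[s_t[0] : s_t[1], s_e[0] : s_e[1]]))) / noise_sd


def aline_envelope(cd: ChannelData) -> np.ndarray:
    """Analytic-signal magnitude of each A-line (time axis)."""
    return np.abs(hilbert(cd.samples, axis=0))
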