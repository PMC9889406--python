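"""Synthetic training-corpus generation.

Each training pair couples a reconstructed, envelope-normalized image
of a single noisy point-source transmission (the network input) with a
ground-truth image: a delta at the source pixel convolved with an
anisotropic Gaussian kernel and scaled to unit peak (the target).
Kernels are specified in pixels as sigma = [sigma_z, sigma_x]; on the
default grid (dz = 37.5 um, dx = 0.3 mm) the axially elongated kernels
compensate for the axial/lateral sampling anisotropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage

from .acoustics import add_noise, simulate_channel_data
from .geometry import ArrayGeometry, ImageGrid, PointSource, Pulse
from .reconstruction import TrackingImage, envelope_normalize, reconstruct_fk

__all__ = [
    "KernelSpec",
    "TrainingPair",
    "DatasetSpec",
    "make_ground_truth",
    "generate_dataset",
    "rebuild_targets",
    "extract_patches",
]

# SNR interval reported for the study conditions
SNR_RANGE = (10.5, 56.1)


@dataclass(frozen=True)
class KernelSpec:
    """Anisotropic Gaussian ground-truth kernel, sigmas in pixels."""

    sigma_z_px: float = 4.0
    sigma_x_px: float = 2.0

    def __post_init__(self) -> None:
        if self.sigma_z_px <= 0 or self.sigma_x_px <= 0:
            raise ValueError("kernel sigmas must be positive")


@dataclass
class TrainingPair:
    input: TrackingImage
    target: TrackingImage
    source: PointSource
    snr: float

    def __post_init__(self) -> None:
        if self.input.grid != self.target.grid:
            raise ValueError("input and target must share the same grid")
        if not (self.input.normalized and self.target.normalized):
            raise ValueError("input and target must both be normalized")


@dataclass(frozen=True)
class DatasetSpec:
    """Corpus description: number of images, kernel, SNR sampling
    (log-uniform over ``snr_range``), source region (mm) and seed."""

    n_images: int = 1000
    kernel: KernelSpec = field(default_factory=KernelSpec)
    snr_range: tuple[float, float] = SNR_RANGE
    x_range_mm: tuple[float, float] = (-15.0, 15.0)
    z_range_mm: tuple[float, float] = (10.0, 42.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.snr_range[0] <= 0 or self.snr_range[1] < self.snr_range[0]:
            raise ValueError("snr_range must be positive and ordered")
        if self.x_range_mm[1] < self.x_range_mm[0] or self.z_range_mm[1] < self.z_range_mm[0]:
            raise ValueError("source region must be non-empty")
        if self.z_range_mm[0] <= 0:
            raise ValueError("source depths must be positive")


def make_ground_truth(src: PointSource, grid: ImageGrid, kernel: KernelSpec) -> TrackingImage:
    """Ground-truth image: unit delta at the pixel containing the
    source, convolved with the separable anisotropic Gaussian, scaled
    to peak 1.  The source is rounded to the nearest pixel centre."""
    iz, ix = grid.pixel_index(src.x_mm, src.z_mm)  # raises outside grid
    delta = np.zeros((grid.nz, grid.nx))
    delta[iz, ix] = 1.0
    # zero boundary: reflection would pile mass onto the edge and can
    # shift the peak for sources within a few sigma of the border
    blurred = ndimage.gaussian_filter(
        delta, sigma=(kernel.sigma_z_px, kernel.sigma_x_px), mode="constant", cval=0.0
    )
    blurred /= blurred.max()
    blurred = np.clip(blurred, 0.0, 1.0)
    return TrackingImage(pixels=blurred, grid=grid, normalized=True)


def sample_sources(spec: DatasetSpec, rng: np.random.Generator) -> list[PointSource]:
    """Draw ``n_images`` source positions uniformly over the region."""
    xs = rng.uniform(*spec.x_range_mm, size=spec.n_images)
    zs = rng.uniform(*spec.z_range_mm, size=spec.n_images)
    return [PointSource(float(x), float(z)) for x, z in zip(xs, zs)]


def generate_dataset(
    spec: DatasetSpec,
    geom: ArrayGeometry,
    grid: ImageGrid,
    pulse: Pulse,
    n_sub: int = 8,
) -> list[TrainingPair]:
    """Generate the synthetic corpus, deterministic given ``spec.seed``.

    Per pair: draw a source uniformly in the region, simulate channel
    data, add Gaussian noise at an SNR drawn log-uniformly from
    ``spec.snr_range``, reconstruct with the Fourier method, envelope-
    normalize, and build the Gaussian ground truth.
    """
    x_lo, x_hi, z_lo, z_hi = grid.extent_mm
    if not (
        x_lo <= spec.x_range_mm[0] <= spec.x_range_mm[1] <= x_hi
        and z_lo <= spec.z_range_mm[0] <= spec.z_range_mm[1] <= z_hi
    ):
        raise ValueError("source region must lie inside the image grid")

    root = np.random.SeedSequence(spec.seed)
    pos_rng = np.random.default_rng(root.spawn(1)[0])
    sources = sample_sources(spec, pos_rng)
    snrs = np.exp(
        pos_rng.uniform(np.log(spec.snr_range[0]), np.log(spec.snr_range[1]), spec.n_images)
    )
    noise_seeds = pos_rng.integers(0, 2**31 - 1, size=spec.n_images)

    pairs: list[TrainingPair] = []
    for src, snr, nseed in zip(sources, snrs, noise_seeds):
        cd = simulate_channel_data(src, geom, pulse, n_sub=n_sub)
        cd = add_noise(cd, float(snr), int(nseed))
        img = envelope_normalize(reconstruct_fk(cd, grid))
        target = make_ground_truth(src, grid, spec.kernel)
        pairs.append(TrainingPair(input=img, target=target, source=src, snr=float(snr)))
    return pairs


def rebuild_targets(pairs: Sequence[TrainingPair], kernel: KernelSpec) -> list[TrainingPair]:
    """Same inputs, ground-truth targets regenerated with a different
    kernel.  Useful when comparing training kernels on one corpus."""
    return [
        TrainingPair(
            input=p.input,
            target=make_ground_truth(p.source, p.input.grid, kernel),
            source=p.source,
            snr=p.snr,
        )
        for p in pairs
    ]


def extract_patches(
    pairs: Sequence[TrainingPair],
    patch_px: int = 64,
    batch_size: int = 16,
    seed: int = 0,
    n_batches: int | None = None,
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Stream of aligned random-crop training batches.

    Yields ``(inputs, targets)`` float32 arrays of shape
    ``[batch_size, patch_px, patch_px]``; the same crop window is
    applied to a pair's input and target.  Deterministic given ``seed``;
    yields forever unless ``n_batches`` is given.
    """
    if not pairs:
        raise ValueError("no training pairs supplied")
    grid = pairs[0].input.grid
    if patch_px > min(grid.nx, grid.nz):
        raise ValueError(
            f"patch_px={patch_px} exceeds image size ({grid.nz} x {grid.nx})"
        )
    rng = np.random.default_rng(seed)
    n = len(pairs)
    max_z = grid.nz - patch_px
    max_x = grid.nx - patch_px

    produced = 0
    while n_batches is None or produced < n_batches:
        xs = np.empty((batch_size, patch_px, patch_px), dtype=np.float32)
        ys = np.empty_like(xs)
        for b in range(batch_size):
            k = int(rng.integers(0, n))
            z0 = int(rng.integers(0, max_z + 1))
            x0 = int(rng.integers(0, max_x + 1))
            sl = (slice(z0, z0 + patch_px), slice(x0, x0 + patch_px))
            xs[b] = pairs[k].input.pixels[sl]
            ys[b] = pairs[k].target.pixels[sl]
        yield xs, ys
        produced += 1
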