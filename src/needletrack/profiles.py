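"""Study profiles: the full-scale conditions and a desk-scale profile.

``full_profile`` mirrors the complete study conditions (1000 training
pairs, 16 residual blocks of 64 channels, 80 epochs) and is what the
default :class:`~needletrack.config.PipelineConfig` encodes.

``smoke_profile`` is the desk-scale analogue used by the test suite and
the results script so the whole pipeline runs on a single CPU in
minutes: the image grid is restricted axially to the depth band of the
needle-tip insertions (22-41.2 mm, 512 x 128 pixels at the native
37.5 um x 0.3 mm spacing, so kernel sizes in pixels keep their
meaning), 200 training / 8 validation pairs with sources at depths
24-38 mm, and a 4-block, 16-channel network trained for 20 epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dataset import DatasetSpec, KernelSpec
from .enhancer import NetworkSpec, TrainSpec
from .geometry import ArrayGeometry, ImageGrid, Pulse


@dataclass(frozen=True)
class StudyProfile:
    geometry: ArrayGeometry
    pulse: Pulse
    grid: ImageGrid
    n_train: int
    n_val: int
    source_x_mm: tuple[float, float]
    source_z_mm: tuple[float, float]
    network: NetworkSpec
    epochs: int

    def dataset_spec(
        self, seed: int, n_images: int | None = None, kernel: KernelSpec | None = None
    ) -> DatasetSpec:
        return DatasetSpec(
            n_images=n_images if n_images is not None else self.n_train,
            kernel=kernel or KernelSpec(4, 2),
            x_range_mm=self.source_x_mm,
            z_range_mm=self.source_z_mm,
            seed=seed,
        )

    def train_spec(self, seed: int, epochs: int | None = None) -> TrainSpec:
        return TrainSpec(epochs=epochs if epochs is not None else self.epochs, seed=seed)


def full_profile() -> StudyProfile:
    geom = ArrayGeometry()
    dz = geom.sound_speed_m_s / geom.sampling_freq_hz * 1e3
    grid = ImageGrid(x0_mm=-19.05, z0_mm=0.0, dx_mm=0.3, dz_mm=dz, nx=128, nz=1200)
    return StudyProfile(
        geometry=geom,
        pulse=Pulse(),
        grid=grid,
        n_train=1000,
        n_val=100,
        source_x_mm=(-15.0, 15.0),
        source_z_mm=(10.0, 42.0),
        network=NetworkSpec(n_blocks=16, channels=64),
        epochs=80,
    )


def smoke_profile() -> StudyProfile:
    geom = ArrayGeometry()
    dz = geom.sound_speed_m_s / geom.sampling_freq_hz * 1e3
    grid = ImageGrid(x0_mm=-19.05, z0_mm=22.0, dx_mm=0.3, dz_mm=dz, nx=128, nz=512)
    return StudyProfile(
        geometry=geom,
        pulse=Pulse(),
        grid=grid,
        n_train=200,
        n_val=8,
        source_x_mm=(-12.0, 12.0),
        source_z_mm=(24.0, 38.0),
        network=NetworkSpec(n_blocks=4, channels=16),
        epochs=20,
    )
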