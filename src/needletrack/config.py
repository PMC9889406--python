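"""YAML pipeline configuration.

One document with a section per stage; every field has the package
default, so an empty file yields the full default configuration
(128 elements across 38.4 mm, 1500 m/s, sigma = [4, 2] px kernel).
Unknown keys are rejected and cross-section inconsistencies are
reported together in a single validation error.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .dataset import SNR_RANGE, DatasetSpec, KernelSpec
from .enhancer import NetworkSpec, TrainSpec
from .geometry import ArrayGeometry, ImageGrid, Pulse, default_grid

__all__ = ["PipelineConfig", "load_config", "save_config", "config_hash"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AcquisitionConfig(_Section):
    n_elements: int = 128
    aperture_mm: float = 38.4
    element_width_mm: float | None = None
    sampling_freq_hz: float = 40e6
    sound_speed_m_s: float = 1500.0
    pulse_center_freq_hz: float = 0.6e6
    pulse_fractional_bandwidth: float = 1.7
    n_sub_elements: int = 8

    def geometry(self) -> ArrayGeometry:
        return ArrayGeometry(
            n_elements=self.n_elements,
            aperture_mm=self.aperture_mm,
            element_width_mm=self.element_width_mm,
            sampling_freq_hz=self.sampling_freq_hz,
            sound_speed_m_s=self.sound_speed_m_s,
        )

    def pulse(self) -> Pulse:
        return Pulse(
            center_freq_hz=self.pulse_center_freq_hz,
            fractional_bandwidth=self.pulse_fractional_bandwidth,
        )


class GridConfig(_Section):
    # None -> derived from the acquisition section (dx = pitch,
    # dz = c/fs, lateral pixels on the element centres, z in [0, z_max])
    x0_mm: float | None = None
    z0_mm: float = 0.0
    dx_mm: float | None = None
    dz_mm: float | None = None
    nx: int | None = None
    nz: int | None = None
    z_max_mm: float = 45.0

    def grid(self, acq: AcquisitionConfig) -> ImageGrid:
        base = default_grid(acq.geometry(), z_max_mm=self.z_max_mm)
        dz = self.dz_mm if self.dz_mm is not None else base.dz_mm
        nz = self.nz if self.nz is not None else int(round((self.z_max_mm - self.z0_mm) / dz))
        return ImageGrid(
            x0_mm=self.x0_mm if self.x0_mm is not None else base.x0_mm,
            z0_mm=self.z0_mm,
            dx_mm=self.dx_mm if self.dx_mm is not None else base.dx_mm,
            dz_mm=dz,
            nx=self.nx if self.nx is not None else base.nx,
            nz=nz,
        )


class DatasetConfig(_Section):
    n_images: int = 1000
    n_validation: int = 100
    sigma_z_px: float = 4.0
    sigma_x_px: float = 2.0
    snr_min: float = SNR_RANGE[0]
    snr_max: float = SNR_RANGE[1]
    x_min_mm: float = -15.0
    x_max_mm: float = 15.0
    z_min_mm: float = 10.0
    z_max_mm: float = 42.0

    def kernel(self) -> KernelSpec:
        return KernelSpec(sigma_z_px=self.sigma_z_px, sigma_x_px=self.sigma_x_px)

    def spec(self, seed: int, n_images: int | None = None) -> DatasetSpec:
        return DatasetSpec(
            n_images=n_images if n_images is not None else self.n_images,
            kernel=self.kernel(),
            snr_range=(self.snr_min, self.snr_max),
            x_range_mm=(self.x_min_mm, self.x_max_mm),
            z_range_mm=(self.z_min_mm, self.z_max_mm),
            seed=seed,
        )


class NetworkConfig(_Section):
    n_blocks: int = 16
    channels: int = 64
    conv_kernel: int = 3
    nonlinearity: str = "relu"

    def spec(self) -> NetworkSpec:
        return NetworkSpec(
            n_blocks=self.n_blocks,
            channels=self.channels,
            conv_kernel=self.conv_kernel,
            nonlinearity=self.nonlinearity,
        )


class TrainingConfig(_Section):
    epochs: int = 80
    batch_size: int = 16
    patch_px: int = 64
    learning_rate: float = 1e-3
    loss: str = "L1"
    optimizer: str = "adam"
    steps_per_epoch: int | None = None

    def spec(self, seed: int) -> TrainSpec:
        return TrainSpec(
            epochs=self.epochs,
            batch_size=self.batch_size,
            patch_px=self.patch_px,
            learning_rate=self.learning_rate,
            loss=self.loss,
            optimizer=self.optimizer,
            seed=seed,
            steps_per_epoch=self.steps_per_epoch,
        )


class EvaluationConfig(_Section):
    box_mm: float = 5.0
    object_threshold_db: float = -6.0


class PipelineConfig(_Section):
    acquisition: AcquisitionConfig = Field(default_factory=AcquisitionConfig)
    grid: GridConfig = Field(default_factory=GridConfig)
    dataset: DatasetConfig = Field(default_factory=DatasetConfig)
    network: NetworkConfig = Field(default_factory=NetworkConfig)
    training: TrainingConfig = Field(default_factory=TrainingConfig)
    evaluation: EvaluationConfig = Field(default_factory=EvaluationConfig)
    seed: int = 0

    @model_validator(mode="after")
    def _cross_checks(self) -> "PipelineConfig":
        problems: list[str] = []
        try:
            geom = self.acquisition.geometry()
            self.acquisition.pulse()
        except ValueError as exc:
            problems.append(f"acquisition: {exc}")
            geom = None
        grid = None
        if geom is not None:
            try:
                grid = self.grid.grid(self.acquisition)
            except ValueError as exc:
                problems.append(f"grid: {exc}")
        if grid is not None:
            half = 0.5 * geom.aperture_mm
            x_lo, x_hi, z_lo, z_hi = grid.extent_mm
            if x_lo < -1.5 * half or x_hi > 1.5 * half:
                problems.append("grid: lateral extent far outside the array aperture")
            if grid.dx_mm > geom.element_pitch_mm * (1 + 1e-9):
                problems.append("grid: dx coarser than the element pitch (lateral Nyquist)")
            if self.training.patch_px > min(grid.nx, grid.nz):
                problems.append(
                    f"training: patch_px={self.training.patch_px} exceeds the image "
                    f"size ({grid.nz} x {grid.nx})"
                )
            ds = self.dataset
            if not (
                x_lo <= ds.x_min_mm <= ds.x_max_mm <= x_hi
                and z_lo <= ds.z_min_mm <= ds.z_max_mm <= z_hi
            ):
                problems.append("dataset: source region must lie inside the image grid")
        if self.dataset.sigma_z_px <= 0 or self.dataset.sigma_x_px <= 0:
            problems.append("dataset: kernel sigmas must be positive")
        if self.dataset.snr_min <= 0 or self.dataset.snr_max < self.dataset.snr_min:
            problems.append("dataset: SNR range must be positive and ordered")
        if problems:
            raise ValueError("invalid configuration:\n  - " + "\n  - ".join(problems))
        return self


def load_config(path=None) -> PipelineConfig:
    """Load and validate a YAML config; ``None`` or an empty file gives
    the full default configuration."""
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return PipelineConfig()
    if not isinstance(data, dict):
        raise ValueError("config must be a YAML mapping")
    return PipelineConfig.model_validate(data)


def save_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))


def config_hash(cfg: PipelineConfig) -> str:
    """Stable short hash of the canonical YAML serialization."""
    canon = yaml.safe_dump(cfg.model_dump(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
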