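"""Serialization of channel data, datasets, images and models.

Formats:

* channel data — HDF5: dataset ``samples`` [n_samples x n_elements]
  with attributes ``fs_hz``, ``t0_s``, ``c_m_s``, ``pitch_mm``,
  ``aperture_mm`` (plus element count/width).
* training corpus — HDF5: arrays ``inputs`` / ``targets``
  [n x nz x nx], ``sources`` [n x 2] (x, z in mm), ``snr`` [n], plus
  grid and geometry attributes.
* images — 32-bit float TIFF plus a JSON sidecar (``<image>.json``)
  carrying the grid geometry and the normalization flag.
* models — ``.npz`` weights plus a JSON architecture sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import tifffile

from .acoustics import ChannelData
from .dataset import TrainingPair
from .geometry import ArrayGeometry, ImageGrid, PointSource
from .nn import ResidualCNN
from .reconstruction import TrackingImage

__all__ = [
    "save_channel_data",
    "load_channel_data",
    "save_dataset",
    "load_dataset",
    "save_image",
    "load_image",
    "save_model",
    "load_model",
]


def _geometry_attrs(geom: ArrayGeometry) -> dict:
    return {
        "fs_hz": geom.sampling_freq_hz,
        "c_m_s": geom.sound_speed_m_s,
        "pitch_mm": geom.element_pitch_mm,
        "aperture_mm": geom.aperture_mm,
        "n_elements": geom.n_elements,
        "element_width_mm": geom.element_width_mm,
    }


def _geometry_from_attrs(attrs) -> ArrayGeometry:
    return ArrayGeometry(
        n_elements=int(attrs["n_elements"]),
        aperture_mm=float(attrs["aperture_mm"]),
        element_width_mm=float(attrs["element_width_mm"]),
        sampling_freq_hz=float(attrs["fs_hz"]),
        sound_speed_m_s=float(attrs["c_m_s"]),
    )


def _grid_attrs(grid: ImageGrid) -> dict:
    return {
        "x0_mm": grid.x0_mm,
        "z0_mm": grid.z0_mm,
        "dx_mm": grid.dx_mm,
        "dz_mm": grid.dz_mm,
        "nx": grid.nx,
        "nz": grid.nz,
    }


def _grid_from_attrs(attrs) -> ImageGrid:
    return ImageGrid(
        x0_mm=float(attrs["x0_mm"]),
        z0_mm=float(attrs["z0_mm"]),
        dx_mm=float(attrs["dx_mm"]),
        dz_mm=float(attrs["dz_mm"]),
        nx=int(attrs["nx"]),
        nz=int(attrs["nz"]),
    )


def save_channel_data(cd: ChannelData, path) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("samples", data=cd.samples)
        for k, v in _geometry_attrs(cd.geometry).items():
            ds.attrs[k] = v
        ds.attrs["t0_s"] = cd.t0_s


def load_channel_data(path) -> ChannelData:
    with h5py.File(path, "r") as fh:
        ds = fh["samples"]
        return ChannelData(
            samples=ds[...],
            sampling_freq_hz=float(ds.attrs["fs_hz"]),
            t0_s=float(ds.attrs["t0_s"]),
            geometry=_geometry_from_attrs(ds.attrs),
        )


def save_dataset(pairs: Sequence[TrainingPair], path, geom: ArrayGeometry | None = None) -> None:
    if not pairs:
        raise ValueError("nothing to save")
    grid = pairs[0].input.grid
    with h5py.File(path, "w") as fh:
        fh.create_dataset(
            "inputs", data=np.stack([p.input.pixels for p in pairs]).astype(np.float32)
        )
        fh.create_dataset(
            "targets", data=np.stack([p.target.pixels for p in pairs]).astype(np.float32)
        )
        fh.create_dataset(
            "sources", data=np.array([[p.source.x_mm, p.source.z_mm] for p in pairs])
        )
        fh.create_dataset("snr", data=np.array([p.snr for p in pairs]))
        for k, v in _grid_attrs(grid).items():
            fh.attrs[k] = v
        if geom is not None:
            for k, v in _geometry_attrs(geom).items():
                fh.attrs[k] = v


def load_dataset(path) -> list[TrainingPair]:
    with h5py.File(path, "r") as fh:
        grid = _grid_from_attrs(fh.attrs)
        inputs = fh["inputs"][...]
        targets = fh["targets"][...]
        sources = fh["sources"][...]
        snr = fh["snr"][...]
    pairs = []
    for xi, ti, (sx, sz), s in zip(inputs, targets, sources, snr):
        pairs.append(
            TrainingPair(
                input=TrackingImage(np.asarray(xi, dtype=np.float64), grid, normalized=True),
                target=TrackingImage(np.asarray(ti, dtype=np.float64), grid, normalized=True),
                source=PointSource(float(sx), float(sz)),
                snr=float(s),
            )
        )
    return pairs


def save_image(img: TrackingImage, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, img.pixels.astype(np.float32))
    meta = dict(_grid_attrs(img.grid), normalized=img.normalized)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_image(path) -> TrackingImage:
    path = Path(path)
    pixels = tifffile.imread(path).astype(np.float64)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    grid = _grid_from_attrs(meta)
    img = TrackingImage(pixels, grid, normalized=False)
    if meta.get("normalized"):
        # float32 round-trip can nudge the peak off exactly 1
        pixels = np.clip(img.pixels, 0.0, 1.0)
        pixels[np.unravel_index(np.argmax(pixels), pixels.shape)] = 1.0
        img = TrackingImage(pixels, grid, normalized=True)
    return img


def save_model(model: ResidualCNN, weights_path, arch_path=None) -> None:
    weights_path = Path(weights_path)
    if arch_path is None:
        arch_path = weights_path.with_suffix(".json")
    model.save(weights_path, arch_path)


def load_model(weights_path, arch_path=None) -> ResidualCNN:
    weights_path = Path(weights_path)
    if arch_path is None:
        arch_path = weights_path.with_suffix(".json")
    return ResidualCNN.load(weights_path, arch_path=arch_path)
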