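"""Stage orchestration with provenance.

``run_pipeline`` executes the stages ``simulate`` -> ``make-dataset``
-> ``train`` -> ``enhance`` -> ``evaluate`` in order, writing each
stage's artifact under an output directory together with a manifest
(config hash, root seed, per-stage seeds, package version).  Re-running
with the same configuration skips stages whose artifacts already exist
under the same config hash, unless forced.  All randomness derives from
one root seed, split deterministically per stage.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np

from . import __version__
from .config import PipelineConfig, config_hash
from .dataset import generate_dataset
from .enhancer import build_network, enhance, train
from .evaluation import localization_error, measure_fwhm
from .geometry import PointSource
from .io import (
    load_dataset,
    load_image,
    load_model,
    save_channel_data,
    save_dataset,
    save_image,
    save_model,
)
from .acoustics import add_noise, simulate_channel_data
from .reconstruction import envelope_normalize, reconstruct_fk

STAGES = ("simulate", "make-dataset", "train", "enhance", "evaluate")

log = logging.getLogger("needletrack")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s:%(stage)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


def _stage_log(stage: str, msg: str) -> None:
    log.info(msg, extra={"stage": stage})


def _stage_seeds(root_seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(root_seed)
    children = ss.spawn(len(STAGES) + 2)
    seeds = {}
    for name, child in zip(STAGES + ("validation", "heldout"), children):
        seeds[name] = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
    return seeds


def run_pipeline(
    config: PipelineConfig,
    stages: list[str] | None = None,
    out_dir="pipeline_out",
    force: bool = False,
) -> dict[str, str]:
    """Run the requested stages; returns a stage -> artifact path map."""
    stages = list(stages) if stages else list(STAGES)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; choose from {STAGES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    seeds = _stage_seeds(config.seed)

    manifest_path = out / "manifest.json"
    manifest = {"config_hash": chash, "root_seed": config.seed,
                "stage_seeds": seeds, "version": __version__, "artifacts": {}}
    if manifest_path.exists():
        prev = json.loads(manifest_path.read_text())
        if prev.get("config_hash") == chash and not force:
            manifest["artifacts"] = prev.get("artifacts", {})

    geom = config.acquisition.geometry()
    pulse = config.acquisition.pulse()
    grid = config.grid.grid(config.acquisition)
    n_sub = config.acquisition.n_sub_elements

    paths = {
        "simulate": out / "channels.h5",
        "make-dataset": out / "dataset.h5",
        "train": out / "model.npz",
        "enhance": out / "enhanced.tiff",
        "evaluate": out / "report.json",
    }

    def done(stage: str) -> bool:
        return (
            not force
            and stage in manifest["artifacts"]
            and Path(manifest["artifacts"][stage]).exists()
        )

    def mark(stage: str) -> None:
        manifest["artifacts"][stage] = str(paths[stage])
        manifest_path.write_text(json.dumps(manifest, indent=2))

    ds_cfg = config.dataset
    heldout_src = PointSource(
        0.5 * (ds_cfg.x_min_mm + ds_cfg.x_max_mm) + 0.25 * (ds_cfg.x_max_mm - ds_cfg.x_min_mm),
        0.5 * (ds_cfg.z_min_mm + ds_cfg.z_max_mm),
    )

    for stage in STAGES:
        if stage not in stages:
            continue
        if done(stage):
            _stage_log(stage, "artifact up to date, skipping")
            continue
        if stage == "simulate":
            _stage_log(stage, f"simulating source at ({heldout_src.x_mm:.1f}, "
                              f"{heldout_src.z_mm:.1f}) mm")
            cd = simulate_channel_data(heldout_src, geom, pulse, n_sub=n_sub)
            snr = float(np.sqrt(ds_cfg.snr_min * ds_cfg.snr_max))
            cd = add_noise(cd, snr, seeds["simulate"])
            save_channel_data(cd, paths["simulate"])
        elif stage == "make-dataset":
            _stage_log(stage, f"generating {ds_cfg.n_images}+{ds_cfg.n_validation} pairs")
            tr = generate_dataset(ds_cfg.spec(seeds["make-dataset"]), geom, grid, pulse, n_sub)
            va = generate_dataset(
                ds_cfg.spec(seeds["validation"], n_images=ds_cfg.n_validation),
                geom, grid, pulse, n_sub,
            )
            save_dataset(tr + va, paths["make-dataset"], geom)
        elif stage == "train":
            if not paths["make-dataset"].exists():
                raise FileNotFoundError("train needs the dataset; run 'make-dataset' first")
            pairs = load_dataset(paths["make-dataset"])
            tr, va = pairs[: ds_cfg.n_images], pairs[ds_cfg.n_images :]
            _stage_log(stage, f"training on {len(tr)} pairs / validating on {len(va)}")
            model = build_network(config.network.spec(), seed=seeds["train"])
            model, hist = train(model, tr, va, config.training.spec(seeds["train"]))
            save_model(model, paths["train"])
            hist.to_csv(out / "training_log.csv")
        elif stage == "enhance":
            if not paths["train"].exists():
                raise FileNotFoundError("enhance needs a model; run 'train' first")
            if not paths["simulate"].exists():
                raise FileNotFoundError("enhance needs channel data; run 'simulate' first")
            from .io import load_channel_data

            cd = load_channel_data(paths["simulate"])
            raw = envelope_normalize(reconstruct_fk(cd, grid))
            save_image(raw, out / "raw.tiff")
            model = load_model(paths["train"])
            save_image(enhance(model, raw), paths["enhance"])
            _stage_log(stage, "enhanced image written")
        elif stage == "evaluate":
            if not (out / "raw.tiff").exists() or not paths["enhance"].exists():
                raise FileNotFoundError("evaluate needs images; run 'enhance' first")
            raw = load_image(out / "raw.tiff")
            enh = load_image(paths["enhance"])
            report = {
                "seed": config.seed,
                "config_hash": chash,
                "raw": measure_fwhm(raw, config.evaluation.box_mm).to_dict(),
                "enhanced": measure_fwhm(enh, config.evaluation.box_mm).to_dict(),
                "raw_localization_error_mm": localization_error(raw, heldout_src),
                "enhanced_localization_error_mm": localization_error(enh, heldout_src),
            }
            paths["evaluate"].write_text(json.dumps(report, indent=2))
            _stage_log(stage, f"axial FWHM {report['raw']['axial_fwhm_mm']:.2f} -> "
                              f"{report['enhanced']['axial_fwhm_mm']:.2f} mm")
        mark(stage)
    return {s: str(paths[s]) for s in stages}
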