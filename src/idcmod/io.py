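"""Recording I/O, configuration loading, and pipeline orchestration.

Recordings are stored as HDF5 (samples + axis metadata) and round-trip
bit-exactly.  Configs are YAML (JSON accepted).  ``run_pipeline`` ties the
stages into one deterministic, seeded run writing its artifacts and a log
of every parameter to a directory.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import field as field_mod
from . import kernel as kernel_mod
from .behavior import fit_lmm
from .esa import bandpass_mua, epoch_mean, esa_transform, percent_change
from .recording import EpochWindows, Recording
from .rods import default_morphology
from .synth import (BehaviorSimConfig, SpontaneousSimConfig,
                    simulate_spontaneous, simulate_vonfrey)

__all__ = ["read_recording", "write_recording", "load_config", "run_pipeline"]

logger = logging.getLogger("idcmod")


def write_recording(rec: Recording, path) -> None:
    """Write a recording to HDF5 (lossless)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=rec.samples)
        f.attrs["fs_hz"] = rec.sampling_rate
        if rec.channel_depths_mm is not None:
            f.create_dataset("channel_depths_mm", data=rec.channel_depths_mm)
        f.attrs["epochs_s"] = json.dumps(
            {"pre": rec.epochs.pre, "during": rec.epochs.during,
             "post": rec.epochs.post})
        if rec.onsets_s is not None:
            f.create_dataset("onsets_s", data=rec.onsets_s)
        if rec.intensity_ma is not None:
            f.attrs["intensity_ma"] = rec.intensity_ma
        if rec.idc_amplitude_ua is not None:
            f.attrs["idc_amplitude_ua"] = rec.idc_amplitude_ua


def read_recording(path) -> Recording:
    """Read a recording written by :func:`write_recording`.

    Missing required metadata raises a schema error naming the keys.
    """
    with h5py.File(path, "r") as f:
        missing = [k for k in ("fs_hz",) if k not in f.attrs]
        if "samples" not in f:
            missing.append("samples")
        if missing:
            raise KeyError(f"recording file missing required keys: {missing}")
        epochs = EpochWindows()
        if "epochs_s" in f.attrs:
            d = json.loads(f.attrs["epochs_s"])
            epochs = EpochWindows(tuple(d["pre"]), tuple(d["during"]),
                                  tuple(d["post"]))
        return Recording(
            samples=f["samples"][...],
            sampling_rate=float(f.attrs["fs_hz"]),
            channel_depths_mm=(f["channel_depths_mm"][...]
                               if "channel_depths_mm" in f else None),
            epochs=epochs,
            onsets_s=f["onsets_s"][...] if "onsets_s" in f else None,
            intensity_ma=(float(f.attrs["intensity_ma"])
                          if "intensity_ma" in f.attrs else None),
            idc_amplitude_ua=(float(f.attrs["idc_amplitude_ua"])
                              if "idc_amplitude_ua" in f.attrs else None),
        )


def load_config(path) -> dict:
    """Load a YAML (or JSON) config file into a dict."""
    text = Path(path).read_text()
    return yaml.safe_load(text)


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the configured stages; write artifacts and a parameter log.

    Recognized stages (``config["stages"]``): ``field`` (disk field +
    gain kernel), ``spontaneous`` (simulate + ESA percent change),
    ``vonfrey`` (simulate + LMM fit).  Unknown stage names raise a usage
    error.  Deterministic given ``config["seed"]``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", ["field"])
    known = {"field", "spontaneous", "vonfrey"}
    unknown = set(stages) - known
    if unknown:
        raise ValueError(f"unknown stage(s) {sorted(unknown)}; choose from {sorted(known)}")
    artifacts: dict = {"seed": seed, "stages": list(stages)}

    if "field" in stages:
        tissue = field_mod.TissueModel(
            resistivity=config.get("resistivity_ohm_mm", 5e3),
            lateral_extent=config.get("extent_mm", 2.2),
            depth_extent=config.get("extent_mm", 2.2),
            grid_spacing=config.get("spacing_mm", 0.01))
        source = field_mod.DiskSource(
            center_lateral=config.get("disk_center_mm", 1.1),
            diameter=config.get("disk_diameter_mm", 0.25),
            current=config.get("current_ua", 20.0) * 1e-6)
        grid = field_mod.disk_field(tissue, source)
        np.save(out / "field.npy", grid.potentials)
        specs = default_morphology()
        placements = kernel_mod.scatter_rods(
            specs, config.get("total_rods", 500), tissue.lateral_extent,
            seed=seed)
        kernel_mod.polarize_placements(grid, placements, specs)
        kmap = kernel_mod.interpolate_kernel(placements, tissue.lateral_extent,
                                             tissue.depth_extent, seed=seed)
        np.save(out / "gain_kernel.npy", kmap.values)
        artifacts["field"] = str(out / "field.npy")
        artifacts["gain_kernel"] = str(out / "gain_kernel.npy")

    if "spontaneous" in stages:
        cfg = SpontaneousSimConfig(
            duration_s=config.get("duration_s", 90.0),
            n_channels=config.get("n_channels", 32),
            gain_profile=config.get("gain_profile"),
            noise_sd_uv=config.get("noise_sd_uv", 5.0),
            seed=seed)
        rec = simulate_spontaneous(cfg)
        write_recording(rec, out / "spontaneous.h5")
        mua = bandpass_mua(rec)
        env = esa_transform(mua.samples, mua.sampling_rate)
        pre = epoch_mean(env, mua.sampling_rate, rec.epochs.pre)
        dur = epoch_mean(env, mua.sampling_rate, rec.epochs.during)
        pc = percent_change(dur, pre)
        pd.DataFrame({"depth_mm": rec.channel_depths_mm,
                      "percent_change": pc}).to_csv(
            out / "esa_percent_change.csv", index=False)
        artifacts["spontaneous"] = str(out / "spontaneous.h5")
        artifacts["esa_percent_change"] = str(out / "esa_percent_change.csv")

    if "vonfrey" in stages:
        cfg = BehaviorSimConfig(seed=seed)
        blocks = simulate_vonfrey(cfg)
        blocks.to_csv(out / "vonfrey_blocks.csv", index=False)
        fit = fit_lmm(blocks[blocks["paw"] == "contra"])
        fit.contrasts.to_csv(out / "lmm_contrasts_contra.csv", index=False)
        artifacts["vonfrey_blocks"] = str(out / "vonfrey_blocks.csv")
        artifacts["lmm_contrasts"] = str(out / "lmm_contrasts_contra.csv")

    (out / "run_log.json").write_text(json.dumps(
        {"config": {k: v for k, v in config.items()}, "artifacts": artifacts},
        indent=2, default=str))
    return artifacts
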