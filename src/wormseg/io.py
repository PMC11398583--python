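"""File formats: TIFF image stacks, CSV tables, JSON manifests, checkpoints.

On-disk dataset layout (written by ``wormseg simulate``, read by the other
commands)::

    <dir>/manifest.json          run provenance (config, seed, versions)
    <dir>/layout.csv             well, fov, channel, class, dose_um, seed
    <dir>/images/<id>_bf.tif     brightfield hyperstack, pages T-outer/Z-inner
    <dir>/images/<id>_fl.tif     fluorescence z-stack (Z pages)
    <dir>/masks/<id>_mask.tif    ground-truth mask, 8-bit 0/255

with ``<id> = <well>_f<fov>_c<channel>``.  Model checkpoints are numpy
``.npz`` archives embedding the network configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .model import NetworkConfig, WormSegNet
from .synthetic_data import (ChannelRecord, ChannelStack, DeviceDataset,
                             DosePlan, SceneConfig)

__all__ = [
    "record_id", "write_dataset", "load_dataset", "save_checkpoint",
    "load_checkpoint", "write_manifest", "write_mask",
]


def record_id(rec: ChannelRecord) -> str:
    s = rec.stack
    return f"{s.well_id}_f{s.fov_index}_c{s.channel_index}"


def _config_dict(obj) -> dict:
    d = dataclasses.asdict(obj)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def write_manifest(path: Path, seed: int, configs: dict, extra: dict | None
                   = None) -> dict:
    """Write a run manifest recording configs (with hash), seed, versions."""
    payload = {k: _config_dict(v) if dataclasses.is_dataclass(v) else v
               for k, v in configs.items()}
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    manifest = {
        "tool": "wormseg",
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": seed,
        "config": payload,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
    }
    if extra:
        manifest.update(extra)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def write_mask(path: Path, grid: np.ndarray) -> None:
    tifffile.imwrite(path, (np.asarray(grid, bool) * np.uint8(255)))


def write_dataset(dataset: DeviceDataset, out_dir: str | Path) -> Path:
    """Write a simulated device dataset to disk in the documented layout."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    for rec in dataset.records:
        rid = record_id(rec)
        vol = rec.stack.volume  # (T, Z, Y, X) -> pages T outer, Z inner
        tifffile.imwrite(out / "images" / f"{rid}_bf.tif",
                         vol.reshape((-1,) + vol.shape[2:]))
        if rec.fluorescence is not None:
            tifffile.imwrite(out / "images" / f"{rid}_fl.tif",
                             rec.fluorescence)
        write_mask(out / "masks" / f"{rid}_mask.tif", rec.mask)
    dataset.layout.to_csv(out / "layout.csv", index=False)
    write_manifest(
        out / "manifest.json", dataset.seed,
        {"scene": dataset.scene, "plan": dataset.plan},
        extra={
            "n_records": len(dataset.records),
            "volume_shape": list(dataset.records[0].stack.volume.shape),
        },
    )
    return out


def load_dataset(in_dir: str | Path) -> DeviceDataset:
    """Load a dataset written by :func:`write_dataset`."""
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    scene_kw = dict(manifest["config"]["scene"])
    scene_kw["class_mix"] = tuple(scene_kw["class_mix"])
    scene_kw["contrast_range"] = tuple(scene_kw["contrast_range"])
    scene = SceneConfig(**scene_kw)
    plan_kw = dict(manifest["config"]["plan"])
    plan_kw["doses_um"] = tuple(plan_kw["doses_um"])
    plan_kw["af_hill"] = tuple(plan_kw["af_hill"])
    plan = DosePlan(**plan_kw)
    layout = pd.read_csv(src / "layout.csv")
    t, z = scene.n_timepoints, scene.n_z
    records = []
    for _, row in layout.iterrows():
        rid = f"{row['well']}_f{row['fov']}_c{row['channel']}"
        pages = tifffile.imread(src / "images" / f"{rid}_bf.tif")
        if pages.ndim == 2:
            pages = pages[None]
        vol = pages.reshape(t, z, *pages.shape[-2:])
        fl_path = src / "images" / f"{rid}_fl.tif"
        fluor = tifffile.imread(fl_path) if fl_path.exists() else None
        if fluor is not None and fluor.ndim == 2:
            fluor = fluor[None]
        mask = tifffile.imread(src / "masks" / f"{rid}_mask.tif") > 0
        stack = ChannelStack(
            volume=vol, well_id=str(row["well"]), fov_index=int(row["fov"]),
            channel_index=int(row["channel"]),
            pixel_size_um=scene.pixel_size_um, z_step_um=scene.z_step_um,
        )
        records.append(
            ChannelRecord(stack=stack, fluorescence=fluor, mask=mask,
                          class_label=str(row["class"]),
                          dose_um=float(row["dose_um"]))
        )
    return DeviceDataset(records=records, layout=layout, plan=plan,
                         scene=scene, seed=int(manifest["seed"]))


def save_checkpoint(path: str | Path, model: WormSegNet) -> None:
    """Serialize weights + embedded NetworkConfig to a .npz archive."""
    state = model.state_dict()
    cfg = json.dumps(_config_dict(model.cfg))
    np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path: str | Path) -> WormSegNet:
    with np.load(path) as archive:
        cfg_kw = json.loads(bytes(archive["__config__"].tobytes()).decode())
        cfg_kw["max_input_hw"] = tuple(cfg_kw["max_input_hw"])
        cfg = NetworkConfig(**cfg_kw)
        model = WormSegNet(cfg, seed=0)
        state = {k: archive[k] for k in archive.files if k != "__config__"}
    model.load_state_dict(state)
    return model
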