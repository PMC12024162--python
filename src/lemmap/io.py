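"""Disk formats: PNG images and masks, CSV labels and logs, JSON manifests,
single-file checkpoints.

Images are written as 16-bit grayscale PNG and standardised to [0, 1] on
read regardless of bit depth; masks are 8-bit PNG with values {0, 255}.
A dataset directory looks like::

    out/
      images/<id>.png
      masks/<id>.png        (synthetic datasets only)
      labels.csv            (columns: id, label)
      manifest.json

Checkpoints are numpy ``.npz`` archives bundling the weights, the config and
the training history.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .config import LemConfig
from .synthetic import LabeledImage
from .training import TrainState, build_tiny_backbone

__all__ = [
    "write_image_png", "read_image_png", "write_mask_png", "read_mask_png",
    "save_dataset", "load_dataset", "write_manifest",
    "save_checkpoint", "load_checkpoint",
    "write_score_csv", "write_heatmap_png",
]


def write_image_png(path, pixels: np.ndarray) -> None:
    arr = np.clip(np.asarray(pixels, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 65535.0).round().astype(np.uint16)).save(path)


def read_image_png(path) -> np.ndarray:
    img = Image.open(path)
    arr = np.asarray(img, dtype=float)
    if img.mode in ("I", "I;16", "I;16B"):
        return arr / 65535.0
    if img.mode == "L":
        return arr / 255.0
    if img.mode in ("F",):
        return np.clip(arr, 0.0, 1.0)
    # fall back: normalise by the dtype maximum of the underlying array
    info = np.iinfo(np.asarray(img).dtype)
    return arr / info.max


def read_image_dicom(path) -> np.ndarray:
    """Optional DICOM ingestion (requires ``pydicom``), standardised to [0, 1].

    Real mammograms ship as DICOM; this converts a single-frame grayscale
    file to the package's internal representation.  Nothing else depends on
    it, so environments without pydicom lose only this reader.
    """
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional path
        raise ImportError("DICOM ingestion requires the 'pydicom' package") from exc
    arr = pydicom.dcmread(str(path)).pixel_array.astype(float)
    lo, hi = arr.min(), arr.max()
    return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)


def write_mask_png(path, mask: np.ndarray) -> None:
    Image.fromarray(np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)).save(path)


def read_mask_png(path) -> np.ndarray:
    return np.asarray(Image.open(path)) > 127


def write_manifest(path, command: str, config: LemConfig | None, seed: int | None,
                   inputs: dict | None = None, outputs: dict | None = None) -> None:
    manifest = {
        "command": command,
        "config": config.to_dict() if config is not None else None,
        "seed": seed,
        "inputs": inputs or {},
        "outputs": outputs or {},
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")


def save_dataset(dataset: list[LabeledImage], out_dir, *, command="generate",
                 config: LemConfig | None = None, seed: int | None = None) -> None:
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    any_mask = any(im.mask is not None for im in dataset)
    if any_mask:
        (out / "masks").mkdir(exist_ok=True)
    for im in dataset:
        write_image_png(out / "images" / f"{im.id}.png", im.pixels)
        if im.mask is not None:
            write_mask_png(out / "masks" / f"{im.id}.png", im.mask)
    labels = pd.DataFrame({"id": [im.id for im in dataset],
                           "label": [im.label for im in dataset]})
    labels.to_csv(out / "labels.csv", index=False)
    write_manifest(out / "manifest.json", command, config, seed,
                   outputs={"n_images": len(dataset)})


def load_dataset(in_dir) -> list[LabeledImage]:
    root = Path(in_dir)
    labels_path = root / "labels.csv"
    if not labels_path.exists():
        raise FileNotFoundError(f"no labels.csv in {root}")
    labels = pd.read_csv(labels_path)
    out = []
    for _, row in labels.iterrows():
        iid = str(row["id"])
        pixels = read_image_png(root / "images" / f"{iid}.png")
        mask_path = root / "masks" / f"{iid}.png"
        mask = read_mask_png(mask_path) if mask_path.exists() else None
        out.append(LabeledImage(pixels=pixels, label=int(row["label"]),
                                mask=mask, id=iid))
    return out


def save_checkpoint(path, net, config: LemConfig, state: TrainState) -> None:
    payload = {f"param:{k}": v for k, v in net.state_dict().items()}
    payload["config_json"] = np.array(json.dumps(config.to_dict()))
    payload["history_json"] = np.array(json.dumps(state.history))
    np.savez(path, **payload)


def load_checkpoint(path):
    with np.load(path, allow_pickle=False) as z:
        config = LemConfig.from_dict(json.loads(str(z["config_json"])),
                                     require_explicit=False)
        history = json.loads(str(z["history_json"]))
        net = build_tiny_backbone(config, np.random.default_rng(config.seed))
        state_dict = {k[len("param:"):]: z[k] for k in z.files
                      if k.startswith("param:")}
    net.load_state_dict(state_dict)
    state = TrainState(epoch=len(history), history=history)
    if history:
        state.lr = history[-1]["lr"]
        state.alpha = history[-1]["alpha"]
    return net, config, state


def write_score_csv(path, grid: np.ndarray) -> None:
    np.savetxt(path, np.asarray(grid, dtype=float), delimiter=",", fmt="%.8g")


def write_heatmap_png(path, grid: np.ndarray, cmap: str = "magma") -> None:
    """Render a nonnegative grid as a colormapped PNG."""
    import matplotlib

    grid = np.asarray(grid, dtype=float)
    peak = grid.max()
    norm = grid / peak if peak > 0 else grid
    rgba = matplotlib.colormaps[cmap](norm)
    Image.fromarray((rgba[..., :3] * 255).astype(np.uint8)).save(path)
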