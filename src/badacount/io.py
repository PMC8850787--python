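"""File formats: dot-annotation CSVs, rasters, datasets and checkpoints.

Dot annotations travel as a CSV with header ``image,x,y`` (one row per
point, 0-based pixel coordinates, images referenced by relative path).
Density and count rasters are saved as single-band float TIFF or ``.npy``;
masks as 8-bit PNG (0/255).  A checkpoint is a single ``.npz`` archive of
parameter arrays with the model configuration embedded as JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .network import BadaModel, ModelConfig
from .synthetic_data import SyntheticDataset
from .targets import DotAnnotationSet, ForegroundMask

__all__ = [
    "read_dots_csv",
    "write_dots_csv",
    "save_raster",
    "load_raster",
    "save_mask_png",
    "load_mask_png",
    "save_checkpoint",
    "load_checkpoint",
    "save_dataset",
    "load_image_dir",
]


def read_dots_csv(path, image_sizes: dict[str, tuple[int, int]]) -> dict[str, DotAnnotationSet]:
    """Parse an ``image,x,y`` CSV into per-image annotation sets.

    ``image_sizes`` maps image name to ``(H, W)`` (needed for bounds
    validation); images present in the mapping but absent from the CSV get
    an empty annotation set.
    """
    df = pd.read_csv(path)
    required = {"image", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"dot CSV must have columns {sorted(required)}, got {list(df.columns)}")
    out: dict[str, DotAnnotationSet] = {}
    for name, (H, W) in image_sizes.items():
        rows = df[df["image"] == name]
        pts = rows[["x", "y"]].to_numpy(dtype=np.float64).reshape(-1, 2)
        out[name] = DotAnnotationSet(name, pts, (H, W))
    unknown = set(df["image"]) - set(image_sizes)
    if unknown:
        raise ValueError(f"dot CSV references unknown images: {sorted(unknown)[:5]}")
    return out


def write_dots_csv(path, dots_list: list[DotAnnotationSet]) -> None:
    rows = [
        {"image": d.image_id, "x": x, "y": y}
        for d in dots_list
        for x, y in d.points
    ]
    pd.DataFrame(rows, columns=["image", "x", "y"]).to_csv(path, index=False)


def save_raster(path, raster) -> None:
    """Save a density/count raster as float32 TIFF (or ``.npy``)."""
    values = raster.values if hasattr(raster, "values") else np.asarray(raster)
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, values)
    else:
        tifffile.imwrite(path, values.astype(np.float32))


def load_raster(path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".npy":
        return np.load(path)
    return np.asarray(tifffile.imread(path), dtype=np.float64)


def save_mask_png(path, mask: ForegroundMask) -> None:
    iio.imwrite(path, (mask.values.astype(np.uint8) * 255))


def load_mask_png(path) -> ForegroundMask:
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return ForegroundMask((arr > 127).astype(np.uint8))


# -- checkpoints --------------------------------------------------------------

def _named_parameters(model: BadaModel):
    for i, p in enumerate(model.parameters()):
        yield f"param_{i:04d}", p


def save_checkpoint(path, model: BadaModel) -> None:
    arrays = {name: p.data for name, p in _named_parameters(model)}
    arrays["__config__"] = np.frombuffer(
        json.dumps(_config_dict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> BadaModel:
    archive = np.load(path)
    cfg_json = bytes(archive["__config__"]).decode()
    model = BadaModel(config_from_dict(json.loads(cfg_json)))
    for name, p in _named_parameters(model):
        stored = archive[name]
        if stored.shape != p.data.shape:
            raise ValueError(f"checkpoint parameter {name} shape {stored.shape} != {p.data.shape}")
        p.data = np.asarray(stored, dtype=np.float64)
    return model


def _config_dict(config: ModelConfig) -> dict:
    d = asdict(config)
    d["encoder_channels"] = [list(s) for s in config.encoder_channels]
    d["decoder_channels"] = list(config.decoder_channels)
    d["regressor_channels"] = list(config.regressor_channels)
    return d


def config_from_dict(d: dict) -> ModelConfig:
    d = dict(d)
    d["encoder_channels"] = tuple(tuple(s) for s in d["encoder_channels"])
    d["decoder_channels"] = tuple(d["decoder_channels"])
    d["regressor_channels"] = tuple(d["regressor_channels"])
    return ModelConfig(**d)


# -- datasets -----------------------------------------------------------------

def save_dataset(out_dir, dataset: SyntheticDataset, manifest: dict | None = None) -> None:
    """Write a synthetic dataset as PNGs + dots CSV + mask PNGs + manifest."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    dots = []
    for i, (img, d, m) in enumerate(zip(dataset.images, dataset.dots, dataset.masks)):
        name = f"{d.image_id}.png"
        iio.imwrite(out / "images" / name, (np.clip(img, 0, 1) * 255).astype(np.uint8))
        save_mask_png(out / "masks" / name, m)
        dots.append(DotAnnotationSet(name, d.points, d.image_size))
    write_dots_csv(out / "dots.csv", dots)
    if manifest is not None:
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)


def load_image_dir(image_dir, dots_csv=None):
    """Load a directory of PNG/JPEG images, optionally with a dots CSV.

    Returns ``(images, dots_list)`` with images as float arrays in [0, 1];
    without a CSV every annotation set is empty (target-domain usage).
    """
    image_dir = Path(image_dir)
    paths = sorted(
        p for p in image_dir.iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg")
    )
    if not paths:
        raise ValueError(f"no images found in {image_dir}")
    images = [np.asarray(iio.imread(p), dtype=np.float64)[..., :3] / 255.0 for p in paths]
    sizes = {p.name: img.shape[:2] for p, img in zip(paths, images)}
    if dots_csv is None:
        dots_list = [
            DotAnnotationSet(p.name, np.empty((0, 2)), img.shape[:2])
            for p, img in zip(paths, images)
        ]
    else:
        by_name = read_dots_csv(dots_csv, sizes)
        dots_list = [by_name[p.name] for p in paths]
    return images, dots_list
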