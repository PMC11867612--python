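"""File-format glue: TIFF stacks with JSON sidecars, label maps, grids, tables."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from boutonmap.atlas import RegionMap
from boutonmap.preprocess import ImageStack
from boutonmap.quantify import VoxelGrid

__all__ = [
    "save_stack",
    "load_stack",
    "save_region_map",
    "load_region_map",
    "save_grid",
    "load_grid",
    "sha256_of",
    "write_json",
]


def write_json(path: Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def sha256_of(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _sidecar(path: Path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".json")


def save_stack(path: Path, stack: ImageStack, seed: int | None = None) -> None:
    """Multi-page TIFF in CZYX order plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.voxels, dtype=np.float32))
    write_json(
        _sidecar(path),
        {
            "axes": "CZYX",
            "voxel_size_um": list(stack.voxel_size_um),
            "channel_names": list(stack.channel_names),
            "seed": seed,
        },
    )


def load_stack(path: Path) -> ImageStack:
    path = Path(path)
    meta_path = _sidecar(path)
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    data = tifffile.imread(path)
    if data.ndim == 3:  # single channel
        data = data[None]
    if data.ndim != 4:
        raise ValueError(f"stack {path} must be (C, Z, Y, X); got shape {data.shape}")
    return ImageStack(
        data,
        tuple(meta["voxel_size_um"]),
        channel_names=tuple(meta["channel_names"]),
    )


def save_region_map(path: Path, region_map: RegionMap) -> None:
    path = Path(path)
    tifffile.imwrite(path, region_map.label_image.astype(np.uint16))
    write_json(
        _sidecar(path),
        {
            "pixel_size_um": list(region_map.pixel_size_um),
            "id_to_name": {str(k): v for k, v in region_map.id_to_name.items()},
        },
    )


def load_region_map(path: Path) -> RegionMap:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    labels = tifffile.imread(path)
    return RegionMap(
        labels,
        tuple(meta["pixel_size_um"]),
        {int(k): v for k, v in meta["id_to_name"].items()},
    )


def save_grid(path: Path, grid: VoxelGrid) -> None:
    """Counts as one TIFF page per z-bin (ZYX) plus geometry sidecar."""
    path = Path(path)
    pages = np.transpose(grid.counts, (2, 1, 0)).astype(np.float32)
    tifffile.imwrite(path, pages)
    write_json(
        _sidecar(path),
        {
            "origin_um": list(grid.origin_um),
            "bin_size_um": list(grid.bin_size_um),
            "n_sections_averaged": grid.n_sections_averaged,
            "axes": "ZYX",
        },
    )


def load_grid(path: Path) -> VoxelGrid:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    counts = np.transpose(pages, (2, 1, 0))
    return VoxelGrid(
        tuple(meta["origin_um"]),
        tuple(meta["bin_size_um"]),
        counts,
        n_sections_averaged=int(meta.get("n_sections_averaged", 1)),
    )


def load_landmarks(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["section_id", "fixed_x_um", "fixed_y_um", "moving_x_um", "moving_y_um"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"landmark CSV missing columns: {missing}")
    return df
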