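"""Watershed isolation of puncta from a background-corrected channel.

Seed points are local intensity maxima above threshold, suppressed to a
minimum pairwise physical separation (the nominal bouton diameter); a
marker-based watershed on the inverted intensity landscape, restricted to
suprathreshold voxels, splits touching puncta.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.segmentation import watershed

__all__ = ["find_seed_maxima", "segment_boutons", "BOUTON_COLUMNS"]

BOUTON_COLUMNS = [
    "id",
    "x_um",
    "y_um",
    "z_um",
    "volume_voxels",
    "volume_um3",
    "peak_vgat",
    "integrated_vgat",
    "tdt_intensity",
    "tdt_matched",
    "is_pc",
    "region_id",
    "section_id",
]


def local_maxima_um(
    image: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    threshold: float | None = None,
    min_separation_um: float = 1.0,
) -> pd.DataFrame:
    """Local maxima of a (z, y, x) image with physical non-max suppression.

    A voxel is a candidate when it equals the 26-neighborhood maximum and
    strictly exceeds the neighborhood minimum (flat fields yield none).
    Candidates closer than ``min_separation_um`` (anisotropy respected)
    are suppressed in order of descending intensity; ties break on lowest
    (z, y, x) index, so the result is deterministic.
    """
    image = np.asarray(image, dtype=float)
    dx, dy, dz = voxel_size_um
    footprint = np.ones((3, 3, 3), dtype=bool)
    is_max = image == ndimage.maximum_filter(image, footprint=footprint, mode="nearest")
    not_flat = image > ndimage.minimum_filter(image, footprint=footprint, mode="nearest")
    cand = is_max & not_flat
    if threshold is not None:
        cand &= image >= threshold
    zz, yy, xx = np.nonzero(cand)
    if zz.size == 0:
        return _maxima_frame(zz, yy, xx, np.empty(0), voxel_size_um)
    vals = image[zz, yy, xx]
    order = np.lexsort((xx, yy, zz, -vals))
    zz, yy, xx, vals = zz[order], yy[order], xx[order], vals[order]
    coords = np.column_stack(
        [(xx + 0.5) * dx, (yy + 0.5) * dy, (zz + 0.5) * dz]
    )
    keep = _greedy_suppress(coords, min_separation_um)
    return _maxima_frame(zz[keep], yy[keep], xx[keep], vals[keep], voxel_size_um)


def _greedy_suppress(coords_um: np.ndarray, min_sep_um: float) -> np.ndarray:
    """Indices kept by greedy NMS; ``coords_um`` already priority-sorted."""
    n = coords_um.shape[0]
    if min_sep_um <= 0 or n == 1:
        return np.arange(n)
    tree = cKDTree(coords_um)
    pairs = tree.query_pairs(min_sep_um, output_type="ndarray")
    if pairs.size:
        d = np.linalg.norm(coords_um[pairs[:, 0]] - coords_um[pairs[:, 1]], axis=1)
        pairs = pairs[d < min_sep_um]  # separation exactly min_sep is allowed
    neighbors: dict[int, list[int]] = {}
    for a, b in pairs:
        neighbors.setdefault(int(a), []).append(int(b))
        neighbors.setdefault(int(b), []).append(int(a))
    suppressed = np.zeros(n, dtype=bool)
    keep = []
    for i in range(n):
        if suppressed[i]:
            continue
        keep.append(i)
        for j in neighbors.get(i, ()):
            suppressed[j] = True
    return np.asarray(keep, dtype=int)


def _maxima_frame(zz, yy, xx, vals, voxel_size_um) -> pd.DataFrame:
    dx, dy, dz = voxel_size_um
    return pd.DataFrame(
        {
            "iz": np.asarray(zz, dtype=int),
            "iy": np.asarray(yy, dtype=int),
            "ix": np.asarray(xx, dtype=int),
            "x_um": (np.asarray(xx) + 0.5) * dx,
            "y_um": (np.asarray(yy) + 0.5) * dy,
            "z_um": (np.asarray(zz) + 0.5) * dz,
            "intensity": np.asarray(vals, dtype=float),
        }
    )


def find_seed_maxima(
    corrected_vgat: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    threshold: float,
    min_separation_um: float = 1.0,
) -> pd.DataFrame:
    """Watershed seed points: suprathreshold local maxima ≥ 1 µm apart."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return local_maxima_um(
        corrected_vgat, voxel_size_um, threshold=threshold,
        min_separation_um=min_separation_um,
    )


def segment_boutons(
    corrected_vgat: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    seeds: pd.DataFrame,
    threshold: float,
    min_voxels: int = 2,
    section_id: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Marker-based watershed of the suprathreshold mask around seeds.

    Returns the bouton table (one row per surviving object, centroids
    intensity-weighted in µm) and the integer label volume. Objects
    smaller than ``min_voxels`` are discarded. No seeds is not an error:
    the table is simply empty.
    """
    corrected_vgat = np.asarray(corrected_vgat, dtype=float)
    dx, dy, dz = voxel_size_um
    empty = pd.DataFrame({c: pd.Series(dtype=t) for c, t in _empty_schema().items()})
    labels = np.zeros(corrected_vgat.shape, dtype=np.int32)
    if len(seeds) == 0:
        return empty, labels
    markers = np.zeros(corrected_vgat.shape, dtype=np.int32)
    markers[seeds["iz"].to_numpy(), seeds["iy"].to_numpy(), seeds["ix"].to_numpy()] = (
        np.arange(1, len(seeds) + 1)
    )
    mask = corrected_vgat >= threshold
    labels = watershed(-corrected_vgat, markers=markers, mask=mask)

    ids = np.arange(1, len(seeds) + 1)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=ids)
    survivors = ids[sizes >= min_voxels]
    if survivors.size == 0:
        return empty, np.zeros_like(labels)
    # drop undersized specks from the label volume, then renumber
    drop = ids[sizes < min_voxels]
    if drop.size:
        labels[np.isin(labels, drop)] = 0
    remap = np.zeros(int(ids.max()) + 1, dtype=np.int32)
    remap[survivors] = np.arange(1, survivors.size + 1)
    labels = remap[labels]
    new_ids = np.arange(1, survivors.size + 1)

    com = ndimage.center_of_mass(corrected_vgat, labels, index=new_ids)
    com = np.asarray(com, dtype=float)  # (n, 3) in (z, y, x) index coords
    peak = ndimage.maximum(corrected_vgat, labels, index=new_ids)
    integ = ndimage.sum_labels(corrected_vgat, labels, index=new_ids)
    nvox = ndimage.sum_labels(np.ones_like(labels), labels, index=new_ids).astype(int)
    voxel_vol = dx * dy * dz
    table = pd.DataFrame(
        {
            "id": new_ids,
            "x_um": (com[:, 2] + 0.5) * dx,
            "y_um": (com[:, 1] + 0.5) * dy,
            "z_um": (com[:, 0] + 0.5) * dz,
            "volume_voxels": nvox,
            "volume_um3": nvox * voxel_vol,
            "peak_vgat": np.asarray(peak, dtype=float),
            "integrated_vgat": np.asarray(integ, dtype=float),
            "tdt_intensity": np.nan,
            "tdt_matched": False,
            "is_pc": False,
            "region_id": 0,
            "section_id": section_id,
        }
    )
    return table, labels


def _empty_schema() -> dict:
    return {
        "id": "int64",
        "x_um": "float64",
        "y_um": "float64",
        "z_um": "float64",
        "volume_voxels": "int64",
        "volume_um3": "float64",
        "peak_vgat": "float64",
        "integrated_vgat": "float64",
        "tdt_intensity": "float64",
        "tdt_matched": "bool",
        "is_pc": "bool",
        "region_id": "int64",
        "section_id": "int64",
    }
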