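"""Voxel-grid density maps and per-region count/density/fraction summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from boutonmap.atlas import RegionMap

__all__ = ["VoxelGrid", "bin_to_grid", "average_grids", "summarize_regions"]

DEFAULT_BIN_SIZE_UM = (144.0, 144.0, 4.0)


@dataclass
class VoxelGrid:
    """Counts (or averaged counts) on a regular 3D lattice.

    ``counts`` has axes (x-bin, y-bin, z-bin). Bins are half-open
    [i·w, (i+1)·w) relative to ``origin_um``. ``density`` divides by the
    in-plane bin area, giving boutons/µm² per bin.
    """

    origin_um: tuple[float, float, float]
    bin_size_um: tuple[float, float, float]
    counts: np.ndarray
    n_sections_averaged: int = 1

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError("counts must be a 3D lattice (x, y, z bins)")
        if min(self.bin_size_um) <= 0:
            raise ValueError("bin sizes must be > 0")

    @property
    def density(self) -> np.ndarray:
        bx, by, _ = self.bin_size_um
        return self.counts / (bx * by)

    def bin_indices(self, points_um: np.ndarray) -> np.ndarray:
        """Half-open bin index per point; may lie outside the lattice."""
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        rel = pts - np.asarray(self.origin_um)[: pts.shape[1]]
        return np.floor(rel / np.asarray(self.bin_size_um)[: pts.shape[1]]).astype(int)

    def same_geometry(self, other: "VoxelGrid") -> bool:
        return (
            tuple(self.origin_um) == tuple(other.origin_um)
            and tuple(self.bin_size_um) == tuple(other.bin_size_um)
            and self.counts.shape == other.counts.shape
        )


def bin_to_grid(
    points_um: np.ndarray,
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0),
    bin_size_um: tuple[float, float, float] = DEFAULT_BIN_SIZE_UM,
    shape: tuple[int, int, int] | None = None,
) -> VoxelGrid:
    """Bin 3D points into a half-open lattice; total count is conserved.

    When ``shape`` is None it is inferred from the data extent. With an
    explicit shape, points outside the lattice raise.
    """
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    if pts.size and pts.shape[1] != 3:
        raise ValueError("points must be (n, 3) µm coordinates")
    if pts.size and not np.isfinite(pts).all():
        raise ValueError("point coordinates must be finite")
    bin_size = np.asarray(bin_size_um, dtype=float)
    origin = np.asarray(origin_um, dtype=float)
    if pts.size == 0:
        counts = np.zeros(shape if shape is not None else (1, 1, 1))
        return VoxelGrid(tuple(origin), tuple(bin_size), counts)
    idx = np.floor((pts - origin) / bin_size).astype(int)
    if shape is None:
        if (idx < 0).any():
            raise ValueError("points precede the grid origin")
        shape = tuple(idx.max(axis=0) + 1)
    else:
        if (idx < 0).any() or (idx >= np.asarray(shape)).any():
            raise ValueError("points fall outside the requested grid shape")
    counts = np.zeros(shape)
    np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    return VoxelGrid(tuple(origin), tuple(bin_size), counts)


def average_grids(grids: list[VoxelGrid]) -> VoxelGrid:
    """Per-bin mean count across sections with identical geometry."""
    if len(grids) == 0:
        raise ValueError("no grids to average")
    first = grids[0]
    for g in grids[1:]:
        if not first.same_geometry(g):
            raise ValueError("grids have mismatched origin, bin size, or shape")
    mean = np.mean([g.counts for g in grids], axis=0)
    return VoxelGrid(
        tuple(first.origin_um),
        tuple(first.bin_size_um),
        mean,
        n_sections_averaged=len(grids),
    )


def summarize_regions(
    boutons: pd.DataFrame, region_map: RegionMap
) -> pd.DataFrame:
    """Per-region counts, areal PC density, and PC fraction of all boutons.

    One row per region id present in the map plus a row for background
    (id 0) holding boutons that fell outside every region. ``pc_fraction``
    is NaN where a region has no detected boutons; density divides the PC
    count by the region's in-plane area (background area is NaN).
    """
    areas = region_map.id_to_area_um2
    region_ids = [0] + sorted(areas)
    rows = []
    for rid in region_ids:
        sub = boutons[boutons["region_id"] == rid] if len(boutons) else boutons
        n_vgat = int(len(sub))
        n_pc = int(sub["is_pc"].sum()) if n_vgat else 0
        area = areas.get(rid, np.nan)
        rows.append(
            {
                "region_id": rid,
                "region_name": region_map.id_to_name.get(rid, "background" if rid == 0 else str(rid)),
                "n_vgat": n_vgat,
                "n_pc": n_pc,
                "area_um2": area,
                "pc_density_per_um2": (n_pc / area) if np.isfinite(area) and area > 0 else np.nan,
                "pc_fraction": (n_pc / n_vgat) if n_vgat > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
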