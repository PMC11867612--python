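"""Evoked-response summaries and the bouton-density→response-probability link.

The cell table carries, per recorded cell, an atlas location, a region
label, a boolean ``responded`` flag and the evoked current amplitude
(0 pA for nonresponders). Summaries follow the convention that the
all-cell mean amplitude averages nonresponders in at 0 pA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.proportion import proportion_confint

from boutonmap.quantify import VoxelGrid

__all__ = [
    "EPHYS_COLUMNS",
    "DensityResponseCurve",
    "validate_cells",
    "region_response_stats",
    "local_density",
    "probability_vs_density",
    "compare_density_distributions",
]

logger = logging.getLogger(__name__)

EPHYS_COLUMNS = [
    "cell_id",
    "section_id",
    "x_um",
    "y_um",
    "region_id",
    "responded",
    "amplitude_pa",
]


@dataclass
class DensityResponseCurve:
    """Binned response probability vs local bouton density with Wilson CIs."""

    bin_edges: np.ndarray
    n_cells: np.ndarray
    n_responding: np.ndarray
    probability: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def to_dict(self) -> dict:
        return {
            "bin_edges": [float(e) for e in self.bin_edges],
            "n_cells": [int(n) for n in self.n_cells],
            "n_responding": [int(n) for n in self.n_responding],
            "probability": [float(p) for p in self.probability],
            "ci_low": [float(c) for c in self.ci_low],
            "ci_high": [float(c) for c in self.ci_high],
        }


def validate_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Schema check for the cell table; raises naming offending columns."""
    if len(cells) == 0:
        raise ValueError("empty cell table")
    missing = [c for c in EPHYS_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    amp = cells["amplitude_pa"].to_numpy(dtype=float)
    if not np.isfinite(amp).all() or (amp < 0).any():
        raise ValueError("column 'amplitude_pa' must be finite and >= 0")
    responded = cells["responded"].astype(bool).to_numpy()
    if (amp[~responded] != 0).any():
        raise ValueError("column 'amplitude_pa' must be 0 where 'responded' is false")
    return cells


def region_response_stats(cells: pd.DataFrame, by="region_id") -> pd.DataFrame:
    """Per-group response counts, fraction, and mean amplitudes.

    ``mean_amplitude_all_pa`` averages over every cell with nonresponders
    contributing 0 pA; ``mean_amplitude_responders_pa`` is NaN for groups
    with no responders. Passing ``by=None`` pools everything into one row.
    """
    if len(cells) == 0:
        raise ValueError("empty cell table")
    df = cells.copy()
    df["responded"] = df["responded"].astype(bool)
    if by is None:
        groups = [("all", df)]
    else:
        groups = list(df.groupby(by, sort=True))
    rows = []
    for key, sub in groups:
        n = len(sub)
        n_resp = int(sub["responded"].sum())
        amp = sub["amplitude_pa"].to_numpy(dtype=float)
        rows.append(
            {
                "group": key,
                "n": n,
                "n_responding": n_resp,
                "fraction_responding": n_resp / n,
                "mean_amplitude_all_pa": float(amp.mean()),
                "mean_amplitude_responders_pa": (
                    float(amp[sub["responded"].to_numpy()].mean()) if n_resp else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def local_density(cells: pd.DataFrame, grid: VoxelGrid) -> np.ndarray:
    """Density of the grid voxel containing each cell (NaN outside grid).

    Cells use in-plane coordinates; the single z-bin convention of a thin
    section is handled by clamping z to the grid's z origin.
    """
    pts = np.column_stack(
        [
            cells["x_um"].to_numpy(dtype=float),
            cells["y_um"].to_numpy(dtype=float),
            np.full(len(cells), grid.origin_um[2]),
        ]
    )
    idx = grid.bin_indices(pts)
    shape = np.asarray(grid.counts.shape)
    inside = ((idx >= 0) & (idx < shape)).all(axis=1)
    out = np.full(len(cells), np.nan)
    dens = grid.density
    out[inside] = dens[idx[inside, 0], idx[inside, 1], idx[inside, 2]]
    n_out = int((~inside).sum())
    if n_out:
        logger.info("%d cells outside the density grid were excluded", n_out)
    return out


def probability_vs_density(
    cells: pd.DataFrame,
    densities: np.ndarray,
    bin_edges: np.ndarray | None = None,
    n_bins: int = 5,
) -> DensityResponseCurve:
    """Binned responding fraction vs density with Wilson 95% intervals.

    Bins are half-open [e_i, e_{i+1}); by default the edges are quantiles
    of the pooled density distribution (the top edge is widened slightly
    so the maximum falls in the last bin). Empty bins are dropped.
    """
    densities = np.asarray(densities, dtype=float)
    responded = cells["responded"].astype(bool).to_numpy()
    ok = np.isfinite(densities)
    if not ok.all():
        logger.info("%d cells without a density value were dropped", int((~ok).sum()))
    densities, responded = densities[ok], responded[ok]
    if densities.size == 0:
        raise ValueError("no cells with a finite density value")
    if bin_edges is None:
        qs = np.linspace(0, 1, n_bins + 1)
        bin_edges = np.quantile(densities, qs)
        bin_edges = np.unique(bin_edges)
        eps = 1e-9 * max(1.0, abs(bin_edges[-1]))
        if bin_edges.size == 1:  # all densities identical -> one degenerate bin
            bin_edges = np.array([bin_edges[0], bin_edges[0] + eps])
        else:
            bin_edges[-1] = bin_edges[-1] + eps
    bin_edges = np.asarray(bin_edges, dtype=float)
    which = np.digitize(densities, bin_edges) - 1  # [e_i, e_{i+1}) -> i
    n_cells, n_resp, keep_edges_lo, keep_edges_hi = [], [], [], []
    for b in range(len(bin_edges) - 1):
        sel = which == b
        if not sel.any():
            logger.info("density bin %d is empty and was dropped", b)
            continue
        n_cells.append(int(sel.sum()))
        n_resp.append(int(responded[sel].sum()))
        keep_edges_lo.append(bin_edges[b])
        keep_edges_hi.append(bin_edges[b + 1])
    if not n_cells:
        raise ValueError("no non-empty density bins")
    n_cells = np.asarray(n_cells)
    n_resp = np.asarray(n_resp)
    lo, hi = proportion_confint(n_resp, n_cells, alpha=0.05, method="wilson")
    edges = np.append(np.asarray(keep_edges_lo), keep_edges_hi[-1])
    return DensityResponseCurve(
        bin_edges=edges,
        n_cells=n_cells,
        n_responding=n_resp,
        probability=n_resp / n_cells,
        ci_low=np.asarray(lo, dtype=float),
        ci_high=np.asarray(hi, dtype=float),
    )


def compare_density_distributions(
    densities_responding: np.ndarray,
    densities_nonresponding: np.ndarray,
    method: str = "normal",
    n_permutations: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Mann–Whitney U (responding group) with a two-sided p value.

    ``method="normal"`` uses the tie-corrected normal approximation; all
    observations tied yields p = 1. ``method="permutation"`` estimates the
    p value by label permutation of the same U statistic.
    """
    x = np.asarray(densities_responding, dtype=float)
    y = np.asarray(densities_nonresponding, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    u1 = _u_statistic(x, y)
    n1, n2 = x.size, y.size
    if method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([x, y])
        mu = n1 * n2 / 2.0
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            u = _u_statistic(perm[:n1], perm[n1:])
            if abs(u - mu) >= abs(u1 - mu) - 1e-12:
                hits += 1
        return float(u1), (hits + 1) / (n_permutations + 1)
    if method != "normal":
        raise ValueError(f"unknown method {method!r}")
    n = n1 + n2
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return float(u1), 1.0
    z = (u1 - n1 * n2 / 2.0) / np.sqrt(var)
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return float(u1), p


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    ranks = rankdata(np.concatenate([x, y]))
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)
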