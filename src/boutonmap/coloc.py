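"""Reporter-channel colocalization and bimodal valley classification.

Each detected punctum is assigned a reporter (tdTomato) intensity from
the nearest regional maximum within a center-to-center radius; pooled
per-punctum intensities form a bimodal histogram (noise vs signal) whose
KDE valley separates reporter-positive from reporter-negative puncta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde
from skimage.filters import threshold_otsu

from boutonmap.detect import local_maxima_um

__all__ = [
    "BimodalThresholdReport",
    "detect_tdt_maxima",
    "assign_tdt_intensity",
    "find_bimodal_threshold",
    "classify_pc",
]

logger = logging.getLogger(__name__)


@dataclass
class BimodalThresholdReport:
    """Valley threshold between the noise and signal intensity modes."""

    values_n: int
    mode_locations: tuple[float, float] | None
    valley: float
    bimodality_ok: bool
    fallback_used: bool = False

    def to_dict(self) -> dict:
        return {
            "values_n": int(self.values_n),
            "mode_locations": (
                None
                if self.mode_locations is None
                else [float(m) for m in self.mode_locations]
            ),
            "valley": float(self.valley),
            "bimodality_ok": bool(self.bimodality_ok),
            "fallback_used": bool(self.fallback_used),
        }


def detect_tdt_maxima(
    corrected_tdt: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    min_separation_um: float = 0.5,
    smooth_sigma_um: float = 0.25,
) -> pd.DataFrame:
    """All regional maxima of the lightly smoothed reporter channel.

    No intensity threshold is applied — classification happens downstream
    at the histogram valley. Constant (zero-gradient) fields yield no
    maxima.
    """
    corrected_tdt = np.asarray(corrected_tdt, dtype=float)
    dx, dy, dz = voxel_size_um
    if smooth_sigma_um > 0:
        smoothed = ndimage.gaussian_filter(
            corrected_tdt,
            sigma=(smooth_sigma_um / dz, smooth_sigma_um / dy, smooth_sigma_um / dx),
            mode="nearest",
        )
    else:
        smoothed = corrected_tdt
    return local_maxima_um(
        smoothed, voxel_size_um, threshold=None, min_separation_um=min_separation_um
    )


def assign_tdt_intensity(
    boutons: pd.DataFrame,
    maxima: pd.DataFrame,
    corrected_tdt: np.ndarray,
    labels: np.ndarray,
    max_center_distance_um: float = 0.7,
) -> pd.DataFrame:
    """Fill ``tdt_intensity`` and ``tdt_matched`` for each bouton.

    The nearest reporter maximum within ``max_center_distance_um`` of the
    bouton centroid (3D physical distance, inclusive boundary) supplies
    the intensity; unmatched boutons fall back to the maximum corrected
    reporter value inside their own voxel mask.
    """
    out = boutons.copy()
    if len(out) == 0:
        return out
    centroids = out[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    matched = np.zeros(len(out), dtype=bool)
    intensity = np.full(len(out), np.nan)
    if len(maxima) > 0:
        tree = cKDTree(maxima[["x_um", "y_um", "z_um"]].to_numpy(dtype=float))
        dist, idx = tree.query(centroids, k=1)
        # inclusive radius; epsilon absorbs float round-off at the boundary
        matched = dist <= max_center_distance_um + 1e-9
        intensity[matched] = maxima["intensity"].to_numpy(dtype=float)[idx[matched]]
    if (~matched).any():
        ids = out["id"].to_numpy()[~matched]
        mask_max = ndimage.maximum(np.asarray(corrected_tdt, dtype=float), labels, index=ids)
        intensity[~matched] = np.asarray(mask_max, dtype=float)
    out["tdt_intensity"] = intensity
    out["tdt_matched"] = matched
    return out


def find_bimodal_threshold(
    values: np.ndarray,
    min_values: int = 50,
    grid_points: int = 512,
) -> BimodalThresholdReport:
    """Valley of the KDE (Silverman bandwidth) between the two main modes.

    With fewer than two KDE modes the threshold falls back to Otsu's
    method on the raw values and the report flags ``fallback_used``.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < min_values:
        raise ValueError(
            f"need >= {min_values} intensity values for a bimodal threshold "
            f"(got {values.size}); pool boutons across sections"
        )
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return BimodalThresholdReport(values.size, None, lo, False, True)
    kde = gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(lo, hi, grid_points)
    dens = kde(grid)
    interior = np.arange(1, grid_points - 1)
    is_peak = (dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])
    peaks = interior[is_peak]
    if peaks.size >= 2:
        top2 = peaks[np.argsort(dens[peaks])[-2:]]
        left, right = int(top2.min()), int(top2.max())
        valley_idx = left + int(np.argmin(dens[left : right + 1]))
        modes = (float(grid[left]), float(grid[right]))
        return BimodalThresholdReport(values.size, modes, float(grid[valley_idx]), True)
    logger.warning(
        "intensity histogram not bimodal (%d KDE modes); falling back to Otsu",
        peaks.size,
    )
    return BimodalThresholdReport(
        values.size, None, float(threshold_otsu(values)), False, True
    )


def classify_pc(boutons: pd.DataFrame, report: BimodalThresholdReport) -> pd.DataFrame:
    """Set ``is_pc`` = matched within radius AND intensity strictly above valley."""
    out = boutons.copy()
    out["is_pc"] = out["tdt_matched"].to_numpy(dtype=bool) & (
        out["tdt_intensity"].to_numpy(dtype=float) > report.valley
    )
    return out
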