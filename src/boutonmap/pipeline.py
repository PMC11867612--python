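"""End-to-end orchestration of the anatomy and ephys analyses."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from boutonmap import atlas, coloc, detect, ephys, io, preprocess, quantify
from boutonmap.atlas import RegionMap, Transform2D
from boutonmap.config import PipelineParams
from boutonmap.preprocess import ImageStack

__all__ = ["AnatomyResult", "analyze_stack", "run_anatomy", "run_ephys"]

logger = logging.getLogger(__name__)


@dataclass
class AnatomyResult:
    boutons: pd.DataFrame
    region_summary: pd.DataFrame
    grid: quantify.VoxelGrid
    threshold_report: preprocess.ThresholdReport
    bimodal_report: coloc.BimodalThresholdReport
    qc: atlas.RegistrationQC | None
    stage_counts: dict


def analyze_stack(
    stack: ImageStack,
    region_map: RegionMap,
    params: PipelineParams,
    transform: Transform2D | None = None,
    rois: list | None = None,
    section_id: int = 0,
) -> AnatomyResult:
    """Run the full single-section anatomy analysis in memory.

    Stages: background-correct both channels, estimate the detection
    threshold from ROIs, watershed-isolate puncta, colocalize with the
    reporter channel, classify reporter-positive puncta at the bimodal
    valley, assign atlas regions, and summarize counts/densities and the
    coarse density grid.
    """
    params.validate()
    if stack.n_channels < 2:
        raise ValueError("stack must contain the label and reporter channels")
    vs = stack.voxel_size_um

    corrected = []
    for ci in range(2):
        ch = np.asarray(stack.voxels[ci], dtype=float)
        bg = preprocess.estimate_background(ch, vs, params.background_diameter_um)
        corrected.append(preprocess.subtract_background(ch, bg))
    corr_vgat, corr_tdt = corrected

    threshold_report = preprocess.compute_intensity_threshold(
        corr_vgat, vs, rois=rois, k=params.threshold_k, roi_side_px=params.roi_side_px
    )
    seeds = detect.find_seed_maxima(
        corr_vgat, vs, threshold_report.threshold,
        min_separation_um=params.bouton_diameter_um,
    )
    boutons, labels = detect.segment_boutons(
        corr_vgat, vs, seeds, threshold_report.threshold,
        min_voxels=params.min_bouton_voxels, section_id=section_id,
    )

    maxima = coloc.detect_tdt_maxima(
        corr_tdt, vs,
        min_separation_um=params.tdt_min_separation_um,
        smooth_sigma_um=params.tdt_smooth_sigma_um,
    )
    boutons = coloc.assign_tdt_intensity(
        boutons, maxima, corr_tdt, labels, max_center_distance_um=params.match_radius_um
    )
    bimodal = coloc.find_bimodal_threshold(boutons["tdt_intensity"].to_numpy())
    boutons = coloc.classify_pc(boutons, bimodal)

    if len(boutons):
        boutons["region_id"] = atlas.assign_regions(
            boutons[["x_um", "y_um"]].to_numpy(), region_map, transform
        )

    region_summary = quantify.summarize_regions(boutons, region_map)

    (x0, x1), (y0, y1) = region_map.bounds_um()
    bx, by, bz = params.bin_size_um
    shape = (
        int(np.ceil((x1 - x0) / bx)),
        int(np.ceil((y1 - y0) / by)),
        max(1, int(np.ceil(params.stack_depth_um / bz))),
    )
    pc = boutons[boutons["is_pc"]] if len(boutons) else boutons
    grid = quantify.bin_to_grid(
        pc[["x_um", "y_um", "z_um"]].to_numpy() if len(pc) else np.empty((0, 3)),
        origin_um=(x0, y0, 0.0),
        bin_size_um=params.bin_size_um,
        shape=shape,
    )

    qc = None
    if transform is not None:
        qc = atlas.displacement_qc(
            transform, region_map.bounds_um(), params.qc_grid_spacing_um
        )

    stage_counts = {
        "seeds": int(len(seeds)),
        "boutons": int(len(boutons)),
        "tdt_maxima": int(len(maxima)),
        "matched": int(boutons["tdt_matched"].sum()) if len(boutons) else 0,
        "pc": int(boutons["is_pc"].sum()) if len(boutons) else 0,
    }
    logger.info("anatomy stage counts: %s", stage_counts)
    return AnatomyResult(
        boutons=boutons,
        region_summary=region_summary,
        grid=grid,
        threshold_report=threshold_report,
        bimodal_report=bimodal,
        qc=qc,
        stage_counts=stage_counts,
    )


def run_anatomy(
    stack_path: Path,
    region_map_path: Path,
    out_dir: Path,
    params: PipelineParams,
    landmarks_path: Path | None = None,
) -> AnatomyResult:
    """File-based anatomy run: read inputs, analyze, write all outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stack_path, region_map_path = Path(stack_path), Path(region_map_path)
    for p in [stack_path, region_map_path] + ([Path(landmarks_path)] if landmarks_path else []):
        if not p.exists():
            raise FileNotFoundError(f"input file not found: {p}")

    stack = io.load_stack(stack_path)
    region_map = io.load_region_map(region_map_path)

    transform = None
    if landmarks_path is not None:
        lm = io.load_landmarks(landmarks_path)
        transform = atlas.fit_transform(
            lm[["fixed_x_um", "fixed_y_um"]].to_numpy(),
            lm[["moving_x_um", "moving_y_um"]].to_numpy(),
            model=params.transform_model,
        )

    result = analyze_stack(stack, region_map, params, transform=transform)

    result.boutons.to_csv(out_dir / "boutons.csv", index=False)
    result.region_summary.to_csv(out_dir / "region_summary.csv", index=False)
    io.save_grid(out_dir / "pc_density_grid.tif", result.grid)
    io.write_json(out_dir / "threshold_report.json", result.threshold_report.to_dict())
    io.write_json(out_dir / "bimodal_report.json", result.bimodal_report.to_dict())
    if result.qc is not None:
        io.write_json(out_dir / "registration_qc.json", result.qc.to_dict())

    provenance = {
        "params": params.to_dict(),
        "inputs": {
            "stack": io.sha256_of(stack_path),
            "region_map": io.sha256_of(region_map_path),
            "landmarks": io.sha256_of(landmarks_path) if landmarks_path else None,
        },
        "stage_counts": result.stage_counts,
    }
    io.write_json(out_dir / "run_log.json", provenance)
    return result


def run_ephys(
    cells_path: Path,
    grid_path: Path,
    out_dir: Path,
    params: PipelineParams,
) -> dict:
    """File-based ephys run: region stats, density curve, group comparison."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cells_path, grid_path = Path(cells_path), Path(grid_path)
    for p in (cells_path, grid_path):
        if not p.exists():
            raise FileNotFoundError(f"input file not found: {p}")

    cells = ephys.validate_cells(pd.read_csv(cells_path))
    grid = io.load_grid(grid_path)

    stats = ephys.region_response_stats(cells, by="region_id")
    stats.to_csv(out_dir / "region_response_stats.csv", index=False)

    dens = ephys.local_density(cells, grid)
    curve = ephys.probability_vs_density(cells, dens, n_bins=params.density_bins)

    responded = cells["responded"].astype(bool).to_numpy()
    ok = np.isfinite(dens)
    comparison = None
    if (responded & ok).any() and (~responded & ok).any():
        u, p = ephys.compare_density_distributions(
            dens[responded & ok], dens[~responded & ok],
            method=params.rank_test, seed=params.seed,
        )
        comparison = {"test": f"mann-whitney-{params.rank_test}", "U": u, "p_two_sided": p}

    out = {"curve": curve.to_dict(), "comparison": comparison}
    io.write_json(out_dir / "density_response_curve.json", out)
    provenance = {
        "params": params.to_dict(),
        "inputs": {"cells": io.sha256_of(cells_path), "grid": io.sha256_of(grid_path)},
        "n_cells": int(len(cells)),
    }
    io.write_json(out_dir / "run_log.json", provenance)
    return out
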