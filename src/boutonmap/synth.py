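"""Seeded synthetic scenes with known ground truth.

Generates two-channel image stacks (channel 0: all-bouton label, channel
1: reporter) whose statistical structure matches what the analysis
assumes: region-dependent punctum densities, a region-dependent
reporter-positive fraction, bimodal per-punctum reporter intensities,
smooth illumination, dim axon clutter, and Poisson+Gaussian camera
noise. Also generates ephys cell tables linked to a density field by a
logistic model, and noisy landmark pairs for registration tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from boutonmap.atlas import RegionMap, Transform2D
from boutonmap.preprocess import ImageStack
from boutonmap.quantify import VoxelGrid

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "EphysLinkParams",
    "default_scene_config",
    "generate_region_map",
    "render_scene",
    "generate_ephys_cells",
    "perturb_landmarks",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
MAX_EXPECTED_BOUTONS = 1_000_000


@dataclass
class SceneConfig:
    """Parameters of a synthetic two-channel scene.

    ``region_layout`` lists (region_id, (x0, y0, width, height)) axis-
    aligned rectangles in µm. Intensity distributions are log-normal,
    given as (mean, sd) of the underlying normal (a.u.).
    """

    shape_voxels: tuple[int, int, int] = (512, 512, 5)  # (nx, ny, nz)
    voxel_size_um: tuple[float, float, float] = (0.3611, 0.3611, 0.3)
    region_layout: list = field(default_factory=list)
    vgat_density_per_region: dict = field(default_factory=dict)  # boutons/µm²
    pc_fraction_per_region: dict = field(default_factory=dict)
    bouton_fwhm_um: float = 1.0
    vgat_intensity_dist: tuple[float, float] = (math.log(300.0), 0.3)
    tdt_signal_dist: tuple[float, float] = (math.log(100.0), 0.25)
    tdt_noise_dist: tuple[float, float] = (math.log(10.0), 0.25)
    illumination_amplitude: float = 10.0
    illumination_scale_um: float = 30.0
    axon_clutter_density: float = 5e-4  # segments / µm²
    noise: tuple[float, float] = (0.5, 1.0)  # (poisson_gain, read_sd a.u.)
    seed: int = 0

    def validate(self) -> None:
        if min(self.shape_voxels) <= 0:
            raise ValueError("shape_voxels must be positive")
        if min(self.voxel_size_um) <= 0:
            raise ValueError("voxel sizes must be > 0")
        if self.bouton_fwhm_um <= 0:
            raise ValueError("bouton_fwhm_um must be > 0")
        for rid, d in self.vgat_density_per_region.items():
            if not np.isfinite(d) or d < 0:
                raise ValueError(f"vgat density for region {rid} must be finite, >= 0")
        for rid, f in self.pc_fraction_per_region.items():
            if not np.isfinite(f) or not (0.0 <= f <= 1.0):
                raise ValueError(f"pc fraction for region {rid} must lie in [0, 1]")
        if not math.exp(self.tdt_signal_dist[0]) > math.exp(self.tdt_noise_dist[0]):
            raise ValueError("tdt signal mode median must exceed the noise mode median")
        if self.noise[0] <= 0 or self.noise[1] < 0:
            raise ValueError("noise must be (poisson_gain > 0, read_sd >= 0)")

    def extent_um(self) -> tuple[float, float, float]:
        nx, ny, nz = self.shape_voxels
        dx, dy, dz = self.voxel_size_um
        return nx * dx, ny * dy, nz * dz


@dataclass
class GroundTruth:
    """True boutons of a rendered scene; the oracle for recovery tests.

    ``boutons`` columns: x_um, y_um, z_um, region_id, is_pc, vgat_amp,
    tdt_amp.
    """

    boutons: pd.DataFrame

    @property
    def per_region_counts(self) -> pd.DataFrame:
        if len(self.boutons) == 0:
            return pd.DataFrame(columns=["region_id", "n_vgat", "n_pc"]).astype(int)
        grouped = self.boutons.groupby("region_id", sort=True)
        out = grouped.agg(n_vgat=("is_pc", "size"), n_pc=("is_pc", "sum"))
        return out.reset_index().astype({"n_vgat": int, "n_pc": int})

    def to_summary_dict(self) -> dict:
        return {
            str(int(row.region_id)): {"n_vgat": int(row.n_vgat), "n_pc": int(row.n_pc)}
            for row in self.per_region_counts.itertuples()
        }


@dataclass
class EphysLinkParams:
    """Logistic link from local bouton density to response probability."""

    beta0: float = -2.0
    beta1: float = 400.0  # per (boutons/µm²)
    amplitude_dist: tuple[float, float] = (math.log(500.0), 1.0)  # log-normal, pA
    n_cells: int = 300
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be > 0")
        if not np.isfinite([self.beta0, self.beta1]).all():
            raise ValueError("logit coefficients must be finite")


def default_scene_config(seed: int = 0) -> SceneConfig:
    """Three-region default scene: dense / medium / sparse vertical strips."""
    cfg = SceneConfig(seed=seed)
    width, height, _ = cfg.extent_um()
    w3 = width / 3.0
    cfg.region_layout = [
        (1, (0.0, 0.0, w3, height)),
        (2, (w3, 0.0, w3, height)),
        (3, (2 * w3, 0.0, width - 2 * w3, height)),
    ]
    cfg.vgat_density_per_region = {1: 0.02, 2: 0.01, 3: 0.002}
    cfg.pc_fraction_per_region = {1: 0.7, 2: 0.25, 3: 0.05}
    return cfg


def generate_region_map(
    layout: list,
    shape: tuple[int, int],
    voxel_size_um: tuple[float, float],
    id_to_name: dict[int, str] | None = None,
) -> RegionMap:
    """Rasterize rectangle regions (µm) onto a 2D label map.

    A pixel belongs to a rectangle when its center lies inside the
    half-open box [x0, x0+w) × [y0, y0+h). Uncovered pixels are 0.
    Overlapping rectangles are an error naming both region ids.
    """
    nx, ny = shape
    dx, dy = voxel_size_um[0], voxel_size_um[1]
    labels = np.zeros((ny, nx), dtype=np.uint16)
    width_um, height_um = nx * dx, ny * dy
    seen: set[int] = set()
    cx = (np.arange(nx) + 0.5) * dx
    cy = (np.arange(ny) + 0.5) * dy
    for rid, rect in layout:
        rid = int(rid)
        if rid <= 0:
            raise ValueError(f"region ids must be > 0 (got {rid})")
        if rid in seen:
            raise ValueError(f"duplicate region id {rid}")
        seen.add(rid)
        x0, y0, w, h = (float(v) for v in rect)
        if x0 < 0 or y0 < 0 or x0 + w > width_um + 1e-9 or y0 + h > height_um + 1e-9:
            raise ValueError(f"region {rid} rectangle exceeds image bounds")
        in_x = (cx >= x0) & (cx < x0 + w)
        in_y = (cy >= y0) & (cy < y0 + h)
        block = np.outer(in_y, in_x)
        clash = block & (labels != 0)
        if clash.any():
            other = int(labels[clash][0])
            raise ValueError(f"regions {other} and {rid} overlap")
        labels[block] = rid
    names = dict(id_to_name) if id_to_name else {int(r): f"region_{int(r)}" for r, _ in layout}
    return RegionMap(labels, (dx, dy), names)


def render_scene(config: SceneConfig) -> tuple[ImageStack, GroundTruth]:
    """Render a two-channel stack with known bouton ground truth.

    Channel 0 holds an illumination field plus anisotropic Gaussian spots
    (FWHM ``bouton_fwhm_um`` in physical µm) at Poisson-sampled locations
    per region; channel 1 holds bright reporter spots at reporter-positive
    boutons, dim noise-level spots at the rest, and faint axon clutter.
    Camera noise is Poisson (scaled by gain) plus Gaussian read noise.
    Identical config and seed give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    nx, ny, nz = config.shape_voxels
    dx, dy, dz = config.voxel_size_um
    width, height, depth = config.extent_um()

    areas = {
        int(rid): float(rect[2]) * float(rect[3]) for rid, rect in config.region_layout
    }
    expected = sum(
        areas[rid] * config.vgat_density_per_region.get(rid, 0.0) for rid in areas
    )
    if expected > MAX_EXPECTED_BOUTONS:
        raise ValueError(
            f"expected bouton count {expected:.0f} exceeds the desk-scale "
            f"guard of {MAX_EXPECTED_BOUTONS}"
        )

    rows = []
    for rid, rect in config.region_layout:
        rid = int(rid)
        density = config.vgat_density_per_region.get(rid, 0.0)
        frac = config.pc_fraction_per_region.get(rid, 0.0)
        n = rng.poisson(areas[rid] * density)
        x0, y0, w, h = (float(v) for v in rect)
        xs = x0 + rng.uniform(0, w, size=n)
        ys = y0 + rng.uniform(0, h, size=n)
        zs = rng.uniform(0, depth, size=n)
        is_pc = rng.random(n) < frac
        mu_v, sd_v = config.vgat_intensity_dist
        vamps = rng.lognormal(mu_v, sd_v, size=n)
        mu_s, sd_s = config.tdt_signal_dist
        mu_n, sd_n = config.tdt_noise_dist
        tamps = np.where(
            is_pc,
            rng.lognormal(mu_s, sd_s, size=n),
            rng.lognormal(mu_n, sd_n, size=n),
        )
        for i in range(n):
            rows.append((xs[i], ys[i], zs[i], rid, bool(is_pc[i]), vamps[i], tamps[i]))
    truth = GroundTruth(
        pd.DataFrame(
            rows,
            columns=["x_um", "y_um", "z_um", "region_id", "is_pc", "vgat_amp", "tdt_amp"],
        )
    )

    sigma_xy = config.bouton_fwhm_um * _FWHM_TO_SIGMA
    sigma_z = sigma_xy  # isotropic in physical space; lattice is anisotropic

    vgat = _illumination_field(rng, config)
    tdt = _illumination_field(rng, config)
    if len(truth.boutons):
        pts = truth.boutons[["x_um", "y_um", "z_um"]].to_numpy()
        _add_spots(vgat, pts, truth.boutons["vgat_amp"].to_numpy(),
                   (sigma_xy, sigma_xy, sigma_z), config.voxel_size_um)
        _add_spots(tdt, pts, truth.boutons["tdt_amp"].to_numpy(),
                   (sigma_xy, sigma_xy, sigma_z), config.voxel_size_um)
    _add_axon_clutter(tdt, rng, config)

    gain, read_sd = config.noise
    vgat = _camera_noise(vgat, rng, gain, read_sd)
    tdt = _camera_noise(tdt, rng, gain, read_sd)
    stack = ImageStack(
        np.stack([vgat, tdt]).astype(np.float32),
        config.voxel_size_um,
        channel_names=("vgat", "tdt"),
    )
    return stack, truth


def _illumination_field(rng: np.random.Generator, config: SceneConfig) -> np.ndarray:
    """Smooth nonuniform illumination, constant across z, mean ≈ amplitude."""
    nx, ny, nz = config.shape_voxels
    dx, dy, _ = config.voxel_size_um
    amp = config.illumination_amplitude
    if amp <= 0:
        return np.zeros((nz, ny, nx))
    noise = rng.standard_normal((ny, nx))
    sigma_px = (config.illumination_scale_um / dy, config.illumination_scale_um / dx)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_px, mode="wrap")
    sd = smooth.std()
    if sd > 0:
        smooth = (smooth - smooth.mean()) / sd
    plane = np.clip(amp * (1.0 + 0.25 * smooth), 0.0, None)
    return np.broadcast_to(plane, (nz, ny, nx)).copy()


def _add_spots(
    volume: np.ndarray,
    positions_um: np.ndarray,
    amplitudes: np.ndarray,
    sigma_um: tuple[float, float, float],
    voxel_size_um: tuple[float, float, float],
    trunc_sigmas: float = 4.0,
) -> None:
    """Accumulate Gaussian spots (peak = amplitude) sampled at voxel centers."""
    nz, ny, nx = volume.shape
    dx, dy, dz = voxel_size_um
    sx, sy, sz = sigma_um
    rx = max(1, int(math.ceil(trunc_sigmas * sx / dx)))
    ry = max(1, int(math.ceil(trunc_sigmas * sy / dy)))
    rz = max(1, int(math.ceil(trunc_sigmas * sz / dz)))
    for (x, y, z), a in zip(np.atleast_2d(positions_um), np.atleast_1d(amplitudes)):
        cx, cy, cz = int(x / dx), int(y / dy), int(z / dz)
        x0, x1 = max(0, cx - rx), min(nx, cx + rx + 1)
        y0, y1 = max(0, cy - ry), min(ny, cy + ry + 1)
        z0, z1 = max(0, cz - rz), min(nz, cz + rz + 1)
        if x0 >= x1 or y0 >= y1 or z0 >= z1:
            continue
        gx = np.exp(-((np.arange(x0, x1) + 0.5) * dx - x) ** 2 / (2 * sx**2))
        gy = np.exp(-((np.arange(y0, y1) + 0.5) * dy - y) ** 2 / (2 * sy**2))
        gz = np.exp(-((np.arange(z0, z1) + 0.5) * dz - z) ** 2 / (2 * sz**2))
        volume[z0:z1, y0:y1, x0:x1] += a * (
            gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        )


def _add_axon_clutter(
    volume: np.ndarray, rng: np.random.Generator, config: SceneConfig
) -> None:
    """Dim reporter-channel fibers: short faint lines of sub-resolution spots."""
    if config.axon_clutter_density <= 0:
        return
    width, height, depth = config.extent_um()
    n_seg = rng.poisson(config.axon_clutter_density * width * height)
    mu_n, sd_n = config.tdt_noise_dist
    seg_len = 8.0  # µm
    sigma = (0.3, 0.3, 0.3)
    for _ in range(n_seg):
        x0, y0 = rng.uniform(0, width), rng.uniform(0, height)
        z = rng.uniform(0, depth)
        theta = rng.uniform(0, 2 * math.pi)
        amp = 0.5 * rng.lognormal(mu_n, sd_n)
        t = np.linspace(0, seg_len, 16)
        pts = np.column_stack(
            [x0 + t * math.cos(theta), y0 + t * math.sin(theta), np.full_like(t, z)]
        )
        inside = (
            (pts[:, 0] >= 0) & (pts[:, 0] < width)
            & (pts[:, 1] >= 0) & (pts[:, 1] < height)
        )
        if inside.any():
            _add_spots(volume, pts[inside], np.full(inside.sum(), amp),
                       sigma, config.voxel_size_um)


def _camera_noise(
    image: np.ndarray, rng: np.random.Generator, gain: float, read_sd: float
) -> np.ndarray:
    shot = rng.poisson(np.clip(image, 0, None) / gain).astype(float) * gain
    return shot + rng.normal(0.0, read_sd, size=image.shape)


def generate_ephys_cells(
    density_field: VoxelGrid,
    params: EphysLinkParams,
    region_map: RegionMap | None = None,
    section_id: int = 0,
) -> pd.DataFrame:
    """Simulate recorded cells linked to local bouton density.

    Cells are placed uniformly over the grid footprint; each responds with
    probability logistic(beta0 + beta1 · local density) and responders
    draw a log-normal amplitude (nonresponders are exactly 0 pA).
    """
    params.validate()
    if (density_field.counts < 0).any():
        raise ValueError("density field must be non-negative")
    rng = np.random.default_rng(params.seed)
    ox, oy, oz = density_field.origin_um
    sx, sy, _ = density_field.counts.shape
    bx, by, _ = density_field.bin_size_um
    xs = ox + rng.uniform(0, sx * bx, size=params.n_cells)
    ys = oy + rng.uniform(0, sy * by, size=params.n_cells)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(params.n_cells),
            "section_id": section_id,
            "x_um": xs,
            "y_um": ys,
            "region_id": 0,
            "responded": False,
            "amplitude_pa": 0.0,
        }
    )
    if region_map is not None:
        from boutonmap.atlas import assign_regions

        cells["region_id"] = assign_regions(
            cells[["x_um", "y_um"]].to_numpy(), region_map
        )
    from boutonmap.ephys import local_density

    dens = local_density(cells, density_field)
    dens = np.nan_to_num(dens, nan=0.0)
    p = expit(params.beta0 + params.beta1 * dens)
    responded = rng.random(params.n_cells) < p
    mu_a, sd_a = params.amplitude_dist
    amps = np.where(responded, rng.lognormal(mu_a, sd_a, size=params.n_cells), 0.0)
    cells["responded"] = responded
    cells["amplitude_pa"] = amps
    return cells


def perturb_landmarks(
    true_transform: Transform2D,
    n_pairs: int,
    noise_sd_um: float,
    seed: int = 0,
    bounds_um: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 2000.0), (0.0, 2000.0)),
) -> tuple[np.ndarray, np.ndarray]:
    """Random fixed (atlas) points and noisy moving (section) counterparts.

    ``moving = T⁻¹(fixed) + N(0, noise_sd)``, so fitting moving → fixed
    should recover ``true_transform``.
    """
    if n_pairs < 3:
        raise ValueError("n_pairs must be >= 3")
    rng = np.random.default_rng(seed)
    (x0, x1), (y0, y1) = bounds_um
    fixed = np.column_stack(
        [rng.uniform(x0, x1, size=n_pairs), rng.uniform(y0, y1, size=n_pairs)]
    )
    moving = true_transform.inverse().apply(fixed)
    if noise_sd_um > 0:
        moving = moving + rng.normal(0.0, noise_sd_um, size=moving.shape)
    return fixed, moving
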