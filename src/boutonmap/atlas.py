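"""Landmark-based 2D section-to-atlas registration and region assignment.

Registration is in-plane per section: a similarity (default) or affine
transform is estimated by least squares from landmark pairs, alignment
quality is summarized by the displacement of a regular reference grid,
and detected points are assigned region labels by lookup in a 2D label
map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import AffineTransform, SimilarityTransform

__all__ = [
    "Transform2D",
    "RegistrationQC",
    "RegionMap",
    "fit_transform",
    "displacement_qc",
    "assign_regions",
]


@dataclass
class Transform2D:
    """In-plane linear map ``q = A p + t`` acting on µm coordinates."""

    matrix: np.ndarray  # (2, 2)
    translation: np.ndarray  # (2,)
    model: str = "similarity"
    residual_rms_um: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)
        if not np.isfinite(self.matrix).all() or not np.isfinite(self.translation).all():
            raise ValueError("transform parameters must be finite")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("transform matrix is singular")

    @classmethod
    def identity(cls) -> "Transform2D":
        return cls(np.eye(2), np.zeros(2))

    def apply(self, points_um: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "Transform2D":
        inv = np.linalg.inv(self.matrix)
        return Transform2D(inv, -inv @ self.translation, model=self.model)

    def __call__(self, points_um: np.ndarray) -> np.ndarray:
        return self.apply(points_um)


@dataclass
class RegistrationQC:
    """Grid-displacement summary of a section-to-atlas transform."""

    n_points: int
    grid_spacing_um: float
    displacements_um: np.ndarray
    mean_um: float
    sd_um: float

    def to_dict(self) -> dict:
        return {
            "n_points": int(self.n_points),
            "grid_spacing_um": float(self.grid_spacing_um),
            "displacements_um": [float(d) for d in self.displacements_um],
            "mean_um": float(self.mean_um),
            "sd_um": float(self.sd_um),
        }


@dataclass
class RegionMap:
    """2D integer label image with id→name table; 0 is background."""

    label_image: np.ndarray  # (ny, nx) integer
    pixel_size_um: tuple[float, float]  # (dx, dy)
    id_to_name: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.label_image = np.asarray(self.label_image)
        if self.label_image.ndim != 2:
            raise ValueError("label_image must be 2D")
        if min(self.pixel_size_um) <= 0:
            raise ValueError("pixel sizes must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_image.shape

    @property
    def region_ids(self) -> list[int]:
        ids = np.unique(self.label_image)
        return [int(i) for i in ids if i != 0]

    @property
    def id_to_area_um2(self) -> dict[int, float]:
        dx, dy = self.pixel_size_um
        ids, counts = np.unique(self.label_image, return_counts=True)
        return {int(i): float(c) * dx * dy for i, c in zip(ids, counts) if i != 0}

    def bounds_um(self) -> tuple[tuple[float, float], tuple[float, float]]:
        ny, nx = self.label_image.shape
        dx, dy = self.pixel_size_um
        return (0.0, nx * dx), (0.0, ny * dy)


def fit_transform(
    fixed_points: np.ndarray,
    moving_points: np.ndarray,
    model: str = "similarity",
) -> Transform2D:
    """Least-squares transform mapping ``moving`` onto ``fixed`` (both in µm).

    Parameters
    ----------
    fixed_points, moving_points:
        (n, 2) corresponding coordinates; the returned transform satisfies
        ``T(moving) ≈ fixed``.
    model:
        ``"similarity"`` (rotation + isotropic scale + translation, ≥ 2
        pairs) or ``"affine"`` (≥ 3 non-collinear pairs).
    """
    fixed = np.atleast_2d(np.asarray(fixed_points, dtype=float))
    moving = np.atleast_2d(np.asarray(moving_points, dtype=float))
    if fixed.shape != moving.shape or fixed.shape[1] != 2:
        raise ValueError("fixed and moving must be matching (n, 2) arrays")
    n = fixed.shape[0]
    if model == "similarity":
        if n < 2:
            raise ValueError("similarity model needs >= 2 landmark pairs")
        tf = SimilarityTransform.from_estimate(moving, fixed)
    elif model == "affine":
        if n < 3:
            raise ValueError("affine model needs >= 3 landmark pairs")
        tf = AffineTransform.from_estimate(moving, fixed)
    else:
        raise ValueError(f"unknown transform model {model!r}")
    if not tf or not np.isfinite(tf.params).all():
        raise ValueError(f"degenerate landmark geometry for {model} fit")
    matrix = tf.params[:2, :2]
    translation = tf.params[:2, 2]
    if abs(np.linalg.det(matrix)) < 1e-12:
        raise ValueError(f"degenerate landmark geometry for {model} fit")
    out = Transform2D(matrix, translation, model=model)
    resid = out.apply(moving) - fixed
    # per-coordinate RMS, so pure landmark noise of SD s gives residual ~ s
    out.residual_rms_um = float(np.sqrt(np.mean(resid**2)))
    return out


def displacement_qc(
    transform: Transform2D,
    atlas_bounds_um: tuple[tuple[float, float], tuple[float, float]],
    grid_spacing_um: float = 350.0,
) -> RegistrationQC:
    """Displacement |T(p) − p| on a regular grid across the atlas bounds.

    The grid is anchored at the bounds origin so the metric is
    deterministic for given bounds.
    """
    (x0, x1), (y0, y1) = atlas_bounds_um
    if grid_spacing_um <= 0:
        raise ValueError("grid spacing must be > 0")
    xs = np.arange(x0, x1 + 1e-9, grid_spacing_um)
    ys = np.arange(y0, y1 + 1e-9, grid_spacing_um)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("atlas bounds enclose no grid point")
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    disp = np.linalg.norm(transform.apply(pts) - pts, axis=1)
    sd = float(np.std(disp, ddof=1)) if disp.size > 1 else 0.0
    return RegistrationQC(
        n_points=disp.size,
        grid_spacing_um=float(grid_spacing_um),
        displacements_um=disp,
        mean_um=float(np.mean(disp)),
        sd_um=sd,
    )


def assign_regions(
    points_um: np.ndarray,
    region_map: RegionMap,
    transform: Transform2D | None = None,
) -> np.ndarray:
    """Region id at the atlas pixel containing each transformed point.

    Points mapping outside the label image get background id 0.
    """
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    if transform is not None:
        pts = transform.apply(pts)
    dx, dy = region_map.pixel_size_um
    ny, nx = region_map.label_image.shape
    ix = np.floor(pts[:, 0] / dx).astype(int)
    iy = np.floor(pts[:, 1] / dy).astype(int)
    inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    ids = np.zeros(pts.shape[0], dtype=int)
    ids[inside] = region_map.label_image[iy[inside], ix[inside]]
    return ids
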