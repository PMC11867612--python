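"""Background correction and intensity-threshold estimation.

The background of a channel is a wide in-plane Gaussian smooth of each
z-plane; it is subtracted with clipping at zero. Detection thresholds
are estimated from square ROIs as pooled median + k·SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "ImageStack",
    "ThresholdReport",
    "estimate_background",
    "subtract_background",
    "compute_intensity_threshold",
    "default_rois",
]

# FWHM = 2 sqrt(2 ln 2) sigma for a Gaussian
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class ImageStack:
    """Multi-channel 3D intensity volume with physical voxel geometry.

    ``voxels`` has axes (channel, z, y, x); ``voxel_size_um`` is (dx, dy, dz).
    """

    voxels: np.ndarray
    voxel_size_um: tuple[float, float, float]
    channel_names: tuple[str, ...] = ("vgat", "tdt")

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError("voxels must have axes (channel, z, y, x)")
        if min(self.voxel_size_um) <= 0:
            raise ValueError("voxel sizes must be > 0")
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError("one channel name per channel required")

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    def channel(self, name_or_index) -> np.ndarray:
        if isinstance(name_or_index, str):
            return self.voxels[self.channel_names.index(name_or_index)]
        return self.voxels[name_or_index]

    def extent_um(self) -> tuple[float, float, float]:
        _, nz, ny, nx = self.voxels.shape
        dx, dy, dz = self.voxel_size_um
        return nx * dx, ny * dy, nz * dz


@dataclass
class ThresholdReport:
    """Pooled-ROI intensity threshold: median + k·SD."""

    roi_specs: list[tuple[float, float, int]]  # (corner x µm, corner y µm, side px)
    pooled_median: float
    pooled_sd: float
    k: float = 1.0
    threshold: float = field(init=False)

    def __post_init__(self) -> None:
        self.threshold = float(self.pooled_median + self.k * self.pooled_sd)

    def to_dict(self) -> dict:
        return {
            "roi_specs": [
                {"corner_x_um": float(x), "corner_y_um": float(y), "side_px": int(s)}
                for x, y, s in self.roi_specs
            ],
            "pooled_median": float(self.pooled_median),
            "pooled_sd": float(self.pooled_sd),
            "k": float(self.k),
            "threshold": float(self.threshold),
        }


def estimate_background(
    channel: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    diameter_um: float = 50.0,
) -> np.ndarray:
    """Smooth background field of a (z, y, x) channel.

    A Gaussian of FWHM ``diameter_um`` is applied independently to each
    z-plane (the stack is far shallower than the kernel). The operator is
    linear and preserves constant images.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.ndim != 3:
        raise ValueError("channel must have axes (z, y, x)")
    dx, dy, _ = voxel_size_um
    if diameter_um <= 0:
        raise ValueError("diameter_um must be > 0")
    if diameter_um < 2.0 * min(dx, dy):
        raise ValueError(
            f"background diameter {diameter_um} µm is smaller than 2 pixels"
        )
    sigma_um = diameter_um * _FWHM_TO_SIGMA
    sigma_px = (sigma_um / dy, sigma_um / dx)
    out = np.empty_like(channel)
    for iz in range(channel.shape[0]):
        out[iz] = gaussian_filter(channel[iz], sigma=sigma_px, mode="nearest")
    return out


def subtract_background(channel: np.ndarray, background: np.ndarray) -> np.ndarray:
    """``max(channel − background, 0)`` elementwise."""
    channel = np.asarray(channel, dtype=float)
    background = np.asarray(background, dtype=float)
    if channel.shape != background.shape:
        raise ValueError(
            f"shape mismatch: channel {channel.shape} vs background {background.shape}"
        )
    return np.clip(channel - background, 0.0, None)


def default_rois(
    corrected: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    side_px: int = 50,
    n_rois: int = 3,
) -> list[tuple[float, float, int]]:
    """Pick ``n_rois`` square ROIs spanning low to high local intensity.

    Candidate non-overlapping squares tile the image; they are ranked by
    mean corrected intensity and sampled evenly across that ranking, so
    the pooled statistics see areas of various punctum density.
    Deterministic for a given image.
    """
    nz, ny, nx = corrected.shape
    dx, dy, _ = voxel_size_um
    if side_px > min(nx, ny):
        raise ValueError("ROI side exceeds image extent")
    means = []
    for y0 in range(0, ny - side_px + 1, side_px):
        for x0 in range(0, nx - side_px + 1, side_px):
            means.append(
                (float(corrected[:, y0 : y0 + side_px, x0 : x0 + side_px].mean()), x0, y0)
            )
    means.sort()
    picks = np.linspace(0, len(means) - 1, num=min(n_rois, len(means))).round().astype(int)
    return [(means[i][1] * dx, means[i][2] * dy, side_px) for i in picks]


def compute_intensity_threshold(
    corrected: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    rois: list[tuple[float, float, int]] | None = None,
    k: float = 1.0,
    roi_side_px: int = 50,
) -> ThresholdReport:
    """Pool ROI voxel intensities; threshold = median + k·SD (sample SD).

    ROIs are (corner_x_um, corner_y_um, side_px) squares applied across
    all z-planes. When ``rois`` is None, :func:`default_rois` picks them.
    """
    corrected = np.asarray(corrected, dtype=float)
    nz, ny, nx = corrected.shape
    dx, dy, _ = voxel_size_um
    if rois is None:
        rois = default_rois(corrected, voxel_size_um, side_px=roi_side_px)
    if len(rois) == 0:
        raise ValueError("at least one ROI is required")
    pooled = []
    for x_um, y_um, side in rois:
        ix0 = int(np.floor(x_um / dx))
        iy0 = int(np.floor(y_um / dy))
        if ix0 < 0 or iy0 < 0 or ix0 + side > nx or iy0 + side > ny:
            raise ValueError(
                f"ROI corner ({x_um}, {y_um}) µm, side {side} px is out of bounds"
            )
        block = corrected[:, iy0 : iy0 + side, ix0 : ix0 + side]
        if block.size == 0:
            raise ValueError("empty ROI")
        pooled.append(block.ravel())
    values = np.concatenate(pooled)
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return ThresholdReport(
        roi_specs=[(float(x), float(y), int(s)) for x, y, s in rois],
        pooled_median=float(np.median(values)),
        pooled_sd=sd,
        k=float(k),
    )
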