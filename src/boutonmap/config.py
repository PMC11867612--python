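"""Pipeline configuration: a flat, versioned key-value document.

Unknown keys are rejected so that silent default drift cannot occur.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineParams", "load_params", "params_from_dict"]

CONFIG_VERSION = 1


@dataclass
class PipelineParams:
    """All numeric procedure constants of the anatomy/ephys pipeline."""

    background_diameter_um: float = 50.0
    threshold_k: float = 1.0
    roi_side_px: int = 50
    n_rois: int = 3
    bouton_diameter_um: float = 1.0
    tdt_min_separation_um: float = 0.5
    tdt_smooth_sigma_um: float = 0.25
    match_radius_um: float = 0.7
    min_bouton_voxels: int = 2
    bin_size_um: tuple[float, float, float] = (144.0, 144.0, 4.0)
    qc_grid_spacing_um: float = 350.0
    voxel_size_um: tuple[float, float, float] = (0.3611, 0.3611, 0.3)
    stack_depth_um: float = 1.5
    transform_model: str = "similarity"
    density_bins: int = 5
    rank_test: str = "normal"
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "background_diameter_um",
            "threshold_k",
            "bouton_diameter_um",
            "match_radius_um",
            "qc_grid_spacing_um",
            "stack_depth_um",
        ):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"parameter {name} must be > 0 (got {v})")
        if self.roi_side_px <= 0 or self.n_rois <= 0:
            raise ValueError("roi_side_px and n_rois must be > 0")
        if min(self.bin_size_um) <= 0 or min(self.voxel_size_um) <= 0:
            raise ValueError("bin and voxel sizes must be > 0")
        if not all(self.match_radius_um < b for b in self.bin_size_um):
            raise ValueError("match_radius_um must be smaller than every bin size")
        if self.transform_model not in ("similarity", "affine"):
            raise ValueError(f"unknown transform_model {self.transform_model!r}")
        if self.rank_test not in ("normal", "permutation"):
            raise ValueError(f"unknown rank_test {self.rank_test!r}")

    def to_dict(self) -> dict:
        out = {"config_version": CONFIG_VERSION}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out


def params_from_dict(doc: dict) -> PipelineParams:
    doc = dict(doc)
    version = doc.pop("config_version", CONFIG_VERSION)
    if version != CONFIG_VERSION:
        raise ValueError(f"unsupported config_version {version}")
    known = {f.name for f in fields(PipelineParams)}
    unknown = sorted(set(doc) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    tuple_keys = {"bin_size_um", "voxel_size_um"}
    for k in tuple_keys & set(doc):
        doc[k] = tuple(doc[k])
    params = PipelineParams(**doc)
    params.validate()
    return params


def load_params(path: Path | None) -> PipelineParams:
    if path is None:
        params = PipelineParams()
        params.validate()
        return params
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise ValueError("config file must be a flat key-value mapping")
    return params_from_dict(doc)
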