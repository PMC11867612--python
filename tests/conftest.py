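import numpy as np
import pytest

from boutonmap import synth
from boutonmap.config import PipelineParams
from boutonmap.pipeline import analyze_stack

VOXEL = (0.3611, 0.3611, 0.3)


@pytest.fixture(scope="session")
def default_scene():
    """One rendered default 3-region scene with ground truth and region map."""
    cfg = synth.default_scene_config(seed=1)
    stack, truth = synth.render_scene(cfg)
    nx, ny, _ = cfg.shape_voxels
    region_map = synth.generate_region_map(
        cfg.region_layout, (nx, ny), cfg.voxel_size_um[:2]
    )
    return cfg, stack, truth, region_map


@pytest.fixture(scope="session")
def default_analysis(default_scene):
    cfg, stack, truth, region_map = default_scene
    return analyze_stack(stack, region_map, PipelineParams())


def spot_image(positions_um, amplitudes, shape_zyx=(5, 64, 64), voxel=VOXEL,
               fwhm_um=1.0, baseline=0.0):
    """Noiseless Gaussian-spot fixture rendered on the voxel lattice."""
    vol = np.full(shape_zyx, float(baseline))
    sigma = fwhm_um / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    synth._add_spots(
        vol,
        np.atleast_2d(positions_um),
        np.atleast_1d(amplitudes),
        (sigma, sigma, sigma),
        voxel,
    )
    return vol
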