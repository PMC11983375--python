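import numpy as np
import pytest

from lipidmsi import annotation, peaks, pipeline, synthetic


@pytest.fixture(scope="session")
def lipid_db():
    return annotation.load_lipid_table()


@pytest.fixture(scope="session")
def hypotheses(lipid_db):
    return annotation.build_hypotheses(lipid_db)


@pytest.fixture(scope="session")
def small_scene():
    """Default 5-member scene at a reduced 16-pixel raster."""
    spec = synthetic.SceneSpec(raster_px=16, seed=11)
    scene = synthetic.make_scene(spec)
    cube, gt = synthetic.simulate_cube(scene)
    return spec, scene, cube, gt


@pytest.fixture(scope="session")
def small_run(small_scene, tmp_path_factory):
    """Full pipeline execution on the small default scene."""
    spec, _, _, gt = small_scene
    cfg = pipeline.PipelineConfig(n_components=6, k=3)
    run = pipeline.run_pipeline(
        cfg, scene_spec=spec, outdir=tmp_path_factory.mktemp("pipeline_run")
    )
    return run, gt


def gaussian_spectrum(grid, centers, sigma, areas=None):
    """Sum of unit-area Gaussians, sampled on ``grid``."""
    grid = np.asarray(grid, float)
    if areas is None:
        areas = [1.0] * len(centers)
    y = np.zeros_like(grid)
    for c, a in zip(centers, areas):
        g = np.exp(-0.5 * ((grid - c) / sigma) ** 2)
        y += a * g / g.sum()
    return y


@pytest.fixture
def toy_feature_image():
    """4x4-pixel two-channel image with a bright and a dim half."""
    table = peaks.PeakTable(
        np.array([700.0, 800.0]),
        np.array([699.9, 799.9]),
        np.array([700.1, 800.1]),
        np.array([10.0, 10.0]),
        np.array([False, False]),
    )
    matrix = np.zeros((16, 2))
    matrix[:8] = [100.0, 10.0]
    matrix[8:] = [1.0, 0.1]
    return peaks.FeatureImage(peak_table=table, matrix=matrix, shape=(4, 4))
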