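"""Shared fixtures: synthetic scenes and one full pipeline run per session."""

import numpy as np
import pytest

from standagb.pipeline import RunConfig, run_all
from standagb.synthetic_scene import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def base_config():
    """Small three-species scene used by generator-level tests."""
    return SceneConfig(
        extent=(0.0, 0.0, 120.0, 120.0), stand_tile_m=60.0,
        point_density_pts_m2=6.0, stems_per_ha=300.0,
        min_apex_separation_m=4.0, seed=42)


@pytest.fixture(scope="session")
def base_scene(base_config):
    return generate_scene(base_config)


@pytest.fixture(scope="session")
def segmentation_scene():
    """Scene sized for detection accuracy checks: apex spacing is twice the
    segmentation spacing threshold (the mean crown diameter, 2 m)."""
    cfg = SceneConfig(
        extent=(0.0, 0.0, 150.0, 150.0), stand_tile_m=75.0,
        point_density_pts_m2=8.0, stems_per_ha=300.0,
        min_apex_separation_m=4.0, seed=7)
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def normalized_segmentation_scene(segmentation_scene):
    """Ground-filtered and height-normalized cloud of the detection scene."""
    from standagb.point_cloud import classify_ground, denoise, normalize_heights

    cloud = denoise(segmentation_scene.cloud.copy())
    cloud = classify_ground(cloud)
    norm, _ = normalize_heights(cloud)
    return norm


@pytest.fixture(scope="session")
def demo_config(tmp_path_factory):
    wd = tmp_path_factory.mktemp("demo_run")
    return RunConfig(
        workdir=str(wd),
        scene=SceneConfig(
            extent=(0.0, 0.0, 270.0, 270.0), stand_tile_m=135.0,
            point_density_pts_m2=6.0, stems_per_ha=350.0,
            min_apex_separation_m=4.0, seed=11),
        seed=11)


@pytest.fixture(scope="session")
def demo_run(demo_config):
    """One full synthetic experiment; manifests keyed by stage name."""
    manifests = run_all(demo_config)
    return {m["stage"]: m for m in manifests}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
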