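import numpy as np
import pytest

from octrack import PhantomConfig, generate_scene
from octrack.features import extract_organoids


@pytest.fixture(scope="session")
def small_scene():
    """Quick 3-timepoint phantom used by several modules' tests."""
    cfg = PhantomConfig(shape=(48, 80, 80), n_organoids=5, days=(1, 3, 5), seed=11)
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def small_scene_records(small_scene):
    return {d: extract_organoids(lv) for d, lv in small_scene.labels.items()}


@pytest.fixture(scope="session")
def tracking_scene():
    """Ten organoids over seven timepoints, the reference tracking scenario."""
    cfg = PhantomConfig(
        shape=(64, 128, 128),
        n_organoids=10,
        days=(1, 3, 5, 7, 9, 11, 13),
        seed=5,
    )
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def tracking_scene_records(tracking_scene):
    return {d: extract_organoids(lv) for d, lv in tracking_scene.labels.items()}
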