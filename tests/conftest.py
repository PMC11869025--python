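import numpy as np
import pytest

from vinescout import (
    HueBlobDetector,
    LuminanceForeground,
    SceneSpec,
    generate_scene,
)


@pytest.fixture(scope="session")
def small_spec() -> SceneSpec:
    """Compact scene used across tests: fast to render, same structure."""
    return SceneSpec(
        width=480,
        height=360,
        n_clusters=8,
        cluster_radius_range=(10.0, 18.0),
        foreground_band=(190, 340),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_scene(small_spec):
    return generate_scene(small_spec)


@pytest.fixture(scope="session")
def foreground_backend():
    return LuminanceForeground()


@pytest.fixture(scope="session")
def blob_detector():
    return HueBlobDetector()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
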