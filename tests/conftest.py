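import pytest

from gridfree import SceneSpec, SegmentThresholds, generate_scene


@pytest.fixture
def small_scene():
    return generate_scene(SceneSpec(shape=(400, 400), n_objects=10, seed=7))


@pytest.fixture
def permissive_thresholds():
    return SegmentThresholds(area_min=20, diag_min=4)
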