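import numpy as np
import pytest
from hypothesis import settings

from hairpinpath.model_io import frameset_from_backbone
from hairpinpath.synthetic import (
    CONDITION_HBONDS,
    CONDITION_TURNS,
    alpha_syn12_topology,
    build_template_library,
    make_ideal_hairpin,
    make_ideal_helix,
)

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def topology():
    return alpha_syn12_topology("physiological")


@pytest.fixture(scope="session")
def templates(topology):
    """Template library for the physiological condition (built once)."""
    return build_template_library(
        topology,
        CONDITION_TURNS["physiological"],
        CONDITION_HBONDS["physiological"],
    )


@pytest.fixture(scope="session")
def helix_frame(topology):
    return make_ideal_helix(topology)


@pytest.fixture(scope="session")
def hairpin_frame(topology):
    return make_ideal_hairpin(
        topology,
        CONDITION_TURNS["physiological"],
        CONDITION_HBONDS["physiological"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_frameset(topology, helix_frame, rng):
    """20 noisy helix frames."""
    coords = helix_frame[None] + rng.normal(0, 0.002, (20, *helix_frame.shape))
    from hairpinpath.model_io import TrajectoryFrameSet

    return TrajectoryFrameSet(
        topology, coords, np.arange(20) * 0.05, "fixture"
    )


@pytest.fixture(scope="session")
def frameset_from_frame():
    """Helper: wrap a single frame (or stack) into a TrajectoryFrameSet."""
    from hairpinpath.model_io import TrajectoryFrameSet

    def _wrap(topology, coords):
        coords = np.asarray(coords)
        if coords.ndim == 2:
            coords = coords[None]
        return TrajectoryFrameSet(
            topology, coords, np.arange(coords.shape[0], dtype=float)
        )

    return _wrap
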