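import numpy as np
import pytest

from locoresp.io_formats import SessionConfig
from locoresp.synthetic_data import SimScenario, simulate_session


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_session(seed: int = 1, **overrides):
    """Synthetic session plus a matching analysis config."""
    kwargs = dict(seed=seed, duration=60.0, quiet_s=2.0)
    kwargs.update(overrides)
    sc = SimScenario(**kwargs)
    emg, tracks, gt = simulate_session(sc)
    cfg = SessionConfig(
        belt_speed=sc.belt_speed if sc.gait != "rest" else 0.0,
        fps=sc.fps,
        fs_emg=sc.fs_emg,
        params={"baseline_epoch": [0.0, sc.quiet_s], "seed": sc.seed},
    )
    return sc, emg, tracks, gt, cfg


@pytest.fixture
def trot_session():
    return make_session(seed=1)
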