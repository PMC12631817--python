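import numpy as np
import pytest

from uspt import synthdata as sd
from uspt import transport as tr


@pytest.fixture(scope="session")
def control_preset():
    return sd.make_control_preset()


@pytest.fixture(scope="session")
def small_cohort(control_preset):
    """A quick 6-trajectory control cohort for plumbing tests."""
    from dataclasses import replace

    preset = replace(control_preset, n_trajectories=6, n_frames=300)
    trajs, truth = sd.generate_cohort(preset, seed=1234)
    return preset, trajs, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_model(spec, d=0.01, speeds=(0.5, 0.5), diag=0.9):
    """Small helper to build a MotionModel for a given state-kind tuple."""
    k = len(spec)
    states = []
    directions = [np.array([1.0, 0.0]), np.array([-1.0, 0.0]), np.array([0.0, 1.0])]
    di = 0
    for kind in spec:
        if kind == "D":
            states.append(tr.MotionState("D", d))
        else:
            states.append(tr.MotionState("DT", d, speeds[di % len(speeds)] * directions[di]))
            di += 1
    a = np.full((k, k), (1 - diag) / max(k - 1, 1))
    np.fill_diagonal(a, diag if k > 1 else 1.0)
    return tr.MotionModel(states, a, np.full(k, 1.0 / k))
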