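import numpy as np
import pytest

import sharkmove as sm
from sharkmove.synthetic import ScenarioSpec, StateEmission


@pytest.fixture(scope="session")
def preset_tracks():
    """One full simulated study (39 sequences) from the whale-shark preset."""
    return sm.simulate_tracks(sm.whale_shark_preset(seed=11))


@pytest.fixture(scope="session")
def preset_series(preset_tracks):
    return [sm.steps_and_angles(t) for t in preset_tracks]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def two_state_spec(seed=0, n_sequences=4, length_range=(150, 200), beta1=None):
    """Small, well-separated two-state scenario used across HMM tests."""
    if beta1 is None:
        beta1 = np.zeros((2, 2))
    return ScenarioSpec(
        emissions=[
            StateEmission(mu=0.05, sigma=0.03, theta=0.0, kappa=1.0, zeta=0.01),
            StateEmission(mu=0.50, sigma=0.30, theta=0.0, kappa=0.10, zeta=0.01),
        ],
        beta0=np.array([[0.0, -1.5], [-1.5, 0.0]]),
        beta1=np.asarray(beta1, dtype=float),
        delta0=np.array([0.5, 0.5]),
        n_sequences=n_sequences,
        length_range=length_range,
        covariate_assignment=0.5,
        seed=seed,
    )


def random_walk_track(rng, n=200, step_scale=1.0, video_id="rw", human=0):
    """Smooth-ish random-walk track for geometry tests."""
    angles = rng.normal(0.0, 0.6, size=n - 1)
    heading = np.cumsum(np.concatenate([[rng.uniform(-np.pi, np.pi)], angles[1:]]))
    steps = rng.gamma(4.0, step_scale / 4.0, size=n - 1)
    x = np.concatenate([[0.0], np.cumsum(steps * np.cos(heading))])
    y = np.concatenate([[0.0], np.cumsum(steps * np.sin(heading))])
    return sm.TrackTable(
        video_id=video_id, frames=np.arange(n), x=x, y=y, human_present=human
    )
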