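"""Shared fixtures: small synthetic datasets used across test modules."""

import numpy as np
import pytest

from driftstab import dataio, synthetic as sy
from driftstab.data import KinematicsSeries, SessionData


@pytest.fixture(scope="session")
def drifting_dataset():
    """Six sessions of 40 units with moderate random-walk tuning drift."""
    cfg = sy.SimulateConfig(
        n_units=40, n_sessions=6, n_trials=40, seed=7, p_gap=0.3,
        drift=sy.DriftSpec("random_walk", step_size=0.05, seed=1),
        noise_params=sy.NoiseParams(0.5, 0.5, 0.5))
    return sy.generate_dataset(cfg)


@pytest.fixture(scope="session")
def prepared_dataset(drifting_dataset):
    return drifting_dataset.map_sessions(dataio.prepare_decoding_series)


@pytest.fixture(scope="session")
def stationary_dataset():
    """Zero-drift sessions: same tuning every day, fresh noise."""
    cfg = sy.SimulateConfig(
        n_units=30, n_sessions=5, n_trials=30, seed=21, p_gap=0.0,
        drift=sy.DriftSpec("random_walk", step_size=0.0, seed=2),
        noise_params=sy.NoiseParams(0.5, 0.5, 0.5))
    return sy.generate_dataset(cfg)


@pytest.fixture(scope="session")
def prepared_stationary(stationary_dataset):
    return stationary_dataset.map_sessions(dataio.prepare_decoding_series)


def make_ramp_session(n_trials=12, samples_per_trial=40, maze_len=4.5,
                      n_units=6, seed=0, informative=False):
    """Hand-built session: linear position ramps, optional linear code.

    With ``informative=True`` the first unit's activity equals the
    (per-trial-centered) position exactly, making the session perfectly
    linearly decodable; remaining units are pure noise.
    """
    rng = np.random.default_rng(seed)
    T = n_trials * samples_per_trial
    pos = np.tile(np.linspace(0, maze_len, samples_per_trial), n_trials)
    trial = np.repeat(np.arange(n_trials), samples_per_trial)
    kin = KinematicsSeries(
        time=np.arange(T) / 5.3, position=pos,
        velocity=np.gradient(pos) * 5.3,
        view_angle=np.zeros(T), trial_id=trial,
        correct=np.ones(T, bool), cue=np.zeros(T, int),
        iti_flag=np.zeros(T, bool), maze_len_m=maze_len)
    act = rng.standard_normal((T, n_units))
    if informative:
        centered = pos - maze_len / 2.0
        act[:, 0] = centered
    return SessionData(day_index=0, unit_ids=np.arange(n_units),
                       activity=act, kinematics=kin, sample_rate_hz=5.3)
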