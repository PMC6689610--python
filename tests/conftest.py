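"""Shared fixtures: small deterministic synthetic sessions."""

import numpy as np
import pytest

import hrtfcues as hc


@pytest.fixture(scope="session")
def tiny_grid():
    return hc.SessionGrid(azimuths=hc.default_azimuths(step=30.0))


@pytest.fixture(scope="session")
def tiny_session(tiny_grid):
    """7-azimuth, 0.5 s sweep session on land (canal blocked), SNR 40 dB."""
    geometry = hc.preset_geometry("crocodile", canal_state="blocked")
    scene = hc.SceneConfig(condition="land", noise_level=-40.0, seed=11)
    return hc.simulate_session(
        tiny_grid, geometry, scene, hc.StimulusSpec(duration=0.5),
        seed=11, n_calibrations=3,
    )


@pytest.fixture(scope="session")
def tiny_maps(tiny_grid, tiny_session):
    return hc.analyze_session(
        tiny_grid, tiny_session.recordings, tiny_session.calibrations,
        reference=tiny_session.stimulus_signal,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
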