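"""Shared fixtures: small simulated trials and one rendered+tracked sequence.

Everything is generated programmatically at test time; the expensive
render-and-track fixture is session-scoped because several tests assert on
different aspects of the same recovery run.
"""

import dataclasses

import numpy as np
import pytest

import neuromech as nm
from neuromech.simdata import ImagingConfig, _geometry_at


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_trial():
    """One default sustained 20 %MVC trial (30-s plateau, CST-driven)."""
    return nm.simulate_trial(seed=3)


@pytest.fixture(scope="session")
def default_analysis(default_trial):
    return nm.analyze_trial(default_trial)


@pytest.fixture(scope="session")
def tracked_ramp():
    """Rendered ramp-hold sequence with 7.5-mm commanded shortening, tracked.

    Short-muscle geometry (rest 60.2 mm), noiseless fascicle command, 6-s
    plateau so the sequence stays desk-scale (880 frames at 80 fps).
    """
    protocol = nm.ProtocolConfig(plateau_s=6.0, rest_s=0.5)
    mech = dataclasses.replace(nm.SHORT_TA, fascicle_noise_mm=0.0)
    trial = nm.simulate_trial(
        protocol=protocol, mechanics=mech, seed=4, with_frames=True
    )
    geom0 = _geometry_at(
        ImagingConfig(),
        trial.truth_fascicle.rest_length_mm,
        trial.truth_fascicle.pennation_deg[0],
    )
    result = nm.track_fascicle(trial.frames, geom0)
    return trial, result
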