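"""Shared fixtures: one default synthetic session (with cross-validated
projections) reused across test modules, plus a tiny hand-written session."""

import numpy as np
import pandas as pd
import pytest

from attnaxes import GeneratorConfig, SessionData
from attnaxes.attention_axes import cross_validated_projections
from attnaxes.synthetic_data import generate_session


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=123)


@pytest.fixture(scope="session")
def synth_session(default_config):
    """One default-condition synthetic session plus its ground truth."""
    return generate_session(default_config)


@pytest.fixture(scope="session")
def synth_projections(synth_session):
    """Cross-validated axis model and per-flash projection records."""
    session, _ = synth_session
    model, records = cross_validated_projections(
        session, n_folds=40, rng=np.random.default_rng(7))
    return model, records


def make_tiny_session():
    """Hand-written 2-trial, 2-unit session small enough to reason about."""
    flashes = pd.DataFrame([
        # session, trial, flash, onset, cue_trial, cue, stim, ori, target,
        # t_loc, delta, outcome, rt
        ("T", 1, 1, 400, False, "RF", "bilateral", 45.0, False, "none",
         0.0, "none", np.nan),
        ("T", 1, 2, 1200, False, "RF", "bilateral", 45.0, False, "none",
         0.0, "none", np.nan),
        ("T", 1, 3, 2000, False, "RF", "bilateral", 48.0, True, "RF",
         3.0, "hit", 250.0),
        ("T", 2, 1, 350, False, "away", "bilateral", 135.0, False, "none",
         0.0, "none", np.nan),
        ("T", 2, 2, 1100, False, "away", "bilateral", 132.0, True, "away",
         -3.0, "miss", np.nan),
    ], columns=["session_id", "trial_id", "flash_index", "onset_ms",
                "is_cue_trial", "cue_location", "stimulus_locations",
                "orientation_RF", "is_target", "target_location",
                "delta_orientation", "outcome", "response_time_ms"])
    spikes = pd.DataFrame({
        "unit_id": ["u0", "u0", "u0", "u1", "u1"],
        "trial_id": [1, 1, 2, 1, 2],
        "time_ms": [650, 799, 500, 300, 1099],
    })
    units = pd.DataFrame({"unit_id": ["u0", "u1"], "snr": [3.5, np.nan]})
    return SessionData(flashes, spikes, units)


@pytest.fixture()
def tiny_session():
    return make_tiny_session()
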