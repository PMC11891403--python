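"""Shared fixtures.

The default model's steady state and the three feeding experiments are
expensive enough (a couple of seconds each) to be computed once per
session and shared across tests.
"""

from __future__ import annotations

import pytest

from acylsim import build_model, find_steady_state, run_feeding_experiment


@pytest.fixture(scope="session")
def model():
    return build_model()


@pytest.fixture(scope="session")
def baseline(model):
    return find_steady_state(model)


@pytest.fixture(scope="session")
def experiments(model, baseline):
    """The three fatty-acid feeding experiments with a shared baseline."""
    return {
        fa: run_feeding_experiment(model, fa, baseline=baseline)
        for fa in ("palmitate", "palmitoleate", "cis-vaccenate")
    }


@pytest.fixture(scope="session")
def palmitate(experiments):
    return experiments["palmitate"]
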