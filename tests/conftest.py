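"""Shared fixtures: small constructed sessions and simulated cohorts.

Expensive simulated cohorts are session-scoped so that module tests and the
acceptance tests reuse the same data.
"""

from __future__ import annotations

import numpy as np
import pytest

from spiketrans.core import (
    CellClass,
    EpochSet,
    Session,
    SpikeTrain,
    StimulusEvents,
)
from spiketrans.prediction import cohort_difference_features
from spiketrans.simulate import simulate_stim_feature_cohort


@pytest.fixture
def tiny_session() -> Session:
    """Two units, three epochs, two stimulus events."""
    epochs = EpochSet(
        {"Before": (0.0, 10.0), "Experience": (10.0, 20.0), "After": (20.0, 30.0)}
    )
    trains = {
        "u1": SpikeTrain("u1", np.array([1.0, 2.0, 12.0, 25.0]), CellClass.PYR, 1),
        "u2": SpikeTrain("u2", np.array([0.5, 11.0, 21.0]), CellClass.PV, 2),
    }
    events = StimulusEvents(np.array([12.0, 13.0]), 0.030, 0.020, ("u1", None))
    return Session(trains=trains, epochs=epochs, events=events, duration_s=30.0)


@pytest.fixture(scope="session")
def latency_cohort_features():
    """122 assemblies whose stimulus effect restructures pair latency."""
    cohort = simulate_stim_feature_cohort(122, "latency", seed=7)
    return cohort_difference_features(cohort)


@pytest.fixture(scope="session")
def gain_cohort_features():
    """122 assemblies whose stimulus effect is a pure postsynaptic rate gain."""
    cohort = simulate_stim_feature_cohort(122, "gain", seed=8)
    return cohort_difference_features(cohort)
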