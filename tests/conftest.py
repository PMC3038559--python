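import warnings

import numpy as np
import pytest

from restconn import (
    CausalGraphSpec,
    build_var_model,
    sensory_pattern_graph,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def pattern_spec():
    """The calibrated 18-ROI sensory-network generator spec (built once)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sensory_pattern_graph()


@pytest.fixture(scope="session")
def pattern_cohort(pattern_spec):
    """One 29-subject, 200-time-point cohort from the reference network."""
    model = build_var_model(pattern_spec)
    return simulate_cohort(model, n_subjects=29, n_timepoints=200, seed=1234)


@pytest.fixture()
def two_roi_spec():
    """Stationary 2-ROI VAR(1) with a single directed link x -> y."""
    coeff = np.array([[[0.5, 0.0], [0.4, 0.5]]])
    return CausalGraphSpec(("x", "y"), 1, coeff, np.eye(2), seed=7)


@pytest.fixture()
def null_spec_4():
    """4-ROI white-noise spec (no lag structure, independent innovations)."""
    return CausalGraphSpec(
        ("a", "b", "c", "d"), 1, np.zeros((1, 4, 4)), np.eye(4), seed=11
    )
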