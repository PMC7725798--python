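"""Shared fixtures: synthetic legs, trials and cohorts with known truth."""

import numpy as np
import pytest

from myocot.synthetic_gait import (
    SyntheticCohortSpec,
    default_leg_spec,
    generate_cohort,
    generate_trial,
)


@pytest.fixture(scope="session")
def leg_spec():
    return default_leg_spec()


@pytest.fixture(scope="session")
def truth_model(leg_spec):
    return leg_spec.truth_model()


@pytest.fixture(scope="session")
def symmetric_trial(leg_spec):
    """A trial with zero injected asymmetries."""
    return generate_trial(leg_spec, 0.5, {}, seed=10)


@pytest.fixture(scope="session")
def asymmetric_trial(leg_spec):
    """A trial with known signed asymmetries."""
    asym = {"step_length": 0.08, "stance_time": 0.15, "double_support": 0.08}
    return generate_trial(leg_spec, 0.5, asym, seed=11)


@pytest.fixture(scope="session")
def small_cohort(leg_spec):
    """Three speeds x two trials, imposed B04 CoT trend, no jitter/noise."""
    spec = SyntheticCohortSpec(
        speeds=(0.4, 0.6, 0.8), trials_per_speed=2, amp_jitter=0.0, seed=4
    )
    return generate_cohort(spec, leg_spec), spec
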