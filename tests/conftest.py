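import numpy as np
import pytest

from isrsa import SimSpec, generate_behavior, generate_timecourses


@pytest.fixture(scope="session")
def toy_spec():
    """Small mixed cohort: one node per planted structure plus a weak one."""
    return SimSpec(
        n_subjects=24,
        n_nodes=4,
        n_timepoints=240,
        node_models=("annak", "nn", "null", "annak"),
        coupling=(0.8, 0.8, 0.0, 0.4),
        seed=11,
    )


@pytest.fixture(scope="session")
def toy_cohort(toy_spec):
    behavior = generate_behavior(toy_spec)
    tc = generate_timecourses(behavior, toy_spec)
    return behavior, tc


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
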