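import numpy as np
import pandas as pd
import pytest

from survcompare import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest planted-signal cohort shared by read-only tests."""
    return generate_cohort(CohortSpec(n_patients=150, n_genes=40, seed=7))


def random_step_curve(rng, horizon):
    """A random valid survival step curve on [0, horizon]."""
    k = rng.integers(1, 6)
    times = np.sort(rng.uniform(1, horizon, size=k))
    values = np.sort(rng.uniform(0, 1, size=k))[::-1]
    from survcompare import StepCurve

    return StepCurve(times=times, values=values)


def make_followup(rng, n, horizon, dead_frac=0.6):
    day = rng.uniform(1, horizon * 1.3, size=n)
    status = np.where(rng.random(n) < dead_frac, "dead", "alive").astype(object)
    return day, status
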