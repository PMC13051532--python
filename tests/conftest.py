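import numpy as np
import pytest

from idmaft.likelihood import (
    ModelParams,
    RandomEffectSpec,
    SubjectArrays,
    SubjectRecord,
)
from idmaft.simulate import generate, scenario
from idmaft.transitions import TransitionParams


@pytest.fixture(scope="session")
def small_cohort():
    """A small early-censoring cohort (n_initial=500) with its truth table."""
    scen = scenario("E65_S", seed=20240)
    dataset, truth = generate(scen)
    return scen, dataset, truth


@pytest.fixture(scope="session")
def small_arrays(small_cohort):
    _, dataset, _ = small_cohort
    return SubjectArrays(dataset)


@pytest.fixture
def example_params():
    """Plausible dementia-cohort parameters with a hetvar random effect."""
    return ModelParams(
        inc=TransitionParams(np.array([4.62, 0.03]), 7.0, "i"),
        mort0=TransitionParams(np.array([4.49, -0.04]), 10.8, "m0"),
        mort1=TransitionParams(np.array([4.23, -0.08]), 8.1, "m1"),
        re=RandomEffectSpec(
            "hetvar",
            si2=0.008237,
            sm02=0.000714,
            sm12=0.000063,
            ci_m1=0.000115,
        ),
    )


def make_subject(
    entry=60.0,
    t_left=78.0,
    t_right=81.0,
    last=86.0,
    delta1=1,
    delta2=1,
    x=(1.0, 1.0),
):
    return SubjectRecord(
        entry_age=entry,
        t_left=t_left,
        t_right=t_right,
        last_age=last,
        delta1=delta1,
        delta2=delta2,
        x=np.asarray(x),
    )
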