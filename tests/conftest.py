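import numpy as np
import pytest

from metsim.cohort import GeneratorConfig, generate_cohort
from metsim.core import Stratum
from metsim.curves import RateCurve

@pytest.fixture(scope="session")
def default_cohort():
    """A mid-sized cohort drawn from the default generating process."""
    return generate_cohort(GeneratorConfig(n_participants=40_000, seed=20_240_101))


@pytest.fixture(scope="session")
def stratum():
    return Stratum("female", "low")


def constant_incidence(rate: float, stratum=Stratum("female", "low")) -> RateCurve:
    # logit3 with k=0 is the constant function L/2
    return RateCurve(stratum, "incidence", "logit3", (2.0 * rate, 0.0, 40.0))


def constant_recovery(rate: float, stratum=Stratum("female", "low")) -> RateCurve:
    return RateCurve(stratum, "recovery", "poly4", (rate, 0.0, 0.0, 0.0, 0.0))


@pytest.fixture
def make_constant_curves():
    def _make(lam: float, mu: float, stratum=Stratum("female", "low")):
        return constant_incidence(lam, stratum), constant_recovery(mu, stratum)

    return _make
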