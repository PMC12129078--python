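import numpy as np
import pytest

import benefitsens as bs


@pytest.fixture(scope="session")
def truths():
    """Quadrature truth sets for the three preset scenarios."""
    return {name: bs.truth_by_quadrature(bs.scenario(name)) for name in ("I", "II", "III")}


@pytest.fixture(scope="session")
def worked_example():
    """The fully-enumerated 36-subject illustration table."""
    return bs.worked_example_table()


@pytest.fixture(scope="session")
def scenario3_n2000():
    """One fixed Scenario III trial of n=2000 with its fitted model."""
    data = bs.sample_trial(bs.scenario("III", n=2000), seed=314159)
    model = bs.fit_outcome_model(data)
    return data, model


def random_joint(rng: np.random.Generator) -> bs.JointPotentialDist:
    """A random strictly positive joint potential-outcome distribution."""
    cells = rng.dirichlet(np.ones(4)) * 0.96 + 0.01
    return bs.JointPotentialDist(p00=cells[0], p01=cells[1], p10=cells[2], p11=cells[3])
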