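import numpy as np
import pytest

from compmi.analytic import TwoComponentJoint


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def worked_example_joints():
    """Independent-component joints of the closed-form worked example:
    per-arm component probabilities 0.7 and 0.2."""
    return (
        TwoComponentJoint.from_marginals(0.7, 0.7),
        TwoComponentJoint.from_marginals(0.2, 0.2),
    )


def random_joint(rng, floor: float = 1e-3) -> TwoComponentJoint:
    """A random valid four-cell joint with all cells bounded away from 0."""
    cells = rng.dirichlet(np.ones(4)) * (1 - 4 * floor) + floor
    return TwoComponentJoint(*cells)
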