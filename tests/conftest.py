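import numpy as np
import pytest

import llte
from llte.gait import UserCharacteristics
from llte.parametrization import FrameMesh, SoleMap, complete_design
from llte.solver import NYLON_66


@pytest.fixture(scope="session")
def user():
    return UserCharacteristics(
        body_mass=70.0, foot_length=0.26, lower_leg_length=0.50,
        residuum_length=0.30, build_height_h_ank=0.08)


#: a plausible compliant test foot used across the suite
TEST_DESIGN_VARS = np.array([
    0.012,               # C1.d
    0.02, -0.03, 0.012,  # C2
    0.06, -0.05, 0.012,  # C3
    0.10, 0.012,         # C4.x, C4.d
    0.010, 0.010,        # C5.d, C6.d
])

#: a stiffer design that satisfies the stress constraint under walking loads
FEASIBLE_DESIGN_VARS = np.array([
    0.020, 0.03, -0.02, 0.020, 0.08, -0.04, 0.018, 0.12, 0.016, 0.012, 0.016,
])


@pytest.fixture(scope="session")
def test_design(user):
    return complete_design(TEST_DESIGN_VARS, user)


@pytest.fixture(scope="session")
def ref_gait():
    return llte.synthesize_reference_gait(seed=1)


@pytest.fixture(scope="session")
def nine_cases(ref_gait):
    return llte.resample_stance(ref_gait)


@pytest.fixture(scope="session")
def foot_model(test_design, user):
    """Meshed test foot shared across engine tests (moderate resolution)."""
    from llte.engine import FootModel
    return FootModel(test_design, NYLON_66, user, n_elements=120)


def straight_cantilever(length=0.25, n=50, thickness=0.01, width=0.06) -> FrameMesh:
    """Horizontal cantilever clamped at node 0, as a FrameMesh."""
    x = np.linspace(0.0, length, n + 1)
    nodes = np.column_stack([x, np.zeros_like(x)])
    elements = np.column_stack([np.arange(n), np.arange(1, n + 1)])
    th = np.full(n, thickness)
    sole = SoleMap(
        node_ids=np.arange(n + 1),
        bottom=nodes - [0.0, thickness / 2.0],
        tangent_angle=np.zeros(n + 1),
        offset_vec=np.tile([0.0, -thickness / 2.0], (n + 1, 1)),
        heel_tip_index=0, toe_tip_index=n)
    return FrameMesh(nodes=nodes, elements=elements, thickness=th, width=width,
                     area=width * th, inertia=width * th**3 / 12.0,
                     attachment_node=0, sole=sole,
                     node_segment=np.zeros(n + 1, dtype=int))
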