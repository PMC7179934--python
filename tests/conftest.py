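import numpy as np
import pytest

from gridgen import taskenv


@pytest.fixture(scope="session")
def designs():
    return {
        "1_repeat": taskenv.build_design(1, "repeat"),
        "1_switch": taskenv.build_design(1, "switch"),
        "2": taskenv.build_design(2),
        "3": taskenv.build_design(3),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def open_trial(designs, rng):
    """A wall-free trial with known goal/start placement on the exp-2 grid."""
    design = designs["2"]
    grid = taskenv.GridWorld(goal_cells={"A": (5, 5), "B": (0, 5), "C": (5, 0),
                                         "D": (2, 3)})
    return taskenv.TrialSpec(0, design.test_contexts[0].context_id, grid,
                             (0, 0), "test")
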