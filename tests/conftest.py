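import numpy as np
import pytest

from pcsdecision import generate_task_set, make_task


@pytest.fixture(scope="session")
def printed_tasks():
    """The three example tasks displayed with the paradigm description:
    4 cue validities each, options A and B coded +1/-1."""
    t1 = make_task(
        (0.87, 0.87, 0.76, 0.60),
        [[1, 1], [1, -1], [-1, 1], [-1, 1]],
        id="task1",
    )
    t2 = make_task(
        (0.94, 0.79, 0.73, 0.63),
        [[1, 1], [-1, 1], [1, -1], [1, -1]],
        id="task2",
    )
    t3 = make_task(
        (0.77, 0.74, 0.68, 0.63),
        [[1, 1], [1, -1], [-1, 1], [1, 1]],
        id="task3",
    )
    return t1, t2, t3


@pytest.fixture(scope="session")
def task_set_60():
    """Seeded 60-task generated set shared across the suite (shares the
    PCS grid cache)."""
    return generate_task_set(60, seed=42)


@pytest.fixture(scope="session")
def small_task_set():
    return generate_task_set(12, seed=7)
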