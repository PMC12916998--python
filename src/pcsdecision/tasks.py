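"""Multi-cue probabilistic inference tasks.

A task presents two options (A, B) described by four binary cues of known
validity. Cue validities are proportions correct in (0.5, 1.0), listed in
descending order (most valid cue first). Cue values are coded +1 ("good
performance predicted") / -1 ("bad performance predicted") so that the sign
of a cue-option link in the constraint-satisfaction network follows directly
from the cue value.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

N_CUES = 4
N_OPTIONS = 2

__all__ = [
    "Task",
    "TaskSet",
    "make_task",
    "mirror_task",
    "read_tasks",
    "write_tasks",
    "is_dominated",
]


@dataclass(frozen=True)
class Task:
    """One probabilistic inference item.

    Attributes
    ----------
    id : str
        Identifier, unique within a :class:`TaskSet`.
    validities : tuple of 4 floats
        Cue validities in (0.5, 1.0), sorted non-increasing.
    cue_matrix : 4x2 ndarray of +1/-1
        Rows are cues (in validity order), columns are options A and B.
    dominated : bool
        True when one option is at least as good as the other on every cue
        and strictly better on at least one. Such items have a trivial best
        answer and are excluded by the task generator.
    """

    id: str
    validities: tuple[float, float, float, float]
    cue_matrix: np.ndarray = field(compare=False)
    dominated: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "cue_matrix", np.asarray(self.cue_matrix, dtype=int))
        self.cue_matrix.setflags(write=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Task):
            return NotImplemented
        return (
            self.id == other.id
            and self.validities == other.validities
            and np.array_equal(self.cue_matrix, other.cue_matrix)
        )

    def __hash__(self) -> int:
        return hash((self.id, self.validities, self.cue_matrix.tobytes()))

    @property
    def option_a(self) -> np.ndarray:
        return self.cue_matrix[:, 0]

    @property
    def option_b(self) -> np.ndarray:
        return self.cue_matrix[:, 1]

    def signature(self) -> tuple:
        """Content key (validities rounded to 4 d.p. plus cue pattern) used
        for duplicate detection; the id does not participate."""
        return (
            tuple(round(v, 4) for v in self.validities),
            self.cue_matrix.tobytes(),
        )

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "validities": list(self.validities),
            "option_a": self.option_a.tolist(),
            "option_b": self.option_b.tolist(),
            "dominated": self.dominated,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Task":
        matrix = np.column_stack([d["option_a"], d["option_b"]])
        return make_task(d["validities"], matrix, id=d["id"])


def is_dominated(cue_matrix: np.ndarray) -> bool:
    """Brute-force dominance over the 4 cue rows: one column >= the other
    everywhere with at least one strict inequality."""
    a, b = cue_matrix[:, 0], cue_matrix[:, 1]
    a_dom = bool(np.all(a >= b) and np.any(a > b))
    b_dom = bool(np.all(b >= a) and np.any(b > a))
    return a_dom or b_dom


def make_task(
    validities: Sequence[float],
    cue_matrix: Sequence[Sequence[int]] | np.ndarray,
    id: str = "",
) -> Task:
    """Validate and build a :class:`Task`.

    Validities are stored in descending order; if the input is not sorted the
    cue rows are permuted along with them (stable, so equally valid cues keep
    their input order). Dominated patterns are accepted but flagged.

    Raises
    ------
    ValueError
        On wrong shapes, validities outside (0.5, 1.0), cue values other
        than +1/-1, or identical option columns.
    """
    v = np.asarray(validities, dtype=float)
    if v.shape != (N_CUES,):
        raise ValueError(f"expected {N_CUES} validities, got shape {v.shape}")
    if np.any(v <= 0.5) or np.any(v >= 1.0):
        raise ValueError(f"validities must lie strictly in (0.5, 1.0): {v.tolist()}")
    m = np.asarray(cue_matrix, dtype=int)
    if m.shape != (N_CUES, N_OPTIONS):
        raise ValueError(f"cue matrix must be {N_CUES}x{N_OPTIONS}, got {m.shape}")
    if not np.all(np.isin(m, (-1, 1))):
        raise ValueError("cue values must be +1 or -1")
    if np.array_equal(m[:, 0], m[:, 1]):
        raise ValueError("option columns are identical; the task is undefined")

    order = np.argsort(-v, kind="stable")
    v = v[order]
    m = m[order]
    return Task(
        id=id,
        validities=tuple(float(x) for x in v),
        cue_matrix=m,
        dominated=is_dominated(m),
    )


def mirror_task(task: Task, id: str | None = None) -> Task:
    """Swap options A and B (validities unchanged). Involution; preserves the
    dominated flag by symmetry."""
    return make_task(
        task.validities,
        task.cue_matrix[:, ::-1],
        id=task.id if id is None else id,
    )


@dataclass(frozen=True)
class TaskSet:
    """Ordered collection of tasks with no duplicate content."""

    tasks: tuple[Task, ...]

    def __post_init__(self) -> None:
        sigs = [t.signature() for t in self.tasks]
        if len(set(sigs)) != len(sigs):
            raise ValueError("duplicate tasks in TaskSet")
        ids = [t.id for t in self.tasks]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate task ids in TaskSet")

    def __len__(self) -> int:
        return len(self.tasks)

    def __iter__(self) -> Iterator[Task]:
        return iter(self.tasks)

    def __getitem__(self, i: int) -> Task:
        return self.tasks[i]

    @property
    def ids(self) -> list[str]:
        return [t.id for t in self.tasks]

    def by_id(self, task_id: str) -> Task:
        for t in self.tasks:
            if t.id == task_id:
                return t
        raise KeyError(task_id)

    def validity_matrix(self) -> np.ndarray:
        """(n_tasks, 4) validities."""
        return np.array([t.validities for t in self.tasks])

    def cue_array(self) -> np.ndarray:
        """(n_tasks, 4, 2) cue values."""
        return np.stack([t.cue_matrix for t in self.tasks])

    def fingerprint(self) -> tuple:
        """Hashable content key, used to cache network runs per task set."""
        return tuple(t.signature() for t in self.tasks)

    @classmethod
    def from_tasks(cls, tasks: Iterable[Task]) -> "TaskSet":
        return cls(tuple(tasks))


_HEADER = ["id", "v1", "v2", "v3", "v4", "a1", "a2", "a3", "a4", "b1", "b2", "b3", "b4"]


def write_tasks(task_set: TaskSet, path) -> None:
    """Write a task set as comma-separated text, one row per task."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for t in task_set:
            writer.writerow(
                [t.id]
                + [repr(v) for v in t.validities]
                + t.option_a.tolist()
                + t.option_b.tolist()
            )


def read_tasks(path) -> TaskSet:
    """Read a task set written by :func:`write_tasks`.

    Raises
    ------
    ValueError
        Naming the 1-based data row on any malformed row.
    """
    tasks: list[Task] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            return TaskSet(())
        for rownum, row in enumerate(reader, start=1):
            if not row:
                continue
            if len(row) != len(_HEADER):
                raise ValueError(
                    f"row {rownum}: expected {len(_HEADER)} fields, got {len(row)}"
                )
            try:
                validities = [float(x) for x in row[1:5]]
                a = [int(x) for x in row[5:9]]
                b = [int(x) for x in row[9:13]]
                tasks.append(make_task(validities, np.column_stack([a, b]), id=row[0]))
            except ValueError as exc:
                raise ValueError(f"row {rownum}: {exc}") from exc
    return TaskSet(tuple(tasks))


def task_to_json(task: Task, path) -> None:
    with open(path, "w") as fh:
        json.dump(task.to_dict(), fh, indent=2)


def task_from_json(path) -> Task:
    with open(path) as fh:
        return Task.from_dict(json.load(fh))
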