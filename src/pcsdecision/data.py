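"""Trial-level participant data container.

A participant contributes one trial per task: a choice between options A and
B, a decision time in milliseconds, and a confidence rating on the 50-100
slider scale (50 = random, 100 = certain). Trials are stored in presentation
order; alignment with a task set goes through task ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tasks import TaskSet

__all__ = ["ParticipantDataset", "TRIAL_COLUMNS"]

TRIAL_COLUMNS = ["trial_index", "task_id", "choice", "rt_ms", "confidence"]

CONDITIONS = ("intuition", "deliberation")


@dataclass(frozen=True)
class ParticipantDataset:
    """One participant's trial stream.

    ``trials`` has columns trial_index, task_id, choice ("A"/"B"), rt_ms,
    confidence, plus optional analysis columns added downstream:
    ``rt_excluded`` (bool; trial dropped from time analyses) and
    ``lnrt_detrended`` (ln decision time with the participant's linear
    order trend partialed out, participant mean retained).
    """

    participant_id: str
    condition: str
    trials: pd.DataFrame = field(compare=False)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"trials missing columns: {missing}")
        bad = set(self.trials["choice"]) - {"A", "B"}
        if bad:
            raise ValueError(f"choices must be 'A' or 'B', found {sorted(bad)}")
        if (self.trials["rt_ms"] <= 0).any():
            raise ValueError("decision times must be positive")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def is_preprocessed(self) -> bool:
        return "lnrt_detrended" in self.trials.columns

    def with_trials(self, trials: pd.DataFrame) -> "ParticipantDataset":
        return replace(self, trials=trials.reset_index(drop=True))

    def task_indices(self, task_set: TaskSet) -> np.ndarray:
        """Position of each trial's task within ``task_set``."""
        pos = {tid: i for i, tid in enumerate(task_set.ids)}
        try:
            return np.array([pos[t] for t in self.trials["task_id"]], dtype=int)
        except KeyError as exc:
            raise KeyError(f"trial references unknown task id {exc}") from exc

    def choice_sign(self) -> np.ndarray:
        """+1 for choosing A, -1 for B, per trial."""
        return np.where(self.trials["choice"].to_numpy() == "A", 1, -1)

    def rt_keep_mask(self) -> np.ndarray:
        """Trials usable for decision-time analyses."""
        if "rt_excluded" in self.trials.columns:
            return ~self.trials["rt_excluded"].to_numpy(dtype=bool)
        return np.ones(len(self.trials), dtype=bool)

    def detrended_lnrt(self) -> np.ndarray:
        """ln decision times with order effects partialed out.

        Uses the precomputed ``lnrt_detrended`` column when the pipeline's
        preprocessing has run; otherwise detrends on the fly (per-participant
        linear regression of ln RT on trial index over the kept trials,
        residuals plus participant mean). Entries for excluded trials are
        NaN.
        """
        if self.is_preprocessed:
            return self.trials["lnrt_detrended"].to_numpy(dtype=float)
        keep = self.rt_keep_mask()
        lnrt = np.log(self.trials["rt_ms"].to_numpy(dtype=float))
        out = np.full(len(self.trials), np.nan)
        out[keep] = detrend_on_index(
            lnrt[keep], self.trials["trial_index"].to_numpy(dtype=float)[keep]
        )
        return out


def detrend_on_index(y: np.ndarray, index: np.ndarray) -> np.ndarray:
    """Residuals of a linear fit of ``y`` on ``index``, plus mean(y)."""
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 trials to partial out order effects")
    x = np.asarray(index, dtype=float)
    X = np.column_stack([np.ones_like(x), x - x.mean()])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return (y - X @ coef) + y.mean()
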