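"""Synthetic task sets and simulated participants.

The generator emulates the statistical structure the analysis assumes: a
set of 60 randomly generated 4-cue binary-choice tasks (no dominated
options, no duplicates, no naive-Bayes ties) and, per participant, a trial
stream of (choice, decision time in ms, confidence on the 50-100 slider)
produced under a known strategy with strategy-consistent noise.

Two decision-mode conditions are emulated. Relative to intuition, the
deliberation condition shifts ln decision times upward by the log ratio of
the conditions' observed mean times (9241/5583 ms) and scales the choice
error rate down, reproducing the slower-but-more-accurate pattern of
deliberate responding.

Ground-truth strategy labels are returned separately from the trial data
(sidecar), never inside it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ParticipantDataset, TRIAL_COLUMNS
from .network import DEFAULT_CONSTANTS, PCSConstants
from .predictions import StrategyPredictions, predict_strategy
from .strategies import STRATEGIES, naive_bayes
from .tasks import Task, TaskSet, is_dominated, make_task

__all__ = [
    "AgentSpec",
    "StudySpec",
    "generate_task_set",
    "simulate_participant",
    "simulate_study",
    "write_trials",
    "read_trials",
    "DELIBERATION_LNRT_SHIFT",
    "DELIBERATION_ERROR_MULTIPLIER",
]

#: ln(9241 / 5583): log ratio of mean decision times, deliberation vs
#: intuition; applied as an additive shift on the ln-ms scale.
DELIBERATION_LNRT_SHIFT = float(np.log(9241.0 / 5583.0))

#: Deliberate responding is more accurate; the error rate (or its logistic
#: analogue) shrinks by this factor.
DELIBERATION_ERROR_MULTIPLIER = 0.75

#: Mean ln decision time of the intuition condition (exp = 5583 ms).
INTUITION_MEAN_LNRT = float(np.log(5583.0))


@dataclass(frozen=True)
class AgentSpec:
    """Generative description of one simulated participant.

    ``noise`` is the choice error rate epsilon for deterministic strategies
    and the logistic determinism lambda for "PCS_fitted" agents (larger
    lambda = *less* noisy). The time model lives on the ln-ms scale; the
    confidence model on the 50-100 slider scale, clipped at the bounds the
    way a slider censors.
    """

    strategy: str
    condition: str = "intuition"
    noise: float = 0.12
    P: float = 1.7
    mu_time: float = INTUITION_MEAN_LNRT
    beta_time: float = 0.5
    sigma_time: float = 0.35
    mu_conf: float = 75.0
    beta_conf: float = 10.0
    sigma_conf: float = 8.0
    order_drift: float = 0.0  # ln-units per trial, for order-effect testing
    deliberation_lnrt_shift: float = DELIBERATION_LNRT_SHIFT
    deliberation_error_multiplier: float = DELIBERATION_ERROR_MULTIPLIER
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if self.strategy != "PCS_fitted" and self.noise > 0.5:
            raise ValueError("error rate must be <= .5")

    @property
    def effective_error(self) -> float:
        """Condition-adjusted epsilon (deterministic strategies only)."""
        if self.condition == "deliberation":
            return self.noise * self.deliberation_error_multiplier
        return self.noise

    @property
    def effective_lambda(self) -> float:
        """Condition-adjusted lambda (PCS_fitted agents; deliberation is
        less noisy, i.e. a steeper logistic)."""
        if self.condition == "deliberation":
            return self.noise / self.deliberation_error_multiplier
        return self.noise

    @property
    def effective_mu_time(self) -> float:
        if self.condition == "deliberation":
            return self.mu_time + self.deliberation_lnrt_shift
        return self.mu_time


@dataclass(frozen=True)
class StudySpec:
    """Study-level generative design.

    Defaults mirror the reference design: 67 intuition + 61 deliberation
    participants, 60 tasks, and a strategy mixture dominated by the PCS
    variants (.59 combined), with .28 weighted-additive and .13 simpler
    heuristics.
    """

    n_intuition: int = 67
    n_deliberation: int = 61
    n_tasks: int = 60
    validity_range: tuple[float, float] = (0.60, 0.94)
    mixture: dict[str, float] = field(
        default_factory=lambda: {
            "PCS_fitted": 0.30,
            "PCS_fix": 0.29,
            "WADD_c": 0.28,
            "EQW": 0.07,
            "TTB": 0.06,
        }
    )
    agent_template: AgentSpec = field(
        default_factory=lambda: AgentSpec(strategy="PCS_fitted")
    )
    P_intuition: float = 1.70
    P_deliberation: float = 1.97
    lambda_pcs: float = 2.7
    master_seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture must sum to 1, got {total}")
        unknown = set(self.mixture) - set(STRATEGIES)
        if unknown:
            raise ValueError(f"unknown strategies in mixture: {sorted(unknown)}")


def generate_task_set(
    n_tasks: int = 60,
    validity_range: tuple[float, float] = (0.60, 0.94),
    seed: int = 0,
    max_attempts: int = 100_000,
) -> TaskSet:
    """Rejection-sample a task set.

    Validities are drawn uniformly in ``validity_range`` (rounded to two
    decimals, the precision at which they are displayed) and sorted
    descending; cue patterns are uniform over non-identical +1/-1 columns.
    Candidates are rejected if dominated, a duplicate of an accepted task
    (on rounded validities plus cue pattern), or a naive-Bayes tie, so
    performance against the rational benchmark is well defined for every
    task.
    """
    lo, hi = validity_range
    if not (0.5 < lo < hi < 1.0):
        raise ValueError("validity_range must be within (0.5, 1.0)")
    rng = np.random.default_rng(seed)
    tasks: list[Task] = []
    seen: set = set()
    attempts = 0
    while len(tasks) < n_tasks:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"sampling budget exceeded after {max_attempts} attempts"
            )
        v = np.round(rng.uniform(lo, hi, size=4), 2)
        if np.any(v <= 0.5) or np.any(v >= 1.0):
            continue
        m = rng.choice((-1, 1), size=(4, 2))
        if np.array_equal(m[:, 0], m[:, 1]) or is_dominated(m):
            continue
        task = make_task(v, m, id=f"t{len(tasks) + 1:03d}")
        if task.signature() in seen:
            continue
        if naive_bayes(task)[1] == "tie":
            continue
        seen.add(task.signature())
        tasks.append(task)
    return TaskSet(tuple(tasks))


def _agent_predictions(
    spec: AgentSpec, task_set: TaskSet, constants: PCSConstants
) -> StrategyPredictions:
    P = spec.P if spec.strategy == "PCS_fitted" else None
    return predict_strategy(task_set, spec.strategy, P=P, constants=constants)


def simulate_participant(
    spec: AgentSpec,
    task_set: TaskSet,
    participant_id: str = "sim",
    constants: PCSConstants = DEFAULT_CONSTANTS,
) -> ParticipantDataset:
    """Generate one participant's trial stream under a known strategy.

    Choices follow the strategy's prediction, flipped with probability
    epsilon (deterministic strategies) or sampled through the logistic rule
    (PCS_fitted agents); random-prediction trials are fair coin flips.
    ln-RT and confidence are Gaussian in the strategy's contrast weights;
    trial order is randomized per participant, with an optional linear
    drift on ln-RT for order-effect testing.
    """
    rng = np.random.default_rng(spec.seed)
    preds = _agent_predictions(spec, task_set, constants)
    n = len(task_set)
    order = rng.permutation(n)  # order[i] = task index shown at trial i

    sign = preds.choice_sign[order]
    if spec.strategy == "PCS_fitted":
        p_a = 1.0 / (1.0 + np.exp(-spec.effective_lambda
                                  * preds.activation_diff[order]))
        chosen = np.where(rng.random(n) < p_a, 1, -1)
    else:
        eps = spec.effective_error
        flip = rng.random(n) < eps
        chosen = np.where(sign == 0, 0, np.where(flip, -sign, sign))
        coin = rng.choice((1, -1), size=n)
        chosen = np.where(chosen == 0, coin, chosen)

    trial_index = np.arange(n)
    lnrt = (
        spec.effective_mu_time
        + spec.beta_time * preds.time_contrast[order]
        + spec.order_drift * trial_index
        + rng.normal(0.0, spec.sigma_time, size=n)
    )
    conf = np.clip(
        spec.mu_conf
        + spec.beta_conf * preds.confidence_contrast[order]
        + rng.normal(0.0, spec.sigma_conf, size=n),
        50.0,
        100.0,
    )
    trials = pd.DataFrame(
        {
            "trial_index": trial_index,
            "task_id": [task_set.ids[i] for i in order],
            "choice": np.where(chosen == 1, "A", "B"),
            "rt_ms": np.exp(lnrt),
            "confidence": conf,
        }
    )
    return ParticipantDataset(
        participant_id=participant_id, condition=spec.condition, trials=trials
    )


def simulate_study(
    study: StudySpec,
    task_set: TaskSet | None = None,
    constants: PCSConstants = DEFAULT_CONSTANTS,
) -> tuple[TaskSet, list[ParticipantDataset], list[AgentSpec]]:
    """Generate a full two-condition study.

    Per-participant seeds and strategy labels are drawn from the master
    seed, so regeneration is bit-identical. Returns the task set, the
    participants, and the ground-truth agent specs (sidecar; labels are
    never embedded in the trial data).
    """
    rng = np.random.default_rng(study.master_seed)
    if task_set is None:
        task_set = generate_task_set(
            study.n_tasks,
            study.validity_range,
            seed=int(rng.integers(2**31 - 1)),
        )
    names = list(study.mixture)
    probs = np.array([study.mixture[s] for s in names])
    participants: list[ParticipantDataset] = []
    specs: list[AgentSpec] = []
    counter = 0
    for condition, n_cond in (
        ("intuition", study.n_intuition),
        ("deliberation", study.n_deliberation),
    ):
        for _ in range(n_cond):
            counter += 1
            strategy = names[int(rng.choice(len(names), p=probs))]
            P = (
                study.P_intuition
                if condition == "intuition"
                else study.P_deliberation
            )
            noise = (
                study.lambda_pcs
                if strategy == "PCS_fitted"
                else study.agent_template.noise
            )
            spec = replace(
                study.agent_template,
                strategy=strategy,
                condition=condition,
                P=P,
                noise=noise,
                seed=int(rng.integers(2**31 - 1)),
            )
            pid = f"p{counter:03d}"
            participants.append(
                simulate_participant(spec, task_set, participant_id=pid,
                                     constants=constants)
            )
            specs.append(spec)
    return task_set, participants, specs


def write_trials(participants: Sequence[ParticipantDataset], path) -> None:
    """Long-format tabular export: participant, condition, then the trial
    columns."""
    frames = []
    for p in participants:
        df = p.trials[TRIAL_COLUMNS].copy()
        df.insert(0, "condition", p.condition)
        df.insert(0, "participant", p.participant_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trials(path, column_map: dict[str, str] | None = None) -> list[ParticipantDataset]:
    """Read a long-format trial table back into participant datasets.

    ``column_map`` renames external columns onto the expected schema, so
    externally deposited data can be mapped in.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    out = []
    for (pid, cond), grp in df.groupby(["participant", "condition"], sort=False):
        out.append(
            ParticipantDataset(
                participant_id=str(pid),
                condition=str(cond),
                trials=grp[TRIAL_COLUMNS].reset_index(drop=True),
            )
        )
    return out


def write_ground_truth(specs: Sequence[AgentSpec],
                       participants: Sequence[ParticipantDataset], path) -> None:
    """Sidecar JSON with the generating agent specs, keyed by participant."""
    payload = {
        p.participant_id: {
            "strategy": s.strategy,
            "condition": s.condition,
            "noise": s.noise,
            "P": s.P,
            "seed": s.seed,
        }
        for p, s in zip(participants, specs)
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
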