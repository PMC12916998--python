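"""Heuristic strategy predictions and the naive Bayesian benchmark.

Three serial heuristics are formalized alongside the PCS network:

* **TTB** (take-the-best): decide by the most valid discriminating cue;
  confidence is that cue's validity; time is the elementary-information-
  process (EIP) count up to and including that cue.
* **EQW** (equal weights): choose the option with the larger unweighted sum
  of cue values; confidence is the difference of the sums; time is a
  constant EIP count.
* **WADD_c** (weighted additive, chance-corrected): choose by sums of cue
  values weighted by ``v_i - 0.5``; confidence is the score difference;
  time is a constant EIP count.

The rational benchmark is the naive Bayesian solution: posterior odds from
the product of validity likelihood ratios under cue independence and equal
priors. Option A of the printed example tasks is by convention the
Bayes-superior option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tasks import Task

__all__ = [
    "TaskPrediction",
    "ttb_predict",
    "eqw_predict",
    "waddc_predict",
    "eip_time",
    "naive_bayes",
    "HEURISTICS",
    "STRATEGIES",
]

#: Deterministic serial heuristics.
HEURISTICS = ("TTB", "EQW", "WADD_c")

#: Full strategy set considered in classification.
STRATEGIES = ("TTB", "EQW", "WADD_c", "PCS_fix", "PCS_fitted")

#: EIP counting scheme: per-cue costs for the sequential TTB scan and the
#: fixed totals for the exhaustive strategies (reads + arithmetic +
#: comparison). Any strictly monotone recount yields the same contrast
#: vectors up to an affine map, so classification is insensitive to the
#: exact bookkeeping.
_TTB_EIP_PER_CUE = 3  # 2 reads + 1 comparison
_EQW_EIP = 15  # 8 reads + 6 additions + 1 comparison
_WADDC_EIP = 23  # 8 reads + 8 multiplications + 6 additions + 1 comparison


@dataclass(frozen=True)
class TaskPrediction:
    """One strategy's prediction for one task.

    ``choice`` is "A", "B" or "random" (the strategy does not discriminate);
    ``confidence_raw`` and ``time_raw`` are on the strategy's native scales
    and are turned into contrast weights at the task-set level.
    """

    task_id: str
    choice: str
    confidence_raw: float
    time_raw: float
    converged: bool = True
    activation_diff: float = 0.0


def ttb_predict(task: Task) -> TaskPrediction:
    """Lexicographic rule: scan cues in validity order, first discriminating
    cue decides. No discriminating cue -> random choice at chance
    confidence (.5)."""
    a, b = task.option_a, task.option_b
    for i in range(len(task.validities)):
        if a[i] != b[i]:
            choice = "A" if a[i] > b[i] else "B"
            return TaskPrediction(
                task_id=task.id,
                choice=choice,
                confidence_raw=task.validities[i],
                time_raw=eip_time("TTB", cues_examined=i + 1),
            )
    return TaskPrediction(
        task_id=task.id,
        choice="random",
        confidence_raw=0.5,
        time_raw=eip_time("TTB", cues_examined=len(task.validities)),
    )


def eqw_predict(task: Task) -> TaskPrediction:
    """Unweighted sums of +1/-1 cue values; ties are random with
    confidence 0."""
    sum_a = int(task.option_a.sum())
    sum_b = int(task.option_b.sum())
    diff = sum_a - sum_b
    choice = "A" if diff > 0 else "B" if diff < 0 else "random"
    return TaskPrediction(
        task_id=task.id,
        choice=choice,
        confidence_raw=float(abs(diff)),
        time_raw=eip_time("EQW"),
    )


def waddc_predict(task: Task) -> TaskPrediction:
    """Chance-corrected weighted sums: score(o) = sum_i (v_i - .5) * cue."""
    w = np.asarray(task.validities) - 0.5
    score_a = float(w @ task.option_a)
    score_b = float(w @ task.option_b)
    diff = score_a - score_b
    choice = "A" if diff > 0 else "B" if diff < 0 else "random"
    return TaskPrediction(
        task_id=task.id,
        choice=choice,
        confidence_raw=abs(diff),
        time_raw=eip_time("WADD_c"),
    )


def eip_time(strategy: str, cues_examined: int = 4) -> float:
    """Elementary-information-process count for a serial strategy.

    TTB pays per cue examined and stops at the first discrimination; EQW and
    WADD_c always process all cues, so their counts are task constants.
    """
    if strategy == "TTB":
        if cues_examined < 1:
            raise ValueError("cues_examined must be >= 1")
        return float(_TTB_EIP_PER_CUE * cues_examined)
    if strategy == "EQW":
        return float(_EQW_EIP)
    if strategy == "WADD_c":
        return float(_WADDC_EIP)
    raise ValueError(f"unknown serial strategy: {strategy!r}")


def naive_bayes(task: Task) -> tuple[float, str]:
    """Naive Bayesian solution under cue independence and equal priors.

    The posterior log-odds of A over B accumulate ``ln(v/(1-v))`` for every
    cue favoring A and ``-ln(v/(1-v))`` for every cue favoring B;
    non-discriminating cues contribute nothing.

    Returns
    -------
    (posterior_A, superior_option)
        ``posterior_A`` is the posterior probability that A is the better
        option; ``superior_option`` is "A", "B" or "tie".
    """
    v = np.asarray(task.validities)
    d = (task.option_a - task.option_b) // 2  # +1 favors A, -1 favors B, 0 ties
    log_odds = float(np.sum(d * np.log(v / (1.0 - v))))
    posterior_a = float(1.0 / (1.0 + np.exp(-log_odds)))
    if log_odds > 0:
        superior = "A"
    elif log_odds < 0:
        superior = "B"
    else:
        superior = "tie"
    return posterior_a, superior


def predict_heuristic(strategy: str, task: Task) -> TaskPrediction:
    """Dispatch one of the three serial heuristics."""
    if strategy == "TTB":
        return ttb_predict(task)
    if strategy == "EQW":
        return eqw_predict(task)
    if strategy == "WADD_c":
        return waddc_predict(task)
    raise ValueError(f"unknown heuristic: {strategy!r}")
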