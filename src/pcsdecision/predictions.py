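"""Task-set-level strategy prediction tables and the PCS grid cache.

Raw time and confidence predictions live on strategy-specific scales (EIP
counts, iteration counts, validity sums). For likelihood fitting they are
turned into *contrast weights* — centered to sum zero and scaled to unit
range — which makes classification invariant to affine rescaling of any
strategy's raw predictions.

Network runs are deterministic functions of (task set, P, constants), so the
grid-search fit caches them: one batched run per P value serves every
participant fitted on the same task set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .network import DEFAULT_CONSTANTS, P_FIX, PCSConstants
from .strategies import predict_heuristic, HEURISTICS
from .tasks import TaskSet

__all__ = [
    "contrastify",
    "StrategyPredictions",
    "predict_strategy",
    "predict_all",
    "pcs_batch_run",
    "pcs_grid_tables",
    "GridTables",
    "predictions_frame",
]


def contrastify(raw: np.ndarray) -> np.ndarray:
    """Transform raw predictions into contrast weights.

    ``(x - mean(x)) / (max(x) - min(x))``: the result sums to zero and has
    range one. A constant input (e.g. the fixed EIP counts of EQW and
    WADD_c) maps to the all-zero vector — the strategy then predicts no
    variation on that measure.
    """
    x = np.asarray(raw, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 raw predictions")
    rng = x.max() - x.min()
    if rng == 0.0:
        return np.zeros_like(x)
    return (x - x.mean()) / rng


@dataclass(frozen=True)
class StrategyPredictions:
    """One strategy's predictions over an ordered task set.

    ``choices`` holds "A"/"B"/"random" per task; ``activation_diff`` is the
    signed option-activation difference (zero for non-PCS strategies);
    contrast vectors are task-set-level transforms of the raw predictions.
    """

    strategy: str
    task_ids: tuple[str, ...]
    choices: np.ndarray
    confidence_raw: np.ndarray
    time_raw: np.ndarray
    confidence_contrast: np.ndarray
    time_contrast: np.ndarray
    activation_diff: np.ndarray
    converged: np.ndarray

    def __len__(self) -> int:
        return len(self.task_ids)

    @property
    def choice_sign(self) -> np.ndarray:
        """+1 for predicted A, -1 for predicted B, 0 for random."""
        return np.where(
            self.choices == "A", 1, np.where(self.choices == "B", -1, 0)
        )


def _finish(strategy, task_ids, choices, conf, time, delta, conv) -> StrategyPredictions:
    return StrategyPredictions(
        strategy=strategy,
        task_ids=tuple(task_ids),
        choices=np.asarray(choices, dtype=object),
        confidence_raw=np.asarray(conf, dtype=float),
        time_raw=np.asarray(time, dtype=float),
        confidence_contrast=contrastify(conf),
        time_contrast=contrastify(time),
        activation_diff=np.asarray(delta, dtype=float),
        converged=np.asarray(conv, dtype=bool),
    )


def pcs_batch_run(
    task_set: TaskSet, P: float, constants: PCSConstants = DEFAULT_CONSTANTS
):
    """Run the PCS network for every task of a set in one vectorized sweep.

    Tasks are independent, so the batch iterates all of them synchronously
    and freezes each task's state at its own convergence point; results are
    identical to running :func:`pcsdecision.network.run_to_convergence`
    task by task.

    Returns
    -------
    (a_options, a_cues, iterations, converged)
        Arrays of shape (n, 2), (n, 4), (n,), (n,).
    """
    c = constants
    v = task_set.validity_matrix()  # (n, 4)
    cue = task_set.cue_array().astype(float)  # (n, 4, 2)
    n = len(task_set)
    w_v = (v - 0.5) ** P
    w_co = cue * c.cue_option_weight

    cues = np.zeros((n, 4))
    opts = np.zeros((n, 2))
    iters = np.full(n, c.max_iterations, dtype=int)
    conv = np.zeros(n, dtype=bool)
    streak = np.zeros(n, dtype=int)
    active = np.ones(n, dtype=bool)

    for it in range(1, c.max_iterations + 1):
        # elementwise (not a fused dot) so mirror symmetry stays bit-exact
        cue_in = w_v + (
            w_co[:, :, 0] * opts[:, :1] + w_co[:, :, 1] * opts[:, 1:]
        )
        opt_in = np.einsum("tio,ti->to", w_co, cues) + c.option_inhibition * opts[:, ::-1]
        new_cues = _step(cues, cue_in, c)
        new_opts = _step(opts, opt_in, c)
        if not (np.all(np.isfinite(new_cues)) and np.all(np.isfinite(new_opts))):
            raise FloatingPointError("non-finite activation; check network constants")
        # frozen tasks keep their settled state
        new_cues[~active] = cues[~active]
        new_opts[~active] = opts[~active]
        delta = np.maximum(
            np.abs(new_cues - cues).max(axis=1), np.abs(new_opts - opts).max(axis=1)
        )
        cues, opts = new_cues, new_opts
        stable = delta < c.stability_threshold
        streak = np.where(stable & active, streak + 1, 0)
        done = active & (streak >= c.stability_window)
        if np.any(done):
            first = it - c.stability_window + 1 if (
                c.iteration_convention == "first_stable"
            ) else it
            iters[done] = first
            conv[done] = True
            active &= ~done
        if not np.any(active):
            break
    return opts, cues, iters, conv


def _step(a, inp, c):
    up = a * (1.0 - c.decay) + inp * (c.a_max - a)
    down = a * (1.0 - c.decay) + inp * (a - c.a_min)
    return np.clip(np.where(inp >= 0.0, up, down), c.a_min, c.a_max)


def _pcs_predictions(
    task_set: TaskSet, strategy: str, P: float, constants: PCSConstants
) -> StrategyPredictions:
    opts, _cues, iters, conv = pcs_batch_run(task_set, P, constants)
    delta = opts[:, 0] - opts[:, 1]
    choices = np.where(delta > 0, "A", np.where(delta < 0, "B", "random"))
    return _finish(
        strategy, task_set.ids, choices.astype(object),
        np.abs(delta), iters.astype(float), delta, conv,
    )


_PRED_CACHE: dict[tuple, StrategyPredictions] = {}


def predict_strategy(
    task_set: TaskSet,
    strategy: str,
    P: float | None = None,
    constants: PCSConstants = DEFAULT_CONSTANTS,
) -> StrategyPredictions:
    """Predictions of one strategy over a task set.

    For "PCS_fix" the sensitivity parameter is fixed at 1.9; for
    "PCS_fitted" a ``P`` must be supplied (it comes from the grid fit).
    Results are deterministic in (task set, strategy, P, constants) and
    cached on that key.
    """
    key = (task_set.fingerprint(), strategy,
           None if P is None else round(float(P), 10), constants)
    hit = _PRED_CACHE.get(key)
    if hit is not None:
        return hit
    out = _predict_strategy_uncached(task_set, strategy, P, constants)
    _PRED_CACHE[key] = out
    return out


def _predict_strategy_uncached(
    task_set: TaskSet,
    strategy: str,
    P: float | None,
    constants: PCSConstants,
) -> StrategyPredictions:
    if strategy in HEURISTICS:
        preds = [predict_heuristic(strategy, t) for t in task_set]
        return _finish(
            strategy,
            task_set.ids,
            [p.choice for p in preds],
            [p.confidence_raw for p in preds],
            [p.time_raw for p in preds],
            np.zeros(len(task_set)),
            np.ones(len(task_set), dtype=bool),
        )
    if strategy == "PCS_fix":
        return _pcs_predictions(task_set, strategy, P_FIX, constants)
    if strategy == "PCS_fitted":
        if P is None:
            raise ValueError("PCS_fitted predictions require a P value")
        return _pcs_predictions(task_set, strategy, float(P), constants)
    raise ValueError(f"unknown strategy: {strategy!r}")


def predict_all(
    task_set: TaskSet,
    strategies=("TTB", "EQW", "WADD_c", "PCS_fix"),
    constants: PCSConstants = DEFAULT_CONSTANTS,
    fitted_P: float | None = None,
) -> dict[str, StrategyPredictions]:
    out = {}
    for s in strategies:
        P = fitted_P if s == "PCS_fitted" else None
        out[s] = predict_strategy(task_set, s, P=P, constants=constants)
    return out


@dataclass(frozen=True)
class GridTables:
    """Cached PCS predictions over a P grid for one task set.

    Row ``i`` of every array corresponds to ``p_grid[i]``; columns follow
    the task-set order.
    """

    p_grid: np.ndarray  # (nP,)
    delta: np.ndarray  # (nP, nT) signed a_A - a_B
    iterations: np.ndarray  # (nP, nT)
    time_contrast: np.ndarray  # (nP, nT)
    confidence_contrast: np.ndarray  # (nP, nT)
    converged: np.ndarray  # (nP, nT) bool

    def at(self, i: int, task_set: TaskSet, strategy: str = "PCS_fitted") -> StrategyPredictions:
        """Materialize the prediction table for grid row ``i``."""
        d = self.delta[i]
        choices = np.where(d > 0, "A", np.where(d < 0, "B", "random")).astype(object)
        return StrategyPredictions(
            strategy=strategy,
            task_ids=tuple(task_set.ids),
            choices=choices,
            confidence_raw=np.abs(d),
            time_raw=self.iterations[i].astype(float),
            confidence_contrast=self.confidence_contrast[i],
            time_contrast=self.time_contrast[i],
            activation_diff=d,
            converged=self.converged[i],
        )


_GRID_CACHE: dict[tuple, GridTables] = {}


def pcs_grid_tables(
    task_set: TaskSet,
    p_grid: np.ndarray,
    constants: PCSConstants = DEFAULT_CONSTANTS,
) -> GridTables:
    """Network predictions for every P of a grid, cached per task set.

    The network is λ-free, so the grid fit over (P, λ) needs only one run
    per P; participants sharing a task set share the cache.
    """
    p_grid = np.asarray(p_grid, dtype=float)
    key = (task_set.fingerprint(), constants, tuple(np.round(p_grid, 10)))
    hit = _GRID_CACHE.get(key)
    if hit is not None:
        return hit
    nP, nT = len(p_grid), len(task_set)
    delta = np.empty((nP, nT))
    iters = np.empty((nP, nT))
    tcon = np.empty((nP, nT))
    ccon = np.empty((nP, nT))
    conv = np.empty((nP, nT), dtype=bool)
    for i, P in enumerate(p_grid):
        opts, _cues, it, cv = pcs_batch_run(task_set, float(P), constants)
        d = opts[:, 0] - opts[:, 1]
        delta[i] = d
        iters[i] = it
        tcon[i] = contrastify(it.astype(float))
        ccon[i] = contrastify(np.abs(d))
        conv[i] = cv
    tables = GridTables(p_grid, delta, iters, tcon, ccon, conv)
    _GRID_CACHE[key] = tables
    return tables


def predictions_frame(tables: Mapping[str, StrategyPredictions]) -> pd.DataFrame:
    """Long-format export: task id x strategy x (choice, confidence, time,
    contrasts)."""
    rows = []
    for strategy, p in tables.items():
        for j, tid in enumerate(p.task_ids):
            rows.append(
                {
                    "task_id": tid,
                    "strategy": strategy,
                    "choice": p.choices[j],
                    "confidence_raw": p.confidence_raw[j],
                    "time_raw": p.time_raw[j],
                    "confidence_contrast": p.confidence_contrast[j],
                    "time_contrast": p.time_contrast[j],
                }
            )
    return pd.DataFrame(rows)
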