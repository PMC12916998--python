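"""Parallel constraint satisfaction (PCS) network for binary multi-cue choice.

The network has one driver node (activation clamped at 1), four cue nodes and
two option nodes. The driver feeds each cue node through a weight
``(v_i - 0.5)**P`` — the cue validity corrected for the .5 chance level of a
binary choice and raised to the sensitivity parameter ``P``. Cue-option links
are weak and excitatory or inhibitory according to the cue value (+1/-1);
the two option nodes inhibit each other. All links are bidirectional with
symmetric weights.

Activation spreads by synchronous interactive-activation updating until the
network settles into a stable, maximally coherent state. The settled state
yields the model's three behavioral predictions: the more activated option
node is the predicted choice, the absolute activation difference between the
option nodes is the predicted confidence, and the number of iterations to
convergence is the predicted decision time.

``P`` controls how sharply validity differences are weighted: ``P < 1``
compresses them (more compensatory integration), ``P > 1`` amplifies them
(more non-compensatory), ``P = 1`` weights chance-corrected validities
linearly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .tasks import Task

__all__ = [
    "PCSConstants",
    "PCSParams",
    "NetworkWeights",
    "NetworkResult",
    "build_network",
    "run_to_convergence",
    "pcs_predict",
    "choice_probability",
    "DEFAULT_CONSTANTS",
    "P_FIX",
]

#: Sensitivity parameter of the fixed-parameter model variant.
P_FIX = 1.9


@dataclass(frozen=True)
class PCSConstants:
    """Fixed network constants of the interactive-activation dynamics.

    Defaults are the published values of the model family this network
    belongs to; every one of them is overridable.

    Attributes
    ----------
    decay : float
        Proportional decay of activation per iteration, in (0, 1).
    a_min, a_max : float
        Activation floor and ceiling; a_min < 0 < a_max.
    cue_option_weight : float
        Magnitude of the cue-option links; the sign comes from the cue value.
    option_inhibition : float
        Mutual inhibition between the two option nodes (< 0).
    stability_threshold : float
        Maximal absolute per-node activation change that still counts as
        stable.
    stability_window : int
        Number of consecutive stable iterations required for convergence.
    max_iterations : int
        Hard iteration cap; exceeding it flags non-convergence.
    iteration_convention : {"first_stable", "window_end"}
        Whether the reported iteration count is the first iteration of the
        stable window or the iteration that completed it.
    """

    decay: float = 0.05
    a_min: float = -1.0
    a_max: float = 1.0
    cue_option_weight: float = 0.01
    option_inhibition: float = -0.2
    stability_threshold: float = 1e-6
    stability_window: int = 10
    max_iterations: int = 3000
    iteration_convention: Literal["first_stable", "window_end"] = "first_stable"

    def __post_init__(self) -> None:
        if not (0.0 < self.decay < 1.0):
            raise ValueError("decay must lie in (0, 1)")
        if not (self.a_min < 0.0 < self.a_max):
            raise ValueError("need a_min < 0 < a_max")
        if self.option_inhibition >= 0:
            raise ValueError("option_inhibition must be negative")
        if self.max_iterations < self.stability_window:
            raise ValueError("max_iterations must be >= stability_window")


DEFAULT_CONSTANTS = PCSConstants()


@dataclass(frozen=True)
class PCSParams:
    """Free person parameters of the PCS model.

    ``P`` is the sensitivity exponent on chance-corrected validities;
    ``lambda_`` the determinism of the logistic choice rule (used only when
    mapping activation differences to choice probabilities, not in the
    network dynamics).
    """

    P: float = P_FIX
    lambda_: float = 0.0
    constants: PCSConstants = field(default_factory=PCSConstants)

    def __post_init__(self) -> None:
        if self.P < 0:
            raise ValueError("P must be >= 0")
        if self.lambda_ < 0:
            raise ValueError("lambda must be >= 0")


@dataclass(frozen=True)
class NetworkWeights:
    """Symmetric connection weights of one task's network.

    w_v : (4,) driver->cue weights, (v_i - .5)**P, all >= 0.
    w_co : (4, 2) cue->option weights, sign given by the cue value.
    w_oo : option<->option inhibition, < 0.
    """

    w_v: np.ndarray
    w_co: np.ndarray
    w_oo: float


@dataclass(frozen=True)
class NetworkResult:
    """Settled state of one network run."""

    a_options: np.ndarray  # (2,) final option activations (A, B)
    a_cues: np.ndarray  # (4,) final cue activations
    iterations: int
    converged: bool


def build_network(
    task: Task, P: float, constants: PCSConstants = DEFAULT_CONSTANTS
) -> NetworkWeights:
    """Construct the weight structure for one task.

    Driver->cue weights are ``(v_i - 0.5) ** P``; cue->option weights carry
    the cue-value sign at magnitude ``constants.cue_option_weight``; the
    option nodes share the inhibitory weight ``constants.option_inhibition``.
    """
    if P < 0:
        raise ValueError("P must be >= 0")
    v = np.asarray(task.validities, dtype=float)
    w_v = (v - 0.5) ** P
    w_co = task.cue_matrix * constants.cue_option_weight
    return NetworkWeights(w_v=w_v, w_co=np.asarray(w_co, dtype=float),
                          w_oo=constants.option_inhibition)


def run_to_convergence(
    weights: NetworkWeights, constants: PCSConstants = DEFAULT_CONSTANTS
) -> NetworkResult:
    """Iterate the synchronous interactive-activation update to stability.

    The driver is clamped at 1; cue and option nodes start at 0. Each
    iteration, every non-driver node receives input = the weighted sum of
    its neighbours' activations, and moves by

        a <- a * (1 - decay) + input * (a_max - a)   if input >= 0
        a <- a * (1 - decay) + input * (a - a_min)   if input <  0

    then is clipped into [a_min, a_max] (the raw step can overshoot the
    ceiling by at most the input magnitude when weights are large, e.g. at
    P = 0). The run stops once the largest per-node change stays below
    ``stability_threshold`` for ``stability_window`` consecutive iterations,
    or at ``max_iterations`` with ``converged=False``.
    """
    c = constants
    cues = np.zeros(4)
    opts = np.zeros(2)
    streak = 0
    for it in range(1, c.max_iterations + 1):
        # symmetric links: cues see driver + options, options see cues + rival;
        # the elementwise form keeps mirror symmetry bit-exact (a 2-term BLAS
        # dot may fuse operations asymmetrically)
        cue_in = weights.w_v + (
            weights.w_co[:, 0] * opts[0] + weights.w_co[:, 1] * opts[1]
        )
        opt_in = weights.w_co.T @ cues + weights.w_oo * opts[::-1]
        new_cues = _step(cues, cue_in, c)
        new_opts = _step(opts, opt_in, c)
        if not (np.all(np.isfinite(new_cues)) and np.all(np.isfinite(new_opts))):
            raise FloatingPointError(
                "non-finite activation; check the network constants"
            )
        delta = max(
            np.max(np.abs(new_cues - cues)), np.max(np.abs(new_opts - opts))
        )
        cues, opts = new_cues, new_opts
        if delta < c.stability_threshold:
            streak += 1
            if streak >= c.stability_window:
                n = it - c.stability_window + 1 if (
                    c.iteration_convention == "first_stable"
                ) else it
                return NetworkResult(opts, cues, n, True)
        else:
            streak = 0
    return NetworkResult(opts, cues, c.max_iterations, False)


def _step(a: np.ndarray, inp: np.ndarray, c: PCSConstants) -> np.ndarray:
    up = a * (1.0 - c.decay) + inp * (c.a_max - a)
    down = a * (1.0 - c.decay) + inp * (a - c.a_min)
    return np.clip(np.where(inp >= 0.0, up, down), c.a_min, c.a_max)


def choice_probability(activation_diff: float, lambda_: float) -> float:
    """Logistic probability of choosing the preferred option.

    ``p = 1 / (1 + exp(-lambda * diff))`` for a non-negative activation
    difference (preferred minus non-preferred); lies in [0.5, 1).
    """
    if activation_diff < 0:
        raise ValueError("activation_diff must be >= 0 (preferred minus other)")
    if lambda_ < 0:
        raise ValueError("lambda must be >= 0")
    return float(1.0 / (1.0 + np.exp(-lambda_ * activation_diff)))


def pcs_predict(task: Task, params: PCSParams | None = None):
    """Run the network for one task and derive the prediction triple.

    Returns a :class:`pcsdecision.strategies.TaskPrediction` with
    choice = more activated option ("random" on an exact tie),
    confidence_raw = |a_A - a_B|, time_raw = iterations to convergence.
    Non-convergence is surfaced via ``converged=False`` on the result.
    """
    from .strategies import TaskPrediction  # local import to avoid cycle

    if params is None:
        params = PCSParams()
    weights = build_network(task, params.P, params.constants)
    res = run_to_convergence(weights, params.constants)
    diff = float(res.a_options[0] - res.a_options[1])
    if diff > 0:
        choice = "A"
    elif diff < 0:
        choice = "B"
    else:
        choice = "random"
    return TaskPrediction(
        task_id=task.id,
        choice=choice,
        confidence_raw=abs(diff),
        time_raw=float(res.iterations),
        converged=res.converged,
        activation_diff=diff,
    )
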