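"""Multiple-measure maximum-likelihood (MM-ML) strategy classification.

Each candidate strategy predicts, per task, a choice, a decision-time
ordering and a confidence ordering. The MM-ML method scores a participant's
full data vector — choices, ln decision times and confidence ratings —
under every strategy and assigns the participant to the strategy with the
smallest BIC.

Likelihood structure per strategy:

* choices — Bernoulli. Deterministic strategies (TTB, EQW, WADD_c, PCS_fix)
  apply a constant error rate ``epsilon`` in [0, .5]; trials where the
  strategy predicts a random choice contribute probability .5. The fitted
  PCS variant instead maps the option-activation difference through a
  logistic with determinism parameter ``lambda``.
* decision times — Gaussian on preprocessed ln-RT with mean
  ``mu_T + beta_T * time_contrast`` (``beta_T >= 0``).
* confidence — Gaussian with mean ``mu_C + beta_C * confidence_contrast``
  (``beta_C >= 0``).

The non-negativity constraints on the slopes encode the directional logic
of the method: a strategy may not gain likelihood from predicting the
*reverse* of the observed time or confidence ordering. The contrast
transform makes the fit invariant to affine rescalings of raw predictions.

PCS parameters are fitted by exhaustive grid search over P and lambda
(default [0, 5] in steps of 0.1); network runs are cached per (task set, P)
because the network is lambda-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data import ParticipantDataset
from .network import DEFAULT_CONSTANTS, PCSConstants
from .predictions import (
    GridTables,
    StrategyPredictions,
    contrastify,
    pcs_grid_tables,
    predict_strategy,
)
from .strategies import HEURISTICS, STRATEGIES
from .tasks import TaskSet

__all__ = [
    "MMMLConfig",
    "GaussianModel",
    "MMMLFit",
    "ClassificationResult",
    "MisfitTest",
    "CrossValResult",
    "bic",
    "contrastify",
    "fit_strategy",
    "strategy_loglik",
    "grid_fit_pcs",
    "classify",
    "saturated_misfit_test",
    "crossval_classify",
]

MEASURES = ("choice", "time", "confidence")


@dataclass(frozen=True)
class MMMLConfig:
    """Conventions of the MM-ML fit.

    ``measures`` selects which data streams enter the likelihood (the full
    method uses all three; choice-only classification is available for
    comparison). ``k_override`` replaces the default parameter counts.
    ``sigma_floor`` bounds the Gaussian scale away from zero so noise-free
    data keeps a finite likelihood.
    """

    measures: tuple[str, ...] = MEASURES
    p_min: float = 0.0
    p_max: float = 5.0
    p_step: float = 0.1
    lambda_min: float = 0.0
    lambda_max: float = 5.0
    lambda_step: float = 0.1
    sigma_floor: float = 1e-6
    epsilon_floor: float = 1e-6
    misfit_alpha: float = 0.05
    k_override: Mapping[str, int] | None = None
    constants: PCSConstants = field(default_factory=PCSConstants)

    def __post_init__(self) -> None:
        bad = set(self.measures) - set(MEASURES)
        if bad:
            raise ValueError(f"unknown measures: {sorted(bad)}")
        if not (0.0 <= self.p_min <= self.p_max <= 5.0):
            raise ValueError("P grid bounds must satisfy 0 <= p_min <= p_max <= 5")

    @property
    def p_grid(self) -> np.ndarray:
        return _grid(self.p_min, self.p_max, self.p_step)

    @property
    def lambda_grid(self) -> np.ndarray:
        return _grid(self.lambda_min, self.lambda_max, self.lambda_step)

    def k_for(self, strategy: str) -> int:
        """Free-parameter count entering the BIC penalty.

        Defaults: 1 (epsilon) for deterministic strategies and 3 for
        PCS_fitted on the choice side, plus 3 (mu, beta, sigma) per Gaussian
        measure included — i.e. 7 vs 9 under the full three-measure method.
        """
        if self.k_override is not None and strategy in self.k_override:
            return int(self.k_override[strategy])
        n_gauss = sum(m in self.measures for m in ("time", "confidence"))
        base = 3 if strategy == "PCS_fitted" else 1
        return base + 3 * n_gauss


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step)) + 1
    return np.round(lo + step * np.arange(n), 10)


DEFAULT_CONFIG = MMMLConfig()


def bic(loglik: float, k: int, n: int) -> float:
    """Bayesian information criterion: ``-2 logL + k ln(n)``."""
    return -2.0 * loglik + k * np.log(n)


@dataclass(frozen=True)
class GaussianModel:
    """Intercept-plus-contrast Gaussian for one measure."""

    mu: float
    beta: float
    sigma: float

    def loglik(self, y: np.ndarray, x: np.ndarray) -> float:
        resid = y - self.mu - self.beta * x
        return float(
            -0.5 * len(y) * np.log(2.0 * np.pi * self.sigma**2)
            - np.sum(resid**2) / (2.0 * self.sigma**2)
        )


@dataclass(frozen=True)
class MMMLFit:
    """Fitted MM-ML model of one strategy for one participant."""

    strategy: str
    epsilon: float | None
    lambda_: float | None
    P: float | None
    time_model: GaussianModel | None
    conf_model: GaussianModel | None
    ll_choice: float
    ll_time: float
    ll_conf: float
    k: int
    n: int

    @property
    def ll_total(self) -> float:
        return self.ll_choice + self.ll_time + self.ll_conf

    @property
    def bic(self) -> float:
        return bic(self.ll_total, self.k, self.n)


@dataclass(frozen=True)
class MisfitTest:
    """Likelihood-ratio check of the winner's choice model against a
    saturated model with one free choice probability per cue pattern."""

    g2: float
    df: int
    p_value: float
    misfit: bool


@dataclass(frozen=True)
class ClassificationResult:
    participant_id: str
    fits: dict[str, MMMLFit]
    winner: str
    fitted_P: float | None
    fitted_lambda: float | None
    misfit: MisfitTest | None = None

    @property
    def bic_table(self) -> dict[str, float]:
        return {s: f.bic for s, f in self.fits.items()}


@dataclass(frozen=True)
class CrossValResult:
    participant_id: str
    heldout_loglik: dict[str, float]
    winner: str
    fold_tasks: tuple[tuple[str, ...], ...]
    fitted_P_per_fold: tuple[float, ...]


# ---------------------------------------------------------------------------
# alignment helpers


def _aligned(participant: ParticipantDataset, task_set: TaskSet) -> dict:
    idx = participant.task_indices(task_set)
    keep = participant.rt_keep_mask()
    lnrt = participant.detrended_lnrt()
    keep = keep & np.isfinite(lnrt)
    return {
        "idx": idx,
        "sign": participant.choice_sign(),
        "lnrt": lnrt,
        "rt_keep": keep,
        "conf": participant.trials["confidence"].to_numpy(dtype=float),
    }


def _n_obs(al: dict, measures: Sequence[str]) -> int:
    n = 0
    if "choice" in measures:
        n += len(al["sign"])
    if "time" in measures:
        n += int(al["rt_keep"].sum())
    if "confidence" in measures:
        n += len(al["conf"])
    return n


# ---------------------------------------------------------------------------
# per-measure likelihood pieces


def _xlogy(n: float, p: float) -> float:
    return 0.0 if n == 0 else float(n * np.log(p))


def _choice_ll_deterministic(
    pred_sign: np.ndarray, obs_sign: np.ndarray, epsilon: float
) -> float:
    rand = pred_sign == 0
    match = (pred_sign == obs_sign) & ~rand
    mismatch = ~match & ~rand
    return (
        _xlogy(int(rand.sum()), 0.5)
        + _xlogy(int(match.sum()), 1.0 - epsilon)
        + _xlogy(int(mismatch.sum()), epsilon)
    )


def _fit_epsilon(pred_sign: np.ndarray, obs_sign: np.ndarray) -> float:
    scored = pred_sign != 0
    n = int(scored.sum())
    if n == 0:
        return 0.0
    errors = int(((pred_sign != obs_sign) & scored).sum())
    return min(errors / n, 0.5)


def _choice_ll_logistic(
    delta: np.ndarray, obs_sign: np.ndarray, lambda_: float
) -> float:
    # ln sigma(lambda * delta * sign); delta = a_A - a_B, sign = +1 for A
    z = lambda_ * delta * obs_sign
    return float(-np.logaddexp(0.0, -z).sum())


def _fit_gaussian(y: np.ndarray, x: np.ndarray, sigma_floor: float) -> GaussianModel:
    """Least squares with the slope clamped at zero (refit intercept-only),
    ML sigma (divide by n), floored."""
    if len(y) < 3:
        raise ValueError("need at least 3 usable trials per measure")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx > 0:
        beta = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    else:
        beta = 0.0
    beta = max(beta, 0.0)
    mu = float(y.mean() - beta * x.mean())
    resid = y - mu - beta * x
    sigma = float(max(np.sqrt(np.mean(resid**2)), sigma_floor))
    return GaussianModel(mu=mu, beta=beta, sigma=sigma)


# ---------------------------------------------------------------------------
# fitting


def fit_strategy(
    participant: ParticipantDataset,
    task_set: TaskSet,
    strategy: str,
    config: MMMLConfig = DEFAULT_CONFIG,
    predictions: StrategyPredictions | None = None,
) -> MMMLFit:
    """Maximum-likelihood MM-ML fit of one strategy.

    For "PCS_fitted" this dispatches to :func:`grid_fit_pcs`; all other
    strategies have closed-form estimates (error proportion for epsilon,
    least squares for the Gaussian parts).
    """
    if strategy == "PCS_fitted":
        return grid_fit_pcs(participant, task_set, config)[2]
    if predictions is None:
        predictions = predict_strategy(task_set, strategy, constants=config.constants)
    al = _aligned(participant, task_set)
    pred_sign = predictions.choice_sign[al["idx"]]

    epsilon = _fit_epsilon(pred_sign, al["sign"])
    ll_choice = (
        _choice_ll_deterministic(pred_sign, al["sign"], epsilon)
        if "choice" in config.measures
        else 0.0
    )
    time_model, ll_time = _fit_measure(
        al["lnrt"][al["rt_keep"]],
        predictions.time_contrast[al["idx"]][al["rt_keep"]],
        "time" in config.measures,
        config.sigma_floor,
    )
    conf_model, ll_conf = _fit_measure(
        al["conf"],
        predictions.confidence_contrast[al["idx"]],
        "confidence" in config.measures,
        config.sigma_floor,
    )
    return MMMLFit(
        strategy=strategy,
        epsilon=epsilon,
        lambda_=None,
        P=predictions_P(predictions),
        time_model=time_model,
        conf_model=conf_model,
        ll_choice=ll_choice,
        ll_time=ll_time,
        ll_conf=ll_conf,
        k=config.k_for(strategy),
        n=_n_obs(al, config.measures),
    )


def predictions_P(predictions: StrategyPredictions) -> float | None:
    return 1.9 if predictions.strategy == "PCS_fix" else None


def _fit_measure(y, x, enabled: bool, sigma_floor: float):
    if not enabled:
        return None, 0.0
    model = _fit_gaussian(np.asarray(y, float), np.asarray(x, float), sigma_floor)
    return model, model.loglik(np.asarray(y, float), np.asarray(x, float))


def strategy_loglik(
    participant: ParticipantDataset,
    task_set: TaskSet,
    predictions: StrategyPredictions,
    fit: MMMLFit,
    config: MMMLConfig = DEFAULT_CONFIG,
    trial_mask: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Log-likelihood components of given data under *fixed* parameters.

    Used for held-out scoring in cross-validation and for direct checks;
    nothing is re-estimated here. Returns (choice, time, confidence)
    components restricted to ``trial_mask`` when given.
    """
    al = _aligned(participant, task_set)
    mask = np.ones(len(al["sign"]), bool) if trial_mask is None else trial_mask
    idx = al["idx"][mask]
    sign = al["sign"][mask]

    ll_choice = 0.0
    if "choice" in config.measures:
        if fit.strategy == "PCS_fitted":
            ll_choice = _choice_ll_logistic(
                predictions.activation_diff[idx], sign, fit.lambda_
            )
        else:
            ll_choice = _choice_ll_deterministic(
                predictions.choice_sign[idx], sign, fit.epsilon
            )
    ll_time = 0.0
    if "time" in config.measures:
        tm = al["rt_keep"] & mask
        ll_time = fit.time_model.loglik(
            al["lnrt"][tm], predictions.time_contrast[al["idx"][tm]]
        )
    ll_conf = 0.0
    if "confidence" in config.measures:
        ll_conf = fit.conf_model.loglik(
            al["conf"][mask], predictions.confidence_contrast[idx]
        )
    return ll_choice, ll_time, ll_conf


# ---------------------------------------------------------------------------
# grid search for the fitted PCS variant


def _grid_components(
    al: dict, tables: GridTables, lam_grid: np.ndarray, config: MMMLConfig,
    trial_mask: np.ndarray | None = None,
):
    """Vectorized likelihood components over the whole (P, lambda) grid.

    Returns (ll_choice (nP, nL), ll_time (nP,), ll_conf (nP,), gaussian
    parameter arrays) computed on the masked trials.
    """
    mask = np.ones(len(al["sign"]), bool) if trial_mask is None else trial_mask
    idx = al["idx"][mask]
    sign = al["sign"][mask]
    nP = len(tables.p_grid)

    if not tables.converged[:, np.unique(al["idx"])].all():
        raise RuntimeError("PCS network failed to converge for some (task, P)")

    if "choice" in config.measures:
        D = tables.delta[:, idx] * sign  # (nP, nTr)
        z = lam_grid[None, :, None] * D[:, None, :]
        ll_choice = -np.logaddexp(0.0, -z).sum(axis=2)  # (nP, nL)
    else:
        ll_choice = np.zeros((nP, len(lam_grid)))

    ll_time, time_params = _grid_gaussian(
        al["lnrt"], tables.time_contrast, al["idx"], al["rt_keep"] & mask,
        "time" in config.measures, config.sigma_floor,
    )
    ll_conf, conf_params = _grid_gaussian(
        al["conf"], tables.confidence_contrast, al["idx"], mask,
        "confidence" in config.measures, config.sigma_floor,
    )
    return ll_choice, ll_time, ll_conf, time_params, conf_params


def _grid_gaussian(y_full, contrast_table, idx_full, mask, enabled, sigma_floor):
    nP = contrast_table.shape[0]
    if not enabled:
        zero = np.zeros(nP)
        return zero, (zero, zero, np.full(nP, sigma_floor))
    y = np.asarray(y_full, float)[mask]
    xs = contrast_table[:, idx_full[mask]]  # (nP, n)
    n = len(y)
    ym = y.mean()
    xm = xs.mean(axis=1)
    xc = xs - xm[:, None]
    sxx = np.sum(xc**2, axis=1)
    sxy = xc @ (y - ym)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
    beta = np.maximum(beta, 0.0)
    mu = ym - beta * xm
    resid = y[None, :] - mu[:, None] - beta[:, None] * xs
    sse = np.sum(resid**2, axis=1)
    sigma = np.maximum(np.sqrt(sse / n), sigma_floor)
    ll = -0.5 * n * np.log(2.0 * np.pi * sigma**2) - sse / (2.0 * sigma**2)
    return ll, (mu, beta, sigma)


def grid_fit_pcs(
    participant: ParticipantDataset,
    task_set: TaskSet,
    config: MMMLConfig = DEFAULT_CONFIG,
) -> tuple[float, float, MMMLFit]:
    """Exhaustive (P, lambda) grid search maximizing the MM-ML likelihood.

    Ties are broken toward the smallest P, then the smallest lambda.
    Returns (P*, lambda*, fit).
    """
    al = _aligned(participant, task_set)
    tables = pcs_grid_tables(task_set, config.p_grid, config.constants)
    lam_grid = config.lambda_grid
    ll_choice, ll_time, ll_conf, tp, cp = _grid_components(al, tables, lam_grid, config)
    total = ll_choice + (ll_time + ll_conf)[:, None]
    flat = int(np.argmax(total))  # first max: smallest P, then smallest lambda
    i, j = divmod(flat, total.shape[1])
    P_star = float(tables.p_grid[i])
    lam_star = float(lam_grid[j])
    fit = MMMLFit(
        strategy="PCS_fitted",
        epsilon=None,
        lambda_=lam_star,
        P=P_star,
        time_model=GaussianModel(float(tp[0][i]), float(tp[1][i]), float(tp[2][i]))
        if "time" in config.measures else None,
        conf_model=GaussianModel(float(cp[0][i]), float(cp[1][i]), float(cp[2][i]))
        if "confidence" in config.measures else None,
        ll_choice=float(ll_choice[i, j]),
        ll_time=float(ll_time[i]),
        ll_conf=float(ll_conf[i]),
        k=config.k_for("PCS_fitted"),
        n=_n_obs(al, config.measures),
    )
    return P_star, lam_star, fit


# ---------------------------------------------------------------------------
# classification, misfit check, cross-validation


def classify(
    participant: ParticipantDataset,
    task_set: TaskSet,
    strategies: Sequence[str] = STRATEGIES,
    config: MMMLConfig = DEFAULT_CONFIG,
    run_misfit_test: bool = True,
) -> ClassificationResult:
    """Fit every strategy and assign the one with the smallest BIC.

    BIC ties are broken toward fewer parameters, then alphabetically.
    """
    if len(strategies) < 2:
        raise ValueError("need at least 2 strategies to classify")
    fits = {
        s: fit_strategy(participant, task_set, s, config) for s in strategies
    }
    winner = min(fits, key=lambda s: (fits[s].bic, fits[s].k, s))
    wfit = fits[winner]
    misfit = (
        saturated_misfit_test(participant, task_set, wfit, config)
        if run_misfit_test and "choice" in config.measures
        else None
    )
    return ClassificationResult(
        participant_id=participant.participant_id,
        fits=fits,
        winner=winner,
        fitted_P=fits["PCS_fitted"].P if "PCS_fitted" in fits else None,
        fitted_lambda=fits["PCS_fitted"].lambda_ if "PCS_fitted" in fits else None,
        misfit=misfit,
    )


def saturated_misfit_test(
    participant: ParticipantDataset,
    task_set: TaskSet,
    fit: MMMLFit,
    config: MMMLConfig = DEFAULT_CONFIG,
) -> MisfitTest:
    """G-squared test of the winning strategy's choice component against a
    saturated model with one free choice probability per distinct cue
    pattern; a significant result flags choice misfit."""
    al = _aligned(participant, task_set)
    patterns: dict[bytes, list[int]] = {}
    for trial, t_idx in enumerate(al["idx"]):
        key = task_set[t_idx].cue_matrix.tobytes()
        patterns.setdefault(key, []).append(trial)
    ll_sat = 0.0
    for rows in patterns.values():
        s = al["sign"][rows]
        n_a = int((s == 1).sum())
        n_b = len(rows) - n_a
        p_a = n_a / len(rows)
        ll_sat += _xlogy(n_a, p_a if p_a > 0 else 1.0) + _xlogy(
            n_b, (1.0 - p_a) if p_a < 1 else 1.0
        )
    g2 = max(2.0 * (ll_sat - fit.ll_choice), 0.0)
    k_choice = 2 if fit.strategy == "PCS_fitted" else 1
    df = max(len(patterns) - k_choice, 1)
    p_value = float(stats.chi2.sf(g2, df))
    return MisfitTest(g2=g2, df=df, p_value=p_value,
                      misfit=p_value < config.misfit_alpha)


def crossval_classify(
    participant: ParticipantDataset,
    task_set: TaskSet,
    strategies: Sequence[str] = STRATEGIES,
    folds: int = 6,
    seed: int = 0,
    config: MMMLConfig = DEFAULT_CONFIG,
) -> CrossValResult:
    """Six-fold cross-validated strategy selection.

    Tasks are partitioned into ``folds`` seeded folds; for each fold all
    strategy parameters are re-estimated on the remaining tasks' trials and
    the held-out trials are scored with those parameters. The winner
    maximizes the summed out-of-sample log-likelihood (no BIC penalty:
    no parameter is fit to the held-out fold).
    """
    n_tasks = len(task_set)
    if n_tasks < 2 * folds:
        raise ValueError("need at least 2 tasks per fold")
    rng = np.random.default_rng(seed)
    fold_assign = np.array_split(rng.permutation(n_tasks), folds)

    al = _aligned(participant, task_set)
    tables = pcs_grid_tables(task_set, config.p_grid, config.constants)
    lam_grid = config.lambda_grid
    totals = {s: 0.0 for s in strategies}
    fitted_ps: list[float] = []
    pred_cache = {
        s: predict_strategy(task_set, s, constants=config.constants)
        for s in strategies if s != "PCS_fitted"
    }

    for heldout in fold_assign:
        test_mask = np.isin(al["idx"], heldout)
        train_mask = ~test_mask
        n_train = int(train_mask.sum())
        for s in strategies:
            if s == "PCS_fitted":
                llc, llt, llf, tp, cp = _grid_components(
                    al, tables, lam_grid, config, trial_mask=train_mask
                )
                total = llc + (llt + llf)[:, None]
                i, j = divmod(int(np.argmax(total)), total.shape[1])
                fitted_ps.append(float(tables.p_grid[i]))
                fit = MMMLFit(
                    strategy=s, epsilon=None,
                    lambda_=float(lam_grid[j]), P=float(tables.p_grid[i]),
                    time_model=GaussianModel(float(tp[0][i]), float(tp[1][i]), float(tp[2][i])),
                    conf_model=GaussianModel(float(cp[0][i]), float(cp[1][i]), float(cp[2][i])),
                    ll_choice=0.0, ll_time=0.0, ll_conf=0.0,
                    k=config.k_for(s), n=n_train,
                )
                preds = tables.at(i, task_set)
            else:
                preds = pred_cache[s]
                idx_tr = al["idx"][train_mask]
                eps = _fit_epsilon(preds.choice_sign[idx_tr], al["sign"][train_mask])
                # held-out scoring: an epsilon of exactly 0 would assign an
                # unseen error probability 0; the tiny floor guards the
                # impossible event without distorting deterministic fits
                eps = float(np.clip(eps, config.epsilon_floor, 0.5))
                tmask = al["rt_keep"] & train_mask
                time_model = (
                    _fit_gaussian(
                        al["lnrt"][tmask],
                        preds.time_contrast[al["idx"][tmask]],
                        config.sigma_floor,
                    )
                    if "time" in config.measures else None
                )
                conf_model = (
                    _fit_gaussian(
                        al["conf"][train_mask],
                        preds.confidence_contrast[idx_tr],
                        config.sigma_floor,
                    )
                    if "confidence" in config.measures else None
                )
                fit = MMMLFit(
                    strategy=s, epsilon=eps, lambda_=None,
                    P=predictions_P(preds),
                    time_model=time_model, conf_model=conf_model,
                    ll_choice=0.0, ll_time=0.0, ll_conf=0.0,
                    k=config.k_for(s), n=n_train,
                )
            parts = strategy_loglik(
                participant, task_set, preds, fit, config, trial_mask=test_mask
            )
            totals[s] += sum(parts)

    winner = max(totals, key=lambda s: (totals[s], s))
    return CrossValResult(
        participant_id=participant.participant_id,
        heldout_loglik=totals,
        winner=winner,
        fold_tasks=tuple(
            tuple(task_set.ids[i] for i in fold) for fold in fold_assign
        ),
        fitted_P_per_fold=tuple(fitted_ps),
    )
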