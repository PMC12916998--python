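import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pcsdecision import (
    AgentSpec,
    MMMLConfig,
    ParticipantDataset,
    bic,
    classify,
    contrastify,
    crossval_classify,
    fit_strategy,
    generate_task_set,
    grid_fit_pcs,
    predict_strategy,
    saturated_misfit_test,
    simulate_participant,
)
from pcsdecision.classify import _fit_epsilon, _choice_ll_deterministic
from pcsdecision.tasks import TaskSet
from pcsdecision.strategies import eqw_predict, waddc_predict


def make_participant(task_set, choices, rt_ms=None, conf=None, condition="intuition"):
    n = len(task_set)
    trials = pd.DataFrame(
        {
            "trial_index": np.arange(n),
            "task_id": task_set.ids,
            "choice": choices,
            "rt_ms": rt_ms if rt_ms is not None else np.full(n, 1000.0),
            "confidence": conf if conf is not None else np.full(n, 75.0),
        }
    )
    return ParticipantDataset("test", condition, trials)


class TestContrastify:
    def test_simple_example(self):
        assert np.allclose(contrastify([1, 2, 3]), [-0.5, 0.0, 0.5])

    def test_constant_input_gives_zeros(self):
        assert np.array_equal(contrastify([23.0] * 60), np.zeros(60))

    @given(
        x=st.lists(st.floats(-100, 100), min_size=3, max_size=30).filter(
            lambda v: max(v) - min(v) > 1e-6
        ),
        a=st.floats(0.1, 10),
        b=st.floats(-50, 50),
    )
    @settings(max_examples=100, derandomize=True)
    def test_affine_invariance_and_invariants(self, x, a, b):
        c = contrastify(np.array(x))
        assert abs(c.sum()) < 1e-12
        assert c.max() - c.min() == pytest.approx(1.0, abs=1e-12)
        c2 = contrastify(a * np.array(x) + b)
        assert np.allclose(c, c2, atol=1e-9)


class TestBIC:
    def test_formula(self):
        assert bic(-100.0, 7, 180) == pytest.approx(200 + 7 * np.log(180))
        assert bic(-100.0, 7, 180) == pytest.approx(236.36, abs=0.01)

    def test_fit_satisfies_bic_and_additivity(self, task_set_60):
        p = simulate_participant(
            AgentSpec(strategy="WADD_c", noise=0.1, seed=3), task_set_60
        )
        fit = fit_strategy(p, task_set_60, "WADD_c")
        assert fit.ll_total == fit.ll_choice + fit.ll_time + fit.ll_conf
        assert fit.bic == pytest.approx(
            -2 * fit.ll_total + fit.k * np.log(fit.n)
        )
        assert fit.n == 180
        assert fit.k == 7

    def test_penalty_ordering_on_equal_loglik(self):
        # identical logL, k 7 vs 9: the smaller k wins
        assert bic(-100.0, 7, 180) < bic(-100.0, 9, 180)


class TestEpsilonFit:
    def test_error_proportion(self, task_set_60):
        preds = predict_strategy(task_set_60, "TTB")
        sign = preds.choice_sign.copy()
        obs = sign.copy()
        flip = np.flatnonzero(sign != 0)[:6]
        obs[flip] = -obs[flip]
        assert _fit_epsilon(sign, obs) == pytest.approx(
            6 / int((sign != 0).sum())
        )

    def test_cap_at_half(self):
        sign = np.ones(60, dtype=int)
        obs = -np.ones(60, dtype=int)
        obs[:20] = 1  # 40/60 contradictions
        assert _fit_epsilon(sign, obs) == 0.5

    def test_half_epsilon_is_data_independent(self):
        sign = np.ones(60, dtype=int)
        for n_err in (0, 17, 60):
            obs = np.ones(60, dtype=int)
            obs[:n_err] = -1
            ll = _choice_ll_deterministic(sign, obs, 0.5)
            assert ll == pytest.approx(60 * np.log(0.5))


class TestGaussianComponents:
    def test_zero_contrast_fixes_beta_at_zero(self, task_set_60):
        p = simulate_participant(
            AgentSpec(strategy="EQW", noise=0.05, seed=9), task_set_60
        )
        fit = fit_strategy(p, task_set_60, "EQW")
        # EQW time predictions are constant -> all-zero contrast
        assert fit.time_model.beta == 0.0

    def test_slope_recovery_within_ten_percent(self, task_set_60):
        spec = AgentSpec(
            strategy="TTB", noise=0.0, beta_time=0.8, sigma_time=0.1,
            sigma_conf=1.0, seed=11,
        )
        p = simulate_participant(spec, task_set_60)
        fit = fit_strategy(p, task_set_60, "TTB")
        assert fit.time_model.beta == pytest.approx(0.8, rel=0.10)

    def test_noise_free_ttb_agent_dominates_loglik(self, task_set_60):
        spec = AgentSpec(
            strategy="TTB", noise=0.0, sigma_time=0.0, sigma_conf=0.0,
            beta_time=1.0, beta_conf=10.0, seed=2,
        )
        p = simulate_participant(spec, task_set_60)
        res = classify(p, task_set_60, run_misfit_test=False)
        ll = {s: f.ll_total for s, f in res.fits.items()}
        assert all(ll["TTB"] > v for s, v in ll.items() if s != "TTB")
        assert res.winner == "TTB"


class TestGridFit:
    def test_parameter_recovery(self, task_set_60):
        spec = AgentSpec(
            strategy="PCS_fitted", noise=4.0, P=2.0, sigma_time=0.1,
            sigma_conf=1.0, seed=21,
        )
        p = simulate_participant(spec, task_set_60)
        P_star, lam_star, fit = grid_fit_pcs(p, task_set_60)
        assert abs(P_star - 2.0) <= 0.3
        assert fit.P == P_star and fit.lambda_ == lam_star

    def test_lambda_zero_agent_fits_near_zero(self, task_set_60):
        # lambda = 0 generates coin-flip choices
        spec = AgentSpec(
            strategy="PCS_fitted", noise=0.0, P=2.0, sigma_time=0.1,
            sigma_conf=1.0, seed=22,
        )
        p = simulate_participant(spec, task_set_60)
        _, lam_star, _ = grid_fit_pcs(p, task_set_60)
        assert lam_star <= 0.5

    def test_restricted_grid_piles_on_corner(self, task_set_60):
        # restricted-range variant [1, 2]: true P outside it lands on the
        # nearest corner
        config = MMMLConfig(p_min=1.0, p_max=2.0)
        corners = 0
        for seed in range(5):
            spec = AgentSpec(
                strategy="PCS_fitted", noise=4.0, P=3.0, sigma_time=0.1,
                sigma_conf=1.0, seed=seed,
            )
            p = simulate_participant(spec, task_set_60)
            P_star, _, _ = grid_fit_pcs(p, task_set_60, config)
            corners += P_star in (1.0, 2.0)
        assert corners >= 4

    def test_winner_has_minimal_bic(self, task_set_60):
        p = simulate_participant(
            AgentSpec(strategy="PCS_fix", noise=0.05, seed=5), task_set_60
        )
        res = classify(p, task_set_60, run_misfit_test=False)
        assert res.fits[res.winner].bic == min(f.bic for f in res.fits.values())


class TestSaturatedMisfit:
    def test_noise_free_agent_has_zero_g2(self, task_set_60):
        spec = AgentSpec(
            strategy="TTB", noise=0.0, sigma_time=0.0, sigma_conf=0.0,
            beta_time=1.0, beta_conf=10.0, seed=2,
        )
        p = simulate_participant(spec, task_set_60)
        res = classify(p, task_set_60)
        assert res.misfit.g2 == pytest.approx(0.0, abs=1e-9)
        assert not res.misfit.misfit

    def test_random_chooser_misfits_ttb(self, task_set_60):
        rng = np.random.default_rng(13)
        choices = rng.choice(["A", "B"], size=60)
        p = make_participant(
            task_set_60, choices,
            rt_ms=rng.uniform(900, 1100, 60),
        )
        fit = fit_strategy(p, task_set_60, "TTB")
        test = saturated_misfit_test(p, task_set_60, fit)
        # a uniform-random chooser cannot be explained by constant-error TTB
        assert test.g2 > 0

    def test_saturated_loglik_never_below_winner(self, task_set_60):
        for seed in range(3):
            p = simulate_participant(
                AgentSpec(strategy="WADD_c", noise=0.2, seed=seed), task_set_60
            )
            fit = fit_strategy(p, task_set_60, "WADD_c")
            test = saturated_misfit_test(p, task_set_60, fit)
            assert test.g2 >= 0  # nesting: ll_sat >= ll_choice


class TestChoiceOnlyEqualsAdherenceRanking:
    def test_bruteforce_toy_set(self):
        # 6 tasks on which no heuristic predicts a random choice, so the
        # Bernoulli log-likelihood is a monotone function of adherence
        pool = generate_task_set(40, seed=3)
        chosen = [
            t for t in pool
            if eqw_predict(t).choice != "random"
            and waddc_predict(t).choice != "random"
        ][:6]
        ts = TaskSet(tuple(chosen))
        strategies = ("TTB", "EQW", "WADD_c")
        config = MMMLConfig(measures=("choice",),
                            k_override={s: 1 for s in strategies})
        preds = {s: predict_strategy(ts, s) for s in strategies}
        for pattern in range(64):
            choices = ["A" if (pattern >> i) & 1 else "B" for i in range(6)]
            p = make_participant(ts, choices)
            res = classify(p, ts, strategies, config, run_misfit_test=False)
            obs = p.choice_sign()
            adherence = {
                s: (preds[s].choice_sign == obs).mean() for s in strategies
            }
            bics = res.bic_table
            for s1 in strategies:
                for s2 in strategies:
                    if adherence[s1] > adherence[s2]:
                        assert bics[s1] < bics[s2]
                    elif adherence[s1] == adherence[s2]:
                        assert bics[s1] == pytest.approx(bics[s2])


class TestCrossValidation:
    def test_noise_free_agent_always_recovered(self, task_set_60):
        for strat in ("TTB", "WADD_c", "EQW"):
            spec = AgentSpec(
                strategy=strat, noise=0.0, sigma_time=0.0, sigma_conf=0.0,
                beta_time=1.0, beta_conf=10.0, seed=4,
            )
            p = simulate_participant(spec, task_set_60)
            cv = crossval_classify(p, task_set_60, seed=17)
            assert cv.winner == strat

    def test_fold_partition_covers_all_tasks(self, task_set_60):
        p = simulate_participant(
            AgentSpec(strategy="TTB", noise=0.05, seed=6), task_set_60
        )
        cv = crossval_classify(p, task_set_60, seed=17)
        assert len(cv.fold_tasks) == 6
        flat = [tid for fold in cv.fold_tasks for tid in fold]
        assert sorted(flat) == sorted(task_set_60.ids)
        assert {len(f) for f in cv.fold_tasks} == {10}

    def test_too_few_tasks_rejected(self, small_task_set):
        p = simulate_participant(
            AgentSpec(strategy="TTB", noise=0.0, seed=1), small_task_set
        )
        with pytest.raises(ValueError):
            crossval_classify(p, small_task_set, folds=12)
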