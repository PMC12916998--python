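import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pcsdecision import (
    DEFAULT_CONSTANTS,
    PCSConstants,
    PCSParams,
    build_network,
    choice_probability,
    mirror_task,
    pcs_predict,
    run_to_convergence,
)
from pcsdecision.predictions import pcs_batch_run
from pcsdecision.tasks import Task


def oracle_recursion(validities, cue_matrix, P, constants=DEFAULT_CONSTANTS):
    """Independent straight-line reimplementation of the network recursion:
    plain Python floats, explicit loops, no shared code with the package."""
    c = constants
    w_v = [(v - 0.5) ** P for v in validities]
    w_co = [[cue_matrix[i][o] * c.cue_option_weight for o in range(2)]
            for i in range(4)]
    cues = [0.0, 0.0, 0.0, 0.0]
    opts = [0.0, 0.0]
    streak = 0
    for it in range(1, c.max_iterations + 1):
        cue_in = [w_v[i] + w_co[i][0] * opts[0] + w_co[i][1] * opts[1]
                  for i in range(4)]
        opt_in = [
            sum(w_co[i][0] * cues[i] for i in range(4))
            + c.option_inhibition * opts[1],
            sum(w_co[i][1] * cues[i] for i in range(4))
            + c.option_inhibition * opts[0],
        ]
        new_cues, new_opts = [], []
        for old, inp in list(zip(cues, cue_in)) + list(zip(opts, opt_in)):
            if inp >= 0:
                new = old * (1 - c.decay) + inp * (c.a_max - old)
            else:
                new = old * (1 - c.decay) + inp * (old - c.a_min)
            new = min(max(new, c.a_min), c.a_max)
            (new_cues if len(new_cues) < 4 else new_opts).append(new)
        delta = max(
            abs(n - o) for n, o in zip(new_cues + new_opts, cues + opts)
        )
        cues, opts = new_cues, new_opts
        if delta < c.stability_threshold:
            streak += 1
            if streak >= c.stability_window:
                return opts, cues, it - c.stability_window + 1, True
        else:
            streak = 0
    return opts, cues, c.max_iterations, False


class TestBuildNetwork:
    def test_chance_corrected_weights_p1(self, printed_tasks):
        w = build_network(printed_tasks[0], P=1.0)
        assert np.allclose(w.w_v, [0.37, 0.37, 0.26, 0.10])

    def test_p_zero_gives_unit_weights(self, printed_tasks):
        w = build_network(printed_tasks[1], P=0.0)
        assert np.allclose(w.w_v, [1.0, 1.0, 1.0, 1.0])

    def test_p2_squares_the_chance_corrected_weights(self, printed_tasks):
        w = build_network(printed_tasks[0], P=2.0)
        assert np.allclose(w.w_v, [0.1369, 0.1369, 0.0676, 0.0100])

    def test_cue_option_signs_follow_cue_values(self, printed_tasks):
        t = printed_tasks[0]
        w = build_network(t, P=1.0)
        assert np.array_equal(np.sign(w.w_co), t.cue_matrix)
        assert w.w_oo < 0

    def test_negative_p_rejected(self, printed_tasks):
        with pytest.raises(ValueError):
            build_network(printed_tasks[0], P=-0.1)

    def test_weight_ratio_monotone_in_p(self):
        # ((v1-.5)/(v2-.5))**P strictly increasing in P for v1 > v2 > .5
        v1, v2 = 0.9, 0.7
        ratios = [((v1 - 0.5) / (v2 - 0.5)) ** p for p in np.arange(0, 5.1, 0.5)]
        assert np.all(np.diff(ratios) > 0)


class TestRunToConvergence:
    def test_symmetric_fixture_keeps_options_equal(self):
        # relaxed-validation fixture: identical option columns, built directly
        m = np.array([[1, 1], [1, 1], [-1, -1], [1, 1]])
        t = Task(id="sym", validities=(0.9, 0.8, 0.7, 0.6), cue_matrix=m)
        w = build_network(t, P=1.9)
        res = run_to_convergence(w)
        assert res.a_options[0] == res.a_options[1]

    def test_agrees_with_oracle_on_task1(self, printed_tasks):
        t = printed_tasks[0]
        res = run_to_convergence(build_network(t, P=1.9))
        o_opts, o_cues, o_it, o_conv = oracle_recursion(
            t.validities, t.cue_matrix.tolist(), 1.9
        )
        assert res.converged and o_conv
        assert res.iterations == o_it
        assert np.allclose(res.a_options, o_opts, atol=1e-10)
        assert np.allclose(res.a_cues, o_cues, atol=1e-10)
        assert res.a_options[0] > res.a_options[1]

    def test_mirror_swaps_option_activations(self, printed_tasks):
        t = printed_tasks[0]
        r1 = run_to_convergence(build_network(t, P=1.9))
        r2 = run_to_convergence(build_network(mirror_task(t), P=1.9))
        assert np.array_equal(r1.a_options, r2.a_options[::-1])
        assert np.array_equal(r1.a_cues, r2.a_cues)
        assert r1.iterations == r2.iterations

    def test_activations_bounded_throughout(self, task_set_60):
        c = DEFAULT_CONSTANTS
        for P in (0.0, 1.0, 2.5, 5.0):
            opts, cues, iters, conv = pcs_batch_run(task_set_60, P)
            assert np.all(opts >= c.a_min) and np.all(opts <= c.a_max)
            assert np.all(cues >= c.a_min) and np.all(cues <= c.a_max)
            assert np.all(conv)

    def test_batch_runner_matches_sequential(self, task_set_60):
        opts, cues, iters, conv = pcs_batch_run(task_set_60, 1.9)
        for j, t in enumerate(list(task_set_60)[:12]):
            r = run_to_convergence(build_network(t, P=1.9))
            assert r.iterations == iters[j]
            assert np.array_equal(r.a_options, opts[j])

    def test_window_end_convention_offsets_count(self, printed_tasks):
        t = printed_tasks[0]
        c2 = PCSConstants(iteration_convention="window_end")
        r1 = run_to_convergence(build_network(t, P=1.9))
        r2 = run_to_convergence(build_network(t, P=1.9, constants=c2), c2)
        assert r2.iterations == r1.iterations + c2.stability_window - 1


class TestPcsPredict:
    def test_fixed_variant_chooses_a_on_task1(self, printed_tasks):
        pred = pcs_predict(printed_tasks[0], PCSParams(P=1.9))
        assert pred.choice == "A"
        assert pred.converged

    def test_symmetric_fixture_predicts_random(self):
        m = np.array([[1, 1], [-1, -1], [1, 1], [-1, -1]])
        t = Task(id="sym", validities=(0.9, 0.8, 0.7, 0.6), cue_matrix=m)
        w = build_network(t, P=1.9)
        res = run_to_convergence(w)
        assert res.a_options[0] == res.a_options[1]

    def test_mirrored_prediction_swaps_choice_only(self, printed_tasks):
        t = printed_tasks[0]
        p1 = pcs_predict(t, PCSParams(P=1.9))
        p2 = pcs_predict(mirror_task(t), PCSParams(P=1.9))
        assert (p1.choice, p2.choice) == ("A", "B")
        assert p1.confidence_raw == p2.confidence_raw
        assert p1.time_raw == p2.time_raw


class TestChoiceProbability:
    @pytest.mark.parametrize(
        "diff, lam, expected",
        [
            (0.7, 0.0, 0.5),
            (0.0, 3.0, 0.5),
            (1.0, 5.0, 1.0 / (1.0 + math.exp(-5.0))),
        ],
    )
    def test_logistic_values(self, diff, lam, expected):
        assert choice_probability(diff, lam) == pytest.approx(expected, abs=1e-12)

    @given(
        d1=st.floats(0, 2), d2=st.floats(0, 2),
        l1=st.floats(0, 5), l2=st.floats(0, 5),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_both_arguments(self, d1, d2, l1, l2):
        lo_d, hi_d = sorted((d1, d2))
        lo_l, hi_l = sorted((l1, l2))
        assert choice_probability(hi_d, lo_l) >= choice_probability(lo_d, lo_l)
        assert choice_probability(lo_d, hi_l) >= choice_probability(lo_d, lo_l)

    def test_rejects_negative_arguments(self):
        with pytest.raises(ValueError):
            choice_probability(-0.1, 1.0)
        with pytest.raises(ValueError):
            choice_probability(0.1, -1.0)
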