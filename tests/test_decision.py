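import numpy as np
import pandas as pd
import pytest

from tempohmax.decision import (
    BehaviorTable,
    DecisionParams,
    RateSeries,
    Trial,
    accumulate,
    decide,
    fit,
    forced_choice,
    objective,
    simulate_level_means,
    trace_from_s2,
)
from conftest import poisson_race_trials


def series(counts, bw=1.0, cat=""):
    return RateSeries(bw, np.asarray(counts, float), cat)


def behavior_frame(rows):
    return BehaviorTable(
        pd.DataFrame(rows, columns=["noise_level", "category", "mean_rt_ms"])
    )


class TestAccumulate:
    def test_u_zero_is_cumulative_count(self):
        tr = accumulate(series([1, 1, 1], cat="face"), series([0, 0, 0], cat="house"))
        assert np.allclose(tr.ac_face, [1, 2, 3])
        assert np.allclose(tr.ac_house, [0, 0, 0])

    def test_opposing_coefficient_subtracts(self):
        tr = accumulate(series([2, 0]), series([1, 1]), u=1.0)
        assert np.allclose(tr.ac_face, [1, 0])
        assert np.allclose(tr.ac_house, [-1, 0])

    def test_mismatched_series_rejected(self):
        with pytest.raises(ValueError):
            accumulate(series([1, 2]), series([1, 2, 3]))
        with pytest.raises(ValueError):
            accumulate(series([1], bw=1.0), series([1], bw=0.5))

    def test_nondecreasing_without_opposition(self):
        rng = np.random.default_rng(0)
        tr = accumulate(series(rng.poisson(2, 50)), series(rng.poisson(2, 50)))
        assert np.all(np.diff(tr.ac_face) >= 0)
        assert np.all(np.diff(tr.ac_house) >= 0)


class TestDecide:
    def test_unit_rate_crosses_at_threshold_bins(self):
        tr = accumulate(series(np.ones(10), cat="face"), series(np.zeros(10), cat="house"))
        out = decide(tr, DecisionParams(th_face=5, th_house=5, alpha=1, rt_motor=0))
        assert out.choice == "face"
        assert out.rt_model_units == pytest.approx(5.0)

    def test_rt_scaling_and_motor_offset(self):
        tr = accumulate(series(np.ones(150), cat="face"), series(np.zeros(150), cat="house"))
        out = decide(tr, DecisionParams(th_face=100, th_house=100, alpha=2, rt_motor=300))
        assert out.rt_model_units == pytest.approx(100.0)
        assert out.rt_ms == pytest.approx(500.0)

    def test_flat_traces_undecided(self):
        tr = accumulate(series(np.zeros(5)), series(np.zeros(5)))
        out = decide(tr, DecisionParams(th_face=1, th_house=1, alpha=1, rt_motor=0))
        assert out.choice == "undecided" and not out.decided

    def test_rt_nondecreasing_in_threshold(self):
        rng = np.random.default_rng(1)
        tr = accumulate(series(rng.poisson(2, 200), cat="face"), series(np.zeros(200), cat="house"))
        rts = []
        for th in (5, 10, 20, 40):
            out = decide(tr, DecisionParams(th_face=th, th_house=th, alpha=1, rt_motor=0))
            rts.append(out.rt_model_units)
        assert all(a <= b for a, b in zip(rts, rts[1:]))

    def test_horizon_blocks_late_crossings(self):
        tr = accumulate(series(np.ones(10), cat="face"), series(np.zeros(10), cat="house"))
        p = DecisionParams(th_face=8, th_house=8, alpha=1, rt_motor=0, horizon=5.0)
        assert not decide(tr, p).decided


class TestForcedChoice:
    def test_proximity_rule(self):
        tr = accumulate(series([4, 4], cat="face"), series([3, 0], cat="house"))
        p = DecisionParams(th_face=10, th_house=10, alpha=1, rt_motor=0)
        assert forced_choice(tr, p, deadline=1.0) == "face"

    def test_tie_resolved_by_seeded_coin_reproducibly(self):
        tr = accumulate(series([2], cat="face"), series([2], cat="house"))
        p = DecisionParams(th_face=10, th_house=10, alpha=1, rt_motor=0)
        picks = {
            forced_choice(tr, p, 1.0, np.random.default_rng(s)) for s in range(20)
        }
        assert picks == {"face", "house"}  # both outcomes reachable
        a = forced_choice(tr, p, 1.0, np.random.default_rng(3))
        b = forced_choice(tr, p, 1.0, np.random.default_rng(3))
        assert a == b

    def test_agrees_with_decide_past_crossing(self):
        for trial in poisson_race_trials(11, n_per_level=6)[:12]:
            p = DecisionParams(th_face=15, th_house=15, alpha=1, rt_motor=0)
            out = decide(trial.trace, p)
            if out.decided:
                deadline = out.rt_model_units
                # the winner has crossed its bound: proximity >= 1 for it
                assert forced_choice(trial.trace, p, deadline) == out.choice


class TestObjective:
    def test_zero_at_perfect_match(self):
        b = behavior_frame([(0.1, "face", 500.0), (0.1, "house", 520.0)])
        assert objective(b.means, b) == 0.0

    def test_three_four_five_residual(self):
        b = behavior_frame([(0.1, "face", 500.0), (0.1, "house", 520.0)])
        m = pd.DataFrame(
            [(0.1, "face", 503.0), (0.1, "house", 524.0)],
            columns=["noise_level", "category", "mean_rt_ms"],
        )
        assert objective(m, b) == pytest.approx(5.0)

    def test_additive_across_levels(self):
        rows_b, rows_m = [], []
        for i in range(10):
            rows_b += [(i, "face", 500.0), (i, "house", 520.0)]
            rows_m += [(i, "face", 503.0), (i, "house", 524.0)]
        b = behavior_frame(rows_b)
        m = pd.DataFrame(rows_m, columns=["noise_level", "category", "mean_rt_ms"])
        assert objective(m, b) == pytest.approx(50.0)

    def test_level_mismatch_rejected(self):
        b = behavior_frame([(0.1, "face", 500.0), (0.1, "house", 520.0)])
        m = pd.DataFrame(
            [(0.2, "face", 500.0), (0.2, "house", 520.0)],
            columns=["noise_level", "category", "mean_rt_ms"],
        )
        with pytest.raises(ValueError):
            objective(m, b)

    def test_invariant_to_level_order_and_joint_translation(self):
        rng = np.random.default_rng(0)
        rows_b, rows_m = [], []
        for i in range(5):
            for cat in ("face", "house"):
                base = rng.uniform(400, 700)
                rows_b.append((i, cat, base))
                rows_m.append((i, cat, base + rng.normal(0, 20)))
        b = behavior_frame(rows_b)
        m = pd.DataFrame(rows_m, columns=["noise_level", "category", "mean_rt_ms"])
        val = objective(m, b)
        m_shuf = m.sample(frac=1, random_state=1)
        assert objective(m_shuf, b) == pytest.approx(val)
        b_shift = behavior_frame([(l, c, v + 100.0) for l, c, v in rows_b])
        m_shift = m.assign(mean_rt_ms=m["mean_rt_ms"] + 100.0)
        assert objective(m_shift, b_shift) == pytest.approx(val)


class TestSimulateLevelMeans:
    def test_groups_by_chosen_category(self):
        # face evidence only: every trial categorized face whatever its label
        trials = [
            Trial(accumulate(series(np.ones(10), cat="face"), series(np.zeros(10), cat="house")), 0.1, lbl)
            for lbl in ("face", "house")
        ]
        p = DecisionParams(th_face=3, th_house=3, alpha=1, rt_motor=0)
        means = simulate_level_means(trials, p)
        assert set(means["category"]) == {"face"}
        assert means["n_trials"].iloc[0] == 2


class TestFit:
    def test_descent_from_init(self):
        trials = poisson_race_trials(21, n_per_level=10, n_bins=400)
        true = DecisionParams(th_face=10, th_house=10, alpha=10, rt_motor=300)
        behavior = BehaviorTable(simulate_level_means(trials, true))
        init = DecisionParams(th_face=8, th_house=12, alpha=12, rt_motor=250)
        init_obj, _ = __import__("tempohmax.decision", fromlist=["_TrialCache"])._TrialCache(
            trials, behavior, None, 0.0, 0
        ).evaluate(init, 2000.0)
        res = fit(trials, behavior, init, seed=0, n_restarts=2, max_evals=300)
        assert res.objective <= init_obj

    def test_bit_identical_under_fixed_seed(self):
        trials = poisson_race_trials(22, n_per_level=8, n_bins=300)
        true = DecisionParams(th_face=8, th_house=8, alpha=10, rt_motor=300)
        behavior = BehaviorTable(simulate_level_means(trials, true))
        init = DecisionParams(th_face=6, th_house=10, alpha=8, rt_motor=350)
        a = fit(trials, behavior, init, seed=5, n_restarts=2, max_evals=200)
        b = fit(trials, behavior, init, seed=5, n_restarts=2, max_evals=200)
        assert a.params == b.params
        assert a.objective == b.objective
        assert a.n_evals == b.n_evals

    def test_empty_trials_rejected(self):
        b = behavior_frame([(0.1, "face", 500.0), (0.1, "house", 520.0)])
        with pytest.raises(ValueError):
            fit([], b, DecisionParams(th_face=1, th_house=1, alpha=1, rt_motor=0))


class TestBehaviorTable:
    def test_from_trials_aggregates_means(self):
        trials = pd.DataFrame(
            {
                "image_id": ["a", "b", "c", "d"],
                "noise_level": [0.1, 0.1, 0.1, 0.1],
                "category": ["face", "face", "house", "house"],
                "choice": ["face", "face", "house", "face"],
                "rt_ms": [400.0, 500.0, 600.0, 700.0],
                "correct": [True, True, True, False],
            }
        )
        table = BehaviorTable.from_trials(trials)
        face = table.means.query("category == 'face'")["mean_rt_ms"].iloc[0]
        assert face == pytest.approx(450.0)

    def test_rejects_nonpositive_means_and_duplicates(self):
        with pytest.raises(ValueError):
            behavior_frame([(0.1, "face", -5.0)])
        with pytest.raises(ValueError):
            behavior_frame([(0.1, "face", 5.0), (0.1, "face", 6.0)])

    def test_csv_round_trip(self, tmp_path):
        b = behavior_frame([(0.1, "face", 512.25), (0.1, "house", 530.5)])
        path = tmp_path / "behavior.csv"
        b.to_csv(path)
        back = BehaviorTable.from_csv(path)
        assert np.allclose(
            back.means["mean_rt_ms"], b.means["mean_rt_ms"]
        )


class TestTraceFromS2:
    def test_bins_cover_last_spike(self):
        class Pooled:
            def category_times(self, c):
                return np.array([1.0, 2.0, 7.5]) if c == "face" else np.array([3.0])

        tr = trace_from_s2(Pooled(), n_bins=10)
        assert tr.ac_face[-1] == 3
        assert tr.ac_house[-1] == 1
        assert tr.times[-1] >= 7.5
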