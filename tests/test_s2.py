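import numpy as np
import pytest
from hypothesis import given, strategies as st

from tempohmax.frontend import SpikeTrain
from tempohmax.s2 import (
    S2Population,
    STDPLayer,
    base_model_first_spikes,
    calibrate_thresholds,
    infer_spikes,
    init_population,
    load_population,
    population_rate,
    save_population,
    stdp_train,
)

SHAPES = [(3, 4), (2, 2)]


def make_train(times, scales, rows, cols, orients):
    order = np.argsort(times, kind="stable")
    return SpikeTrain(
        np.asarray(times, float)[order],
        np.asarray(scales, int)[order],
        np.asarray(rows, int)[order],
        np.asarray(cols, int)[order],
        np.asarray(orients, int)[order],
    )


def random_train(rng, shapes=SHAPES, n=10):
    scales = rng.integers(0, len(shapes), n)
    rows = np.array([rng.integers(0, shapes[s][0]) for s in scales])
    cols = np.array([rng.integers(0, shapes[s][1]) for s in scales])
    # unique (scale, row, col) sites
    seen, keep = set(), []
    for i, key in enumerate(zip(scales, rows, cols)):
        if key not in seen:
            seen.add(key)
            keep.append(i)
    keep = np.array(keep)
    times = np.sort(rng.uniform(0.5, 10.0, len(keep)))
    return make_train(
        times, scales[keep], rows[keep], cols[keep], rng.integers(0, 4, len(keep))
    )


class TestInit:
    def test_seeded_determinism(self):
        a = init_population(3, SHAPES, seed=5)
        b = init_population(3, SHAPES, seed=5)
        assert np.array_equal(a.weights, b.weights)

    def test_weights_clipped_to_unit_interval(self):
        pop = init_population(5, SHAPES, seed=0, init_sd=0.5)
        assert pop.weights.min() >= 0 and pop.weights.max() <= 1

    def test_default_two_categories_of_ten(self):
        pop = init_population(10, SHAPES, seed=0)
        assert pop.n_cells == 20
        assert list(pop.categories).count("face") == 10

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ValueError):
            init_population(0, SHAPES, seed=0)


class TestSTDPTrain:
    def test_null_learning_rates_leave_weights_unchanged(self):
        pop = init_population(2, SHAPES, seed=1)
        train = random_train(np.random.default_rng(0))
        out = stdp_train(pop, [train], "face", a_plus=0.0, a_minus=0.0, epochs=5)
        assert np.array_equal(out.weights, pop.weights)

    def test_repeated_pattern_matches_update_recursion(self):
        """One cell, one fixed three-afferent pattern, 50 repeats: the
        implementation must equal the multiplicative update recursion applied
        to the causal set directly."""
        pop = init_population(1, [(1, 3)], seed=0, categories=("face",))
        pop.weights[:] = 0.6
        pop.theta_train = np.array([1.0])  # crossing at the 2nd afferent
        train = make_train([1.0, 2.0, 3.0], [0, 0, 0], [0, 0, 0], [0, 1, 2], [0, 0, 0])
        a_plus, a_minus = 2.0**-5, 0.75 * 2.0**-5
        out = stdp_train(
            pop, [train], "face", a_plus=a_plus, a_minus=a_minus,
            epochs=50, shuffle=False,
        )
        idx = pop.afferent_indices(train)
        w_causal, w_rest = 0.6, 0.6
        for _ in range(50):
            w_causal += a_plus * w_causal * (1 - w_causal)
            w_rest -= a_minus * w_rest * (1 - w_rest)
        assert out.weights[0, idx[0]] == pytest.approx(w_causal)
        assert out.weights[0, idx[1]] == pytest.approx(w_causal)
        assert out.weights[0, idx[2]] == pytest.approx(w_rest)
        assert w_causal > 0.6 > w_rest

    def test_postsynaptic_latency_nonincreasing_over_repeats(self):
        rng = np.random.default_rng(4)
        train = random_train(rng, n=20)
        pop = init_population(1, SHAPES, seed=2, categories=("face",))
        pop.theta_train = calibrate_thresholds(pop, [train])
        latencies = []
        for _ in range(50):
            t = base_model_first_spikes(pop, train)[0]
            latencies.append(t)
            pop = stdp_train(pop, [train], "face", epochs=1, shuffle=False)
        latencies = np.array(latencies)
        assert not np.isnan(latencies).any()
        assert np.all(np.diff(latencies) <= 1e-12)

    def test_empty_training_set_rejected(self):
        pop = init_population(1, SHAPES, seed=0)
        with pytest.raises(ValueError):
            stdp_train(pop, [], "face")

    @given(seed=st.integers(0, 500))
    def test_weights_stay_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        pop = init_population(2, SHAPES, seed=seed, init_sd=0.3)
        trains = [random_train(rng, n=12) for _ in range(4)]
        out = stdp_train(pop, trains, "face", a_plus=0.2, a_minus=0.15, epochs=10)
        assert out.weights.min() >= 0.0 and out.weights.max() <= 1.0


class TestInference:
    def test_integrate_and_reset_hand_case(self):
        # three afferents of weight 0.6 at threshold 1.0: spike on the 2nd
        # event, reset, residual 0.6 after the 3rd
        pop = init_population(1, [(1, 3)], seed=0, categories=("face",))
        pop.weights[:] = 0.6
        pop.theta_train = np.array([2.0])
        pop.threshold_factor = 0.5  # f * theta = 1.0
        train = make_train([1.0, 2.0, 3.0], [0, 0, 0], [0, 0, 0], [0, 1, 2], [0, 0, 0])
        out = infer_spikes(pop, train)
        assert np.allclose(out.spike_times[0], [2.0])

    def test_zero_weights_are_silent(self):
        pop = init_population(2, SHAPES, seed=0)
        pop.weights[:] = 0.0
        pop.theta_train = np.ones(pop.n_cells)
        out = infer_spikes(pop, random_train(np.random.default_rng(0)))
        assert all(len(t) == 0 for t in out.spike_times)

    @given(seed=st.integers(0, 300))
    def test_spike_count_nonincreasing_in_threshold_factor(self, seed):
        rng = np.random.default_rng(seed)
        pop = init_population(1, SHAPES, seed=seed, categories=("face",))
        train = random_train(rng, n=14)
        pop.theta_train = calibrate_thresholds(pop, [train])
        counts = [
            infer_spikes(pop, train, threshold_factor=f).counts().sum()
            for f in (0.2, 0.5, 0.8, 1.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_capped_single_spike_equals_base_model_pass(self):
        rng = np.random.default_rng(9)
        pop = init_population(3, SHAPES, seed=1)
        train = random_train(rng, n=15)
        pop.theta_train = calibrate_thresholds(pop, [train], fraction=0.5)
        capped = infer_spikes(pop, train, threshold_factor=1.0, max_spikes_per_cell=1)
        base = base_model_first_spikes(pop, train)
        for times, ref in zip(capped.spike_times, base):
            if np.isnan(ref):
                assert len(times) == 0
            else:
                assert len(times) == 1 and times[0] == ref

    def test_untrained_population_rejected(self):
        pop = init_population(1, SHAPES, seed=0)
        with pytest.raises(ValueError):
            infer_spikes(pop, random_train(np.random.default_rng(0)))


class TestPopulationRate:
    def _s2(self, times_per_cell, cats):
        from tempohmax.s2 import S2SpikeTrain

        return S2SpikeTrain([np.asarray(t, float) for t in times_per_cell], cats)

    def test_silence_gives_zero_series(self):
        series = population_rate(self._s2([[], []], ["face", "face"]), "face", 1.0)
        assert np.all(series.counts == 0)

    def test_cumulative_counts(self):
        s2 = self._s2([[0.5, 0.6, 0.9], [1.5]], ["face", "face"])
        series = population_rate(s2, "face", 1.0, horizon=2.0)
        assert np.allclose(series.counts, [3, 1])
        assert np.allclose(series.cumulative(), [3, 4])

    def test_cumulative_nondecreasing(self):
        rng = np.random.default_rng(0)
        s2 = self._s2([rng.uniform(0, 5, 30)], ["house"])
        series = population_rate(s2, "house", 0.25)
        assert np.all(np.diff(series.cumulative()) >= 0)

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            population_rate(self._s2([[1.0]], ["face"]), "face", 0.0)


class TestSerialization:
    def test_archive_round_trip(self, tmp_path):
        pop = init_population(2, SHAPES, seed=3)
        pop.theta_train = np.arange(4, dtype=float) + 1
        path = tmp_path / "model.npz"
        save_population(pop, path, seed=3)
        back = load_population(path)
        assert np.array_equal(back.weights, pop.weights)
        assert np.array_equal(back.theta_train, pop.theta_train)
        assert back.categories == pop.categories
        assert back.c1_shapes == pop.c1_shapes


class TestSTDPLayer:
    def test_fit_transform_contract(self, fixture_trains, small_fixture):
        y = [im.label for im in small_fixture.originals]
        layer = STDPLayer(n_per_category=2, epochs=5, random_state=0)
        layer.fit(fixture_trains, y)
        assert layer.population_.n_cells == 4
        out = layer.transform(fixture_trains[:2])
        assert len(out) == 2
        assert len(out[0].spike_times) == 4

    def test_label_count_mismatch_rejected(self, fixture_trains):
        with pytest.raises(ValueError):
            STDPLayer().fit(fixture_trains, ["face"])
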