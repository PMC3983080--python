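"""AICc, Akaike weights, scattered-data interpolation and weight maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmpc.model_bank import InputSpace
from mmpc.synthetic_training import simulate_training_data
from mmpc.weight_maps import (
    TrainingInterpolant,
    aicc,
    akaike_weights,
    build_weight_map,
    interpolate_training_data,
)


class TestAicc:
    def test_hand_arithmetic_oracle(self):
        """n=10, RSS=2.5, k=3: 10 ln(0.25) + 6 + 24/6."""
        expected = 10 * np.log(0.25) + 6 + 24 / 6
        assert aicc([2.5], [10], 3) == pytest.approx(expected, abs=1e-10)
        assert aicc([2.5], [10], 3) == pytest.approx(-3.8629, abs=1e-4)

    def test_equal_inputs_give_equal_values(self):
        a = aicc([1.7, 0.4], [12, 9], 5)
        b = aicc([1.7, 0.4], [12, 9], 5)
        assert a - b == 0.0

    @given(st.integers(min_value=1, max_value=17))
    @settings(deadline=None, derandomize=True)
    def test_penalty_strictly_increases_in_k(self, k):
        """For fixed RSS and n, AICc grows with parameter count (k < n-2)."""
        n, rss = 20, 3.0
        if k + 1 < n - 2:
            assert aicc([rss], [n], k + 1) > aicc([rss], [n], k)

    def test_small_sample_guard(self):
        with pytest.raises(ValueError, match="n = "):
            aicc([1.0], [5], 4)

    def test_multi_output_reduces_to_sum(self):
        single = aicc([2.0], [10], 2)
        # two outputs with the same per-output fit double the lack-of-fit
        # term while n doubles in the correction
        double = aicc([2.0, 2.0], [10, 10], 2)
        expected = 2 * 10 * np.log(0.2) + 4 + 2 * 2 * 3 / (20 - 3)
        assert double == pytest.approx(expected, abs=1e-10)
        assert double != pytest.approx(single)


class TestAkaikeWeights:
    def test_equal_values_split_evenly(self):
        np.testing.assert_allclose(
            akaike_weights([100.0, 100.0, 100.0]), np.full(3, 1 / 3), atol=1e-12
        )

    def test_delta_two_oracle(self):
        """AICc (10, 12): weights exp(0)/Z and exp(-1)/Z."""
        w = akaike_weights([10.0, 12.0])
        z = 1 + np.exp(-1.0)
        np.testing.assert_allclose(w, [1 / z, np.exp(-1) / z], atol=1e-12)
        np.testing.assert_allclose(w, [0.7311, 0.2689], atol=1e-4)

    def test_single_model(self):
        np.testing.assert_array_equal(akaike_weights([42.0]), [1.0])

    def test_underflow_safe_for_huge_values(self):
        w = akaike_weights([1e6, 1e6 + 2, 2e6])
        assert np.all(np.isfinite(w)) and w.sum() == pytest.approx(1.0)

    def test_infinite_aicc_gets_zero_weight(self):
        w = akaike_weights([5.0, np.inf])
        np.testing.assert_allclose(w, [1.0, 0.0])

    @given(
        st.lists(st.floats(min_value=-50, max_value=50), min_size=1, max_size=6)
    )
    @settings(deadline=None, derandomize=True)
    def test_normalization_property(self, values):
        w = akaike_weights(values)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all((w >= 0) & (w <= 1))


class TestInterpolation:
    def _interp(self, pts, vals):
        scale = np.array([10.0, 10.0, 30.0])
        return TrainingInterpolant(np.asarray(pts, float), np.asarray(vals, float), scale)

    def test_node_exactness(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform([0, 0, 0], [10, 10, 30], size=(40, 3))
        vals = rng.normal(size=40)
        f = self._interp(pts, vals)
        np.testing.assert_allclose(f(pts), vals, atol=1e-9)

    def test_linearity_between_two_doses(self):
        """Values 0.2 and 0.6 at doses (0,0) and (10,0): midpoint gives 0.4."""
        pts, vals = [], []
        for t in (0.0, 30.0):
            for (d, v) in [((0, 0), 0.2), ((10, 0), 0.6)]:
                pts.append([d[0], d[1], t])
                vals.append(v)
        # off-axis points so the 3-D triangulation is non-degenerate
        pts += [[5, 10, 0], [5, 10, 30]]
        vals += [0.4, 0.4]
        f = self._interp(pts, vals)
        assert f([[5.0, 0.0, 15.0]])[0] == pytest.approx(0.4, abs=1e-9)

    def test_outside_hull_clamps_to_nearest_support_point(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform([2, 2, 5], [8, 8, 25], size=(30, 3))
        vals = rng.normal(size=30)
        f = self._interp(pts, vals)
        scale = np.array([10.0, 10.0, 30.0])
        query = np.array([[9.9, 9.9, 29.0], [0.0, 0.0, 0.0]])
        got = f(query)
        for q, g in zip(query, got):
            d = np.linalg.norm((pts - q) / scale, axis=1)
            assert g == pytest.approx(vals[int(np.argmin(d))])

    def test_degenerate_support_raises_with_hint(self):
        pts = [[0, 0, t] for t in np.linspace(0, 30, 8)]  # all doses equal
        with pytest.raises(ValueError, match="triangulation"):
            self._interp(pts, np.zeros(8))

    def test_convenience_wrapper_matches_training_values(self, plant_dataset):
        exp = plant_dataset.experiments[3]
        t_q = plant_dataset.t_smooth[10]
        v = interpolate_training_data(plant_dataset, exp.dose, t_q)
        assert v == pytest.approx(
            plant_dataset.y_smooth[exp.experiment_id][10], abs=1e-9
        )


class TestWeightMap:
    def test_weights_sum_to_one_across_input_space(self, plant_weight_map):
        rng = np.random.default_rng(11)
        for u in rng.uniform([0, 0], [50, 10], size=(100, 2)):
            w = plant_weight_map.weights_at(u)
            assert w.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all((w >= 0) & (w <= 1)) and np.all(np.isfinite(w))

    def test_plant_identified_from_zero_noise_data(
        self, bank, plant, training_design, run_config
    ):
        """Noise-free plant data drive the plant member's weight above 0.99
        at every training dose (model-identification property)."""
        ds = simulate_training_data(
            plant, training_design, noise_sd=0.0, n_timepoints=8, seed=0
        )
        models = [m.copy() for m in bank]
        for m in models:
            m.n_params = 8  # equal complexity: fitness alone decides
        wmap = build_weight_map(models, ds, run_config.space)
        plant_idx = [m.model_id for m in models].index(plant.model_id)
        for dose, _ in training_design:
            w = wmap.weights_at(dose)
            assert w[plant_idx] > 0.99

    def test_identical_models_split_weight_evenly(
        self, plant, plant_dataset, run_config
    ):
        """Two copies of one model fit any dataset equally: weights are flat
        at 1/2 everywhere (the no-information limit)."""
        twin_a, twin_b = plant.copy(), plant.copy()
        twin_b.model_id = "twin"
        wmap = build_weight_map([twin_a, twin_b], plant_dataset, run_config.space)
        for u in ([0, 0], [25, 5], [50, 10], [10, 1]):
            np.testing.assert_allclose(
                wmap.weights_at(np.asarray(u, float)), [0.5, 0.5], atol=1e-6
            )

    def test_more_data_sharpens_the_map(
        self, bank, plant, training_design, run_config
    ):
        """Increasing the raw point count weakly increases the plant
        member's maximum weight (the 'digital' large-n regime)."""
        models = [m.copy() for m in bank]
        for m in models:
            m.n_params = 8
        plant_idx = [m.model_id for m in models].index(plant.model_id)
        maxima = []
        for n_tp in (6, 12, 24):
            ds = simulate_training_data(
                plant, training_design, noise_sd=0.05, n_timepoints=n_tp, seed=9
            )
            wmap = build_weight_map(models, ds, run_config.space)
            pts = run_config.space.lattice(5)
            maxima.append(max(wmap.weights_at(p)[plant_idx] for p in pts))
        assert maxima[0] <= maxima[1] + 1e-9
        assert maxima[1] <= maxima[2] + 1e-9

    def test_windowed_query_uses_window_times(self, plant_weight_map):
        full = plant_weight_map.weights_at(np.array([30.0, 0.0]))
        windowed = plant_weight_map.weights_at(
            np.array([30.0, 0.0]), window=(18.0, 23.0)
        )
        assert windowed.sum() == pytest.approx(1.0, abs=1e-9)
        # windowed and whole-course weights are legitimately different maps
        assert windowed.shape == full.shape

    def test_json_export_is_self_consistent(self, plant_weight_map):
        d = plant_weight_map.to_json_dict(n_per_dim=3)
        w = np.array(d["weights"])
        assert w.shape == (9, 2)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-9)
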