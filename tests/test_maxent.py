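"""Maximum-entropy model: fitting contract, prediction, jack-knife."""

import numpy as np
import pytest

from coralhab import (
    Grid,
    LayerStack,
    MaxentConfig,
    NicheModel,
    binary_map,
    fit,
    jackknife,
    predict_logistic,
    sample_background,
)
from coralhab.maxent import FeatureSet

CFG = MaxentConfig(seed=0, n_background=500)


def _stack(rng, n=12, m=15):
    a = Grid(rng.normal(size=(n, m)), 0.0, float(n) * 0.5, 0.5)
    b = Grid(rng.normal(size=(n, m)), 0.0, float(n) * 0.5, 0.5)
    a.values[0, 0] = a.nodata
    s = LayerStack()
    s.add("a", a)
    s.add("b", b)
    return s


class TestBackground:
    def test_draws_distinct_cells(self, rng):
        s = _stack(rng)
        cfg = MaxentConfig(seed=3, n_background=10)
        X, r, c = sample_background(s, cfg, return_cells=True)
        assert X.shape == (10, 2)
        assert len({(int(i), int(j)) for i, j in zip(r, c)}) == 10

    def test_seed_reproducible(self, rng):
        s = _stack(rng)
        cfg = MaxentConfig(seed=5, n_background=20)
        np.testing.assert_array_equal(sample_background(s, cfg), sample_background(s, cfg))

    def test_takes_all_with_warning_when_short(self, rng):
        s = _stack(rng, n=4, m=4)
        with pytest.warns(UserWarning, match="using all"):
            X = sample_background(s, MaxentConfig(seed=0, n_background=10_000))
        assert X.shape[0] == s.valid_mask.sum()


class TestFit:
    def test_no_signal_gain_near_zero(self, rng):
        bg = rng.normal(size=(400, 2))
        pres = bg[rng.choice(400, size=60, replace=False)]
        model = fit(pres, bg, CFG)
        # a finite presence subsample leaves a little apparent structure;
        # the gain must be near zero compared with any real signal (~2)
        assert model.training_gain == pytest.approx(0.0, abs=0.15)

    def test_positive_1d_signal_matches_grid_search_sign(self, rng):
        # m < 10 -> linear feature only; presences at high x must give a
        # positive weight, same sign as a brute-force 1-parameter search
        bg = rng.uniform(0, 1, size=(300, 1))
        pres = np.sort(bg[:, 0])[-8:][:, None]
        model = fit(pres, bg, CFG)
        assert model.features.use_quadratic is False
        assert model.weights[0] > 0
        # oracle: unregularised gain over a grid of single weights
        fs = model.features
        P, B = fs.transform(pres)[:, 0], fs.transform(bg)[:, 0]
        grid = np.linspace(-20, 20, 801)
        gains = [
            lam * P.mean() - (np.log(np.mean(np.exp(lam * B))))
            for lam in grid
        ]
        assert grid[int(np.argmax(gains))] > 0

    def test_huge_regularization_gives_uniform_model(self, rng):
        bg = rng.normal(size=(200, 2))
        pres = bg[:30] + 0.5
        model = fit(pres, bg, MaxentConfig(seed=0, regularization_multiplier=1e6))
        assert np.all(model.weights == 0.0)
        hsi = model.hsi(bg)
        assert np.allclose(hsi, hsi[0])

    def test_gain_trace_monotone_nondecreasing(self, world, world_presences):
        stack = world.stack
        rows, cols = world_presences.cell_indices(stack.reference)
        X = stack.covariates_at_cells(rows, cols)
        bg = sample_background(stack, MaxentConfig(seed=1))
        model = fit(X, bg, MaxentConfig(seed=1), stack.names)
        trace = np.array(model.gain_trace)
        assert np.all(np.diff(trace) >= -1e-9)
        # convergence rule: either the gain change dropped below threshold
        # or the iteration cap was hit
        assert (
            abs(trace[-1] - trace[-2]) < MaxentConfig().convergence_threshold
            or len(trace) - 1 == MaxentConfig().max_iterations
        )

    def test_gibbs_probabilities_sum_to_one(self, rng):
        bg = rng.normal(size=(300, 2))
        pres = bg[:40] * 0.5 + 0.8
        model = fit(pres, bg, CFG)
        q = np.exp(model.log_density(bg))
        assert q.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_weights_is_exactly_uniform(self, rng):
        bg = rng.normal(size=(100, 2))
        model = fit(bg[:20], bg, MaxentConfig(seed=0, regularization_multiplier=1e6))
        q = np.exp(model.log_density(bg))
        np.testing.assert_allclose(q, 1.0 / 100, rtol=1e-12)

    def test_input_validation(self, rng):
        bg = rng.normal(size=(50, 2))
        with pytest.raises(ValueError, match="at least 2"):
            fit(bg[:1], bg, CFG)
        bad = bg.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit(bad[:10], bg, CFG)

    def test_json_roundtrip(self, rng):
        bg = rng.normal(size=(150, 2))
        model = fit(bg[:25] + 0.3, bg, CFG)
        back = NicheModel.from_json(model.to_json())
        np.testing.assert_allclose(back.hsi(bg), model.hsi(bg))
        assert back.training_gain == pytest.approx(model.training_gain)


class TestPredict:
    def test_uniform_model_is_constant(self, rng):
        s = _stack(rng)
        bg = sample_background(s, MaxentConfig(seed=0, n_background=100))
        model = fit(bg[:20], bg, MaxentConfig(seed=0, regularization_multiplier=1e6), s.names)
        hsi = predict_logistic(model, s)
        vals = hsi.values[hsi.mask]
        assert np.allclose(vals, vals[0])

    def test_bounded_and_nodata_preserved(self, rng):
        s = _stack(rng)
        bg = sample_background(s, MaxentConfig(seed=0, n_background=150))
        model = fit(bg[:30] + 0.4, bg, CFG, s.names)
        hsi = predict_logistic(model, s)
        assert not hsi.mask[0, 0]  # layer-a nodata cell
        vals = hsi.values[hsi.mask]
        assert np.all((vals >= 0) & (vals <= 1))

    def test_monotone_in_single_positive_linear_weight(self):
        fs = FeatureSet(["x"], np.array([0.0]), np.array([1.0]),
                        use_quadratic=False, use_hinge=False, use_product=False)
        model = NicheModel(fs, np.array([2.0]), 0.0, 1.0, 0.5, 100)
        x = np.linspace(-0.5, 1.5, 101)[:, None]  # sweeps beyond clamp range
        h = model.hsi(x)
        assert np.all(np.diff(h) >= -1e-15)

    def test_variable_mismatch_rejected(self, rng):
        s = _stack(rng)
        bg = sample_background(s, MaxentConfig(seed=0, n_background=100))
        model = fit(bg[:20], bg, CFG, ["p", "q"])
        with pytest.raises(KeyError):
            predict_logistic(model, s)


class TestBinaryMap:
    def test_threshold_extremes(self, rng):
        g = Grid(rng.uniform(0.01, 0.99, size=(5, 5)), 0, 5, 1.0)
        g.values[0, 0] = g.nodata
        all_one = binary_map(g, 0.0)
        assert np.all(all_one.values[all_one.mask] == 1.0)
        all_zero = binary_map(g, 1.0)
        assert np.all(all_zero.values[all_zero.mask] == 0.0)
        assert not all_zero.mask[0, 0]

    def test_count_matches_explicit_oracle(self, rng):
        g = Grid(rng.uniform(size=(8, 8)), 0, 8, 1.0)
        thr = 0.4
        out = binary_map(g, thr)
        expected = int(sum(1 for v in g.values.ravel() if v >= thr))
        assert int(out.values[out.mask].sum()) == expected


class TestJackknife:
    def test_planted_driver_and_noise_variable(self, rng):
        # variable 0 drives presence; variable 1 is pure noise
        bg = np.column_stack([rng.uniform(0, 1, 600), rng.uniform(0, 1, 600)])
        suit = np.exp(-((bg[:, 0] - 0.7) ** 2) / 0.02)
        pres = bg[rng.choice(600, p=suit / suit.sum(), size=80, replace=False)]
        rows, full_gain = jackknife(pres, bg, ["driver", "noise"], CFG)
        by_name = {r.variable: r for r in rows}
        assert by_name["driver"].gain_only > by_name["noise"].gain_only
        assert by_name["noise"].gain_only == pytest.approx(0.0, abs=0.1)
        # removing the driver hurts; removing noise barely changes gain
        assert by_name["noise"].gain_without == pytest.approx(full_gain, abs=0.1)
        assert by_name["driver"].gain_without < full_gain - 0.2

    def test_duplicate_variable_is_redundant(self, rng):
        bg1 = rng.uniform(0, 1, size=(400, 1))
        bg = np.column_stack([bg1, bg1])  # identical twin variables
        suit = np.exp(-((bg[:, 0] - 0.5) ** 2) / 0.02)
        pres = bg[rng.choice(400, p=suit / suit.sum(), size=60, replace=False)]
        rows, full_gain = jackknife(pres, bg, ["v", "twin"], CFG)
        for r in rows:
            assert r.gain_without == pytest.approx(full_gain, abs=0.05)

    def test_needs_two_variables(self, rng):
        bg = rng.uniform(size=(50, 1))
        with pytest.raises(ValueError):
            jackknife(bg[:10], bg, ["only"], CFG)
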