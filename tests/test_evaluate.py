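"""Evaluation statistics against enumeration oracles and worked values."""

import itertools

import numpy as np
import pytest
from scipy import stats

from coralhab import (
    Grid,
    LayerStack,
    auc_presence_background,
    auc_significance,
    covariation_screen,
    gain_likelihood_ratio,
    niche_summary,
    omission_rate,
    partition,
    percentile_threshold,
)
from coralhab import test_gain as compute_test_gain  # avoid pytest collection
from coralhab.maxent import FeatureSet, NicheModel
from coralhab.presences import PresenceRecord, PresenceSet


def _auc_bruteforce(p, b):
    """All-pairs enumeration oracle (ties count one half)."""
    wins = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in p for y in b)
    return wins / (len(p) * len(b))


class TestPartition:
    def _pset(self, n):
        recs = [PresenceRecord("A", 0.5 + i, 0.5) for i in range(n)]
        from coralhab import GeoTransform

        return PresenceSet("A", recs, GeoTransform(0, 1, 1.0, 1, n))

    def test_70_30_sizes(self):
        part = partition(self._pset(10), 0.7, seed=1)
        assert (len(part.train), len(part.test)) == (7, 3)

    def test_seed_reproducible(self):
        p1 = partition(self._pset(20), 0.7, seed=9)
        p2 = partition(self._pset(20), 0.7, seed=9)
        assert [r.lon for r in p1.train.records] == [r.lon for r in p2.train.records]

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2, 1.5])
    def test_degenerate_fractions_rejected(self, frac):
        with pytest.raises(ValueError):
            partition(self._pset(10), frac, seed=0)

    @pytest.mark.parametrize("n,seed", [(4, 0), (5, 1), (11, 2), (50, 3), (101, 4)])
    def test_true_partition(self, n, seed):
        part = partition(self._pset(n), 0.7, seed=seed)
        train = {r.lon for r in part.train.records}
        test = {r.lon for r in part.test.records}
        assert train.isdisjoint(test)
        assert len(train | test) == n
        assert len(train) == min(max(int(round(0.7 * n)), 1), n - 1)


class TestAUC:
    def test_perfect_separation_is_one(self):
        assert auc_presence_background([1.0, 1.0], [0.0, 0.0, 0.0]) == 1.0

    def test_identical_distributions_near_half(self, rng):
        vals = rng.uniform(size=4000)
        assert auc_presence_background(vals[:2000], vals[2000:]) == pytest.approx(0.5, abs=0.03)

    def test_worked_example_five_sixths(self):
        # enumerate the 6 pairs by hand: presences 0.9 and 0.4 beat
        # background 0.5/0.3/0.1 in 3 + 2 of 6 pairings
        assert auc_presence_background([0.9, 0.4], [0.5, 0.3, 0.1]) == pytest.approx(5 / 6)

    def test_matches_bruteforce_and_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(25):
            p = rng.choice(np.linspace(0, 1, 17), size=rng.integers(2, 40))
            b = rng.choice(np.linspace(0, 1, 17), size=rng.integers(2, 160))
            mine = auc_presence_background(p, b)
            assert mine == pytest.approx(_auc_bruteforce(p, b), abs=1e-12)
            y = np.concatenate([np.ones(p.size), np.zeros(b.size)])
            assert mine == pytest.approx(
                roc_auc_score(y, np.concatenate([p, b])), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self, rng):
        p = rng.normal(size=50)
        b = rng.normal(size=200)
        base = auc_presence_background(p, b)
        for f in (np.exp, np.tanh, lambda x: 3 * x - 7):
            assert auc_presence_background(f(p), f(b)) == pytest.approx(base)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            auc_presence_background([], [1.0])


class TestGain:
    def _model_1d(self, weight, bg):
        fs = FeatureSet(["x"], np.array([0.0]), np.array([1.0]),
                        use_quadratic=False, use_hinge=False, use_product=False)
        eta = weight * bg[:, 0]
        logz = float(np.log(np.sum(np.exp(eta))))
        q = np.exp(eta - logz)
        return NicheModel(fs, np.array([weight]), logz, float(-(q * (eta - logz)).sum()),
                          0.0, bg.shape[0])

    def test_exp2_is_about_7_4(self):
        assert gain_likelihood_ratio(2.0) == pytest.approx(7.4, abs=0.02)

    def test_uniform_model_gain_zero(self, rng):
        bg = rng.uniform(size=(40, 1))
        model = self._model_1d(0.0, bg)
        assert compute_test_gain(model, rng.uniform(size=(10, 1)), bg) == pytest.approx(0.0, abs=1e-12)

    def test_matches_manual_arithmetic(self):
        # 4 background points, 3 test presences, one linear weight: compute
        # mean log(q * N) directly
        bg = np.array([[0.0], [0.25], [0.5], [1.0]])
        pres = np.array([[0.1], [0.6], [0.9]])
        w = 1.5
        model = self._model_1d(w, bg)
        z = np.sum(np.exp(w * bg[:, 0]))
        expected = np.mean([np.log(np.exp(w * x) / z * 4) for x in pres[:, 0]])
        assert compute_test_gain(model, pres, bg) == pytest.approx(expected)


class TestThresholdOmission:
    def test_percentile_10_of_1_to_10(self):
        # order statistics 1..10: the 10th percentile interpolates to 1.9
        assert percentile_threshold(np.arange(1, 11), 10) == pytest.approx(1.9)

    def test_all_equal_scores(self):
        assert percentile_threshold([0.3, 0.3, 0.3], 10) == 0.3

    def test_median_of_two(self):
        assert percentile_threshold([1.0, 3.0], 50) == 2.0

    def test_percentile_bounds(self):
        with pytest.raises(ValueError):
            percentile_threshold([1.0], 0)
        with pytest.raises(ValueError):
            percentile_threshold([1.0], 100)

    def test_omission_cases(self):
        assert omission_rate([0.9, 0.8], 0.5) == 0.0
        assert omission_rate([0.1, 0.2], 0.5) == 1.0
        assert omission_rate([0.2, 0.6, 0.8], 0.5) == pytest.approx(1 / 3)

    def test_score_at_threshold_not_omitted(self):
        # strictly-below convention matches the >= rule of the binary map
        assert omission_rate([0.5, 0.7], 0.5) == 0.0

    def test_training_omission_bounded_by_percentile(self, rng):
        scores = rng.uniform(size=200)  # tie-free continuous scores
        thr = percentile_threshold(scores, 10)
        assert omission_rate(scores, thr) <= 0.10


class TestSignificance:
    def test_indistinguishable_groups_large_p(self, rng):
        a = 0.5 + 0.01 * rng.normal(size=20)
        b = 0.5 + 0.01 * rng.normal(size=20)
        assert auc_significance(a, b) > 0.05

    def test_separated_groups_small_p(self, rng):
        a = 0.97 + 0.002 * rng.normal(size=10)
        b = 0.50 + 0.010 * rng.normal(size=10)
        assert auc_significance(a, b) < 0.01

    def test_exact_small_sample_matches_enumeration(self, rng):
        a = list(rng.uniform(size=5))
        b = list(rng.uniform(size=5))
        p = auc_significance(a, b)
        # full enumeration of the rank-sum null at n = m = 5
        pooled = a + b
        ranks = stats.rankdata(pooled)
        obs = ranks[:5].sum()
        sums = [
            sum(ranks[list(idx)]) for idx in itertools.combinations(range(10), 5)
        ]
        mu = np.mean(sums)
        tail = np.mean([abs(s - mu) >= abs(obs - mu) - 1e-12 for s in sums])
        assert p == pytest.approx(tail, abs=1e-9)

    def test_too_few_replicates(self):
        with pytest.raises(ValueError):
            auc_significance([0.9] * 4, [0.5] * 4)


class TestCovariationScreen:
    def _stack(self, cols):
        s = LayerStack()
        for name, v in cols.items():
            s.add(name, Grid(np.asarray(v, dtype=float), 0, len(v), 1.0))
        return s

    def test_self_and_negation(self, rng):
        v = rng.normal(size=(10, 10))
        s = self._stack({"x": v, "neg": -v})
        corr, flags = covariation_screen(s, n_points=100, seed=0)
        assert corr.loc["x", "x"] == pytest.approx(1.0)
        assert corr.loc["x", "neg"] == pytest.approx(-1.0)
        assert ("x", "neg", pytest.approx(-1.0)) in [tuple(f) for f in flags]

    def test_hand_pearson_five_points(self):
        # 5-cell layers checked against the textbook formula
        x = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
        y = np.array([[2.0, 1.0, 4.0, 3.0, 7.0]])
        s = self._stack({"x": x, "y": y})
        corr, _ = covariation_screen(s, n_points=5, seed=0)
        expected = stats.pearsonr(x[0], y[0]).statistic
        assert corr.loc["x", "y"] == pytest.approx(expected)

    def test_zero_variance_flagged(self, rng):
        s = self._stack({"x": rng.normal(size=(5, 5)), "const": np.ones((5, 5))})
        corr, flags = covariation_screen(s, n_points=25, seed=0)
        assert np.isnan(corr.loc["x", "const"])
        assert any(f[0] == "x" and f[1] == "const" for f in flags)

    def test_needs_two_layers(self, rng):
        s = self._stack({"x": rng.normal(size=(4, 4))})
        with pytest.raises(ValueError):
            covariation_screen(s)


class TestNicheSummary:
    def _setup(self, rng):
        vals = rng.uniform(1.0, 9.0, size=(6, 6))
        g = Grid(vals, 0.0, 6.0, 1.0)
        s = LayerStack()
        s.add("temperature", g)
        recs = [PresenceRecord("A", c + 0.5, 5.5 - r) for r, c in [(0, 0), (1, 1), (2, 2)]]
        return s, PresenceSet("A", recs, g.geotransform), vals

    def test_single_presence(self, rng):
        s, pset, vals = self._setup(rng)
        single = PresenceSet("A", pset.records[:1], pset.reference_geotransform)
        out = niche_summary(single, s)
        assert out.loc[0, "mean"] == vals[0, 0]
        assert out.loc[0, "sd"] == 0.0

    def test_exceedance_matches_count_oracle(self, rng):
        s, pset, vals = self._setup(rng)
        out = niche_summary(pset, s, exceedance={"temperature": (">", 5.0)})
        sampled = [vals[0, 0], vals[1, 1], vals[2, 2]]
        expected = 100.0 * sum(v > 5.0 for v in sampled) / 3
        assert out.loc[0, "exceedance_pct"] == pytest.approx(expected)

    def test_nodata_excluded_from_denominator(self, rng):
        s, pset, vals = self._setup(rng)
        other = Grid(vals.copy(), 0.0, 6.0, 1.0)
        other.values[1, 1] = other.nodata
        s.add("oxygen", other)
        out = niche_summary(pset, s)
        ox = out[out["variable"] == "oxygen"].iloc[0]
        assert ox["n"] == 2
        assert ox["mean"] == pytest.approx((vals[0, 0] + vals[2, 2]) / 2)
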