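"""Correlation-based feature selection: discretization, SU, merit, search."""

import itertools

import numpy as np
import pytest

from hhtseizure.cfs import (
    apply_cuts,
    best_first_select,
    mdl_discretize,
    merit,
    symmetrical_uncertainty,
)


class TestMDLDiscretize:
    def test_separated_classes_single_cut_near_zero(self, rng):
        x = np.concatenate([rng.uniform(-2, -0.1, 50), rng.uniform(0.1, 2, 50)])
        y = np.array([0] * 50 + [1] * 50)
        cuts = mdl_discretize(x, y)
        assert len(cuts) >= 1
        assert any(abs(c) < 0.15 for c in cuts)
        # the accepted cut must separate the classes perfectly
        binned = apply_cuts(x, cuts)
        for b in np.unique(binned):
            assert len(np.unique(y[binned == b])) == 1

    def test_label_independent_feature_no_cuts(self, rng):
        x = rng.standard_normal(200)
        y = rng.integers(0, 2, 200)
        assert mdl_discretize(x, y) == []

    def test_constant_feature_no_cuts(self):
        y = np.array([0, 1] * 20)
        assert mdl_discretize(np.full(40, 1.0), y) == []

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 class"):
            mdl_discretize(np.arange(10.0), np.zeros(10, dtype=int))


class TestSymmetricalUncertainty:
    def test_identical_series(self):
        a = np.array([0, 1, 0, 1, 1])
        assert symmetrical_uncertainty(a, a) == pytest.approx(1.0)

    def test_bijection_is_perfect_correlation(self):
        a = np.array([0, 1, 0, 1, 1, 0])
        assert symmetrical_uncertainty(a, 1 - a) == pytest.approx(1.0)

    def test_independent_coins_near_zero(self, rng):
        a = rng.integers(0, 2, 10_000)
        b = rng.integers(0, 2, 10_000)
        assert symmetrical_uncertainty(a, b) < 0.05

    def test_constant_series_defined_zero(self):
        a = np.zeros(10, dtype=int)
        assert symmetrical_uncertainty(a, a) == 0.0

    def test_range(self, rng):
        for _ in range(20):
            a = rng.integers(0, 4, 100)
            b = rng.integers(0, 3, 100)
            assert 0.0 <= symmetrical_uncertainty(a, b) <= 1.0


class TestMerit:
    def test_single_feature_merit_is_class_su(self):
        su_cf = np.array([0.7, 0.2])
        assert merit((0,), su_cf, lambda i, j: 0.0) == pytest.approx(0.7)

    def test_empty_subset_zero(self):
        assert merit((), np.array([0.5]), lambda i, j: 0.0) == 0.0

    def test_duplicate_feature_decreases_merit(self):
        # adding a perfect duplicate (r_ff = 1) to a subset with some
        # internal diversity lowers the merit at unchanged class correlation
        su_cf = np.array([0.6, 0.6, 0.6])
        ff = {(0, 1): 0.2, (0, 2): 1.0, (1, 2): 0.2}

        def su_ff(i, j):
            return ff[(min(i, j), max(i, j))]

        m2 = merit((0, 1), su_cf, su_ff)
        m3 = merit((0, 1, 2), su_cf, su_ff)
        assert m3 < m2

    def test_matches_hand_computed_formula(self, rng):
        su_cf = rng.uniform(0, 1, 5)
        ff = rng.uniform(0, 1, (5, 5))
        ff = (ff + ff.T) / 2
        subset = (0, 2, 4)
        k = 3
        r_cf = su_cf[list(subset)].mean()
        r_ff = np.mean([ff[0, 2], ff[0, 4], ff[2, 4]])
        expected = k * r_cf / np.sqrt(k + k * (k - 1) * r_ff)
        assert merit(subset, su_cf, ff) == pytest.approx(expected, abs=1e-12)


def _exhaustive_best(X, y):
    """Brute-force CFS optimum over all non-empty subsets (oracle)."""
    from hhtseizure.cfs import apply_cuts, mdl_discretize, symmetrical_uncertainty

    p = X.shape[1]
    cuts = [mdl_discretize(X[:, i], y) for i in range(p)]
    disc = [apply_cuts(X[:, i], cuts[i]) for i in range(p)]
    su_cf = np.array(
        [symmetrical_uncertainty(disc[i], y) if cuts[i] else 0.0 for i in range(p)]
    )
    ff = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            ff[i, j] = ff[j, i] = symmetrical_uncertainty(disc[i], disc[j])
    best_m, best_s = 0.0, ()
    for r in range(1, p + 1):
        for s in itertools.combinations(range(p), r):
            m = merit(s, su_cf, ff)
            if m > best_m + 1e-12:
                best_m, best_s = m, s
    return best_m, best_s


class TestBestFirstSelect:
    def _toy(self, rng, n=120):
        """2 informative features, 4 noise."""
        y = rng.integers(0, 2, n)
        X = rng.standard_normal((n, 6))
        X[:, 1] += 3.0 * y
        X[:, 4] -= 3.0 * y
        return X, y

    def test_selects_relevant_pair(self, rng):
        X, y = self._toy(rng)
        res = best_first_select(X, y)
        assert set(res.selected_idx) >= {1} or set(res.selected_idx) >= {4}
        assert not set(res.selected_idx) & {0, 2, 3, 5} - {1, 4}

    def test_all_noise_empty_selection(self, rng):
        X = rng.standard_normal((100, 5))
        y = rng.integers(0, 2, 100)
        res = best_first_select(X, y)
        assert res.merit < 0.1
        assert len(res.selected_idx) <= 1

    def test_perfect_feature_selected(self, rng):
        X = rng.standard_normal((80, 4))
        y = rng.integers(0, 2, 80)
        X[:, 2] = y * 10.0 + rng.normal(0, 0.1, 80)
        res = best_first_select(X, y)
        assert 2 in res.selected_idx

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((20, 3))
        with pytest.raises(ValueError, match="both classes"):
            best_first_select(X, np.zeros(20, dtype=int))

    def test_deterministic(self, rng):
        X, y = self._toy(rng)
        r1 = best_first_select(X, y)
        r2 = best_first_select(X, y)
        assert r1.selected_idx == r2.selected_idx
        assert r1.merit == r2.merit

    @pytest.mark.parametrize("p,seed", [(4, 0), (6, 1), (8, 2), (10, 3), (12, 4)])
    def test_matches_exhaustive_optimum(self, p, seed):
        """Best-first is admissible on small instances (oracle equality)."""
        rng = np.random.default_rng(seed)
        n = 100
        y = rng.integers(0, 2, n)
        X = rng.standard_normal((n, p))
        # plant a few informative columns with varying strength
        for j in range(0, p, 3):
            X[:, j] += rng.uniform(0.5, 2.5) * y
        best_m, _ = _exhaustive_best(X, y)
        res = best_first_select(X, y)
        assert res.merit == pytest.approx(best_m, abs=1e-10)

    def test_reported_merit_is_recomputable(self, rng):
        X, y = self._toy(rng)
        res = best_first_select(X, y)
        from hhtseizure.cfs import apply_cuts, mdl_discretize, symmetrical_uncertainty

        cuts = [mdl_discretize(X[:, i], y) for i in range(X.shape[1])]
        disc = [apply_cuts(X[:, i], cuts[i]) for i in range(X.shape[1])]
        su_cf = np.array(
            [symmetrical_uncertainty(d, y) if c else 0.0 for d, c in zip(disc, cuts)]
        )
        m = merit(tuple(res.selected_idx), su_cf,
                  lambda i, j: symmetrical_uncertainty(disc[i], disc[j]))
        assert m == pytest.approx(res.merit, abs=1e-12)
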