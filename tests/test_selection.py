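"""Hybrid feature selection: variance filter, scorers, union, wrapper."""

import numpy as np
import pytest

from emosda import selection as sel
from emosda.features import FeatureTable
from emosda.synthio import LabelSet


def _table(X):
    return FeatureTable(X, [f"f{i}" for i in range(X.shape[1])],
                        ["stats"] * X.shape[1])


class TestRFLV:
    def test_zero_variance_removed_threshold_kept(self, rng):
        """Strictly-below semantics: a constant column goes, a column whose
        sample variance equals the threshold exactly stays."""
        n = 50
        col = rng.normal(size=n) * 0.1
        threshold = float(np.var(col, ddof=1))
        X = np.column_stack([np.full(n, 3.0), col, rng.normal(size=n)])
        res = sel.rflv(_table(X), threshold)
        assert list(res.mask) == [False, True, True]

    def test_matches_brute_force_scan(self, rng):
        X = rng.normal(size=(40, 30)) * rng.uniform(0.01, 1.0, size=30)
        res = sel.rflv(_table(X), 0.05)
        brute = [np.var(X[:, j], ddof=1) >= 0.05 for j in range(30)]
        assert list(res.mask) == brute

    def test_idempotent(self, rng):
        X = rng.normal(size=(40, 30)) * rng.uniform(0.0, 1.0, size=30)
        t = _table(X)
        once = t.select(sel.rflv(t, 0.05).mask)
        twice = once.select(sel.rflv(once, 0.05).mask)
        assert once.names == twice.names

    def test_needs_two_instances(self):
        with pytest.raises(ValueError):
            sel.rflv(_table(np.zeros((1, 3))))


class TestScorers:
    @pytest.mark.parametrize("method", ["chi2", "mutual_info", "fisher"])
    def test_label_copy_ranks_first(self, rng, method):
        y = rng.integers(0, 2, 300)
        X = rng.normal(size=(300, 10))
        X[:, 4] = y.astype(float)
        res = sel.score_features(_table(X), LabelSet("valence", y), method)
        assert res.ranking[0] == 4

    def test_independent_feature_low_mi(self, rng):
        """A feature independent of the labels carries almost no plug-in
        mutual information at n = 2000 (permutation-null scale ~ bins/n)."""
        y = rng.integers(0, 2, 2000)
        X = rng.normal(size=(2000, 3))
        res = sel.score_features(_table(X), LabelSet("valence", y), "mutual_info")
        assert res.scores.max() < 0.02

    def test_chi2_matches_contingency_formula(self):
        """A binary feature reduces to the textbook 2x2 contingency chi2
        (with the feature totals as the chi2 column sums)."""
        y = np.array([0] * 30 + [1] * 30)
        f = np.array([1] * 20 + [0] * 10 + [1] * 5 + [0] * 25, dtype=float)
        res = sel.score_features(_table(f[:, None]), LabelSet("valence", y), "chi2")
        observed = np.array([f[y == 0].sum(), f[y == 1].sum()])
        expected = f.sum() * np.array([0.5, 0.5])
        chi2_hand = float(np.sum((observed - expected) ** 2 / expected))
        assert res.scores[0] == pytest.approx(chi2_hand)

    def test_mi_matches_plugin_formula(self, rng):
        y = rng.integers(0, 2, 400)
        x = rng.normal(size=400) + 0.8 * y
        res = sel.score_features(_table(x[:, None]), LabelSet("valence", y),
                                 "mutual_info")
        d = sel._quantile_discretize(x)
        mi = 0.0
        for dv in np.unique(d):
            for yv in (0, 1):
                pj = np.mean((d == dv) & (y == yv))
                if pj > 0:
                    mi += pj * np.log(pj / (np.mean(d == dv) * np.mean(y == yv)))
        assert res.scores[0] == pytest.approx(mi)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        with pytest.raises(ValueError):
            sel.score_features(_table(X), LabelSet("valence", np.zeros(20)), "chi2")

    def test_permutation_equivariance(self, rng):
        """Scores follow their features under column permutation."""
        y = rng.integers(0, 2, 200)
        X = rng.normal(size=(200, 6)) + y[:, None] * rng.uniform(0, 1, 6)
        perm = rng.permutation(6)
        a = sel.score_features(_table(X), LabelSet("valence", y), "fisher").scores
        b = sel.score_features(_table(X[:, perm]), LabelSet("valence", y),
                               "fisher").scores
        assert np.allclose(a[perm], b)


class TestUnionTopK:
    def _result(self, scores):
        scores = np.asarray(scores, dtype=float)
        return sel.SelectionResult(scores=scores, ranking=np.argsort(-scores,
                                   kind="stable"),
                                   mask=np.ones(len(scores), dtype=bool),
                                   method="m")

    def test_identical_rankings_union_k(self):
        a = self._result(np.arange(20)[::-1])
        u = sel.union_topk(a, self._result(np.arange(20)[::-1]), k=5)
        assert u.mask.sum() == 5

    def test_disjoint_rankings_union_2k(self):
        a = self._result(np.r_[np.arange(10, 20), np.zeros(10)])
        b = self._result(np.r_[np.zeros(10), np.arange(10, 20)])
        u = sel.union_topk(a, b, k=10)
        assert u.mask.sum() == 20

    def test_partial_overlap(self):
        scores_a = np.zeros(30)
        scores_b = np.zeros(30)
        scores_a[:10] = np.arange(10, 0, -1)     # top-10 of a: 0..9
        scores_b[5:15] = np.arange(10, 0, -1)    # top-10 of b: 5..14, overlap 5
        u = sel.union_topk(self._result(scores_a), self._result(scores_b), k=10)
        assert u.mask.sum() == 15

    def test_commutative(self, rng):
        a = self._result(rng.random(40))
        b = self._result(rng.random(40))
        assert np.array_equal(sel.union_topk(a, b, 10).mask,
                              sel.union_topk(b, a, 10).mask)

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValueError):
            sel.union_topk(self._result(np.ones(5)), self._result(np.ones(6)))


class TestForwardWrapper:
    def test_perfect_feature_selected_first(self, rng):
        y = rng.integers(0, 2, 80)
        X = rng.normal(size=(80, 8))
        X[:, 5] = y * 2.0 - 1.0
        res = sel.forward_wrapper(_table(X), LabelSet("valence", y), "dt", seed=0)
        assert res.mask[5]
        assert res.scores[5] == pytest.approx(1.0)

    def test_noise_terminates_with_few_features(self):
        rng = np.random.default_rng(42)
        y = rng.integers(0, 2, 100)
        X = rng.normal(size=(100, 10))
        res = sel.forward_wrapper(_table(X), LabelSet("valence", y), "dt", seed=0)
        assert res.mask.sum() <= 3

    def test_xor_pair_recovered_by_depth2_tree(self, rng):
        """Neither half of an XOR pair is informative alone; a depth-2
        tree on both is perfect, so the greedy search keeps the pair."""
        a = rng.integers(0, 2, 400)
        b = rng.integers(0, 2, 400)
        y = a ^ b
        X = np.column_stack([a.astype(float), b.astype(float)])
        res = sel.forward_wrapper(_table(X), LabelSet("valence", y), "dt", seed=0)
        assert res.mask[0] and res.mask[1]
        assert res.scores.max() == pytest.approx(1.0)

    def test_skip_perfect_singletons(self, rng):
        y = rng.integers(0, 2, 60)
        X = rng.normal(size=(60, 4))
        X[:, 2] = y.astype(float)
        res = sel.forward_wrapper(_table(X), LabelSet("valence", y), "dt",
                                  seed=0, skip_perfect_singletons=True)
        assert not res.mask[2]

    def test_too_many_folds_rejected(self, rng):
        X = rng.normal(size=(4, 3))
        y = np.array([0, 1, 0, 1])
        with pytest.raises(ValueError):
            sel.forward_wrapper(_table(X), LabelSet("valence", y), "dt", folds=10)
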