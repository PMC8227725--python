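"""ROC/AUROC, Youden, bootstrap, contingency, DICE, Spearman."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

import cnvpheno as c
from cnvpheno.evaluate import ContingencyTable

SCORES4 = np.array([0.1, 0.4, 0.35, 0.8])
LABELS4 = np.array([0, 0, 1, 1])


def brute_force_auroc(scores, labels):
    """Concordant-pair fraction with ties counted 1/2 — O(n^2) oracle."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        assert c.auroc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_four_point_example(self):
        # 3 of 4 positive-negative pairs concordant
        assert c.auroc(SCORES4, LABELS4) == pytest.approx(0.75)

    def test_all_ties_is_half(self):
        assert c.auroc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            c.auroc([0.1, 0.2], [1, 1])

    def test_monotone_transform_invariant(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=50)
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        assert c.auroc(np.exp(s), y) == pytest.approx(c.auroc(s, y))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rank_estimator_vs_pair_count_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        scores = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
        labels = rng.integers(0, 2, size=n)
        labels[:2] = [0, 1]
        a = c.auroc(scores, labels)
        assert a == pytest.approx(brute_force_auroc(scores, labels), abs=1e-12)
        assert a == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
        # trapezoidal area under the explicit curve agrees exactly
        assert c.roc_curve(scores, labels).auroc == pytest.approx(a, abs=1e-12)


class TestRocCurve:
    def test_point_count(self):
        r = c.roc_curve(SCORES4, LABELS4)
        assert len(r.cutoffs) == 4 + 1

    def test_endpoints(self):
        r = c.roc_curve(SCORES4, LABELS4)
        assert (r.sensitivity[0], r.specificity[0]) == (0.0, 1.0)
        assert (r.sensitivity[-1], r.specificity[-1]) == (1.0, 0.0)

    def test_sensitivity_monotone_in_cutoff(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=60)
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        r = c.roc_curve(s, y)
        assert np.all(np.diff(r.cutoffs) < 0)  # descending cutoffs
        assert np.all(np.diff(r.sensitivity) >= 0)
        assert np.all(np.diff(r.specificity) <= 0)

    def test_four_point_area(self):
        assert c.roc_curve(SCORES4, LABELS4).auroc == pytest.approx(0.75)


class TestYouden:
    def test_four_point_example(self):
        cutoff, sens, spec = c.youden_cutoff(c.roc_curve(SCORES4, LABELS4))
        assert sens + spec - 1 == pytest.approx(0.5)
        assert cutoff == pytest.approx(0.35)  # sensitivity tie-break

    def test_perfect_classifier(self):
        cutoff, sens, spec = c.youden_cutoff(c.roc_curve([1, 2, 3, 4], [0, 0, 1, 1]))
        assert (sens, spec) == (1.0, 1.0)
        assert 2 < cutoff <= 3

    def test_uninformative_all_ties(self):
        _, sens, spec = c.youden_cutoff(c.roc_curve([1, 1, 1, 1], [0, 1, 0, 1]))
        assert sens + spec - 1 == pytest.approx(0.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=40)
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        _, se1, sp1 = c.youden_cutoff(c.roc_curve(s, y))
        _, se2, sp2 = c.youden_cutoff(c.roc_curve(np.tanh(s), y))
        assert se1 + sp1 == pytest.approx(se2 + sp2)


class TestBootstrap:
    def test_perfect_separation_degenerate_interval(self):
        rng = np.random.default_rng(2)
        y = np.r_[np.zeros(100, int), np.ones(100, int)]
        s = np.r_[rng.uniform(0, 0.4, 100), rng.uniform(0.6, 1, 100)]
        assert c.bootstrap_ci(s, y, n_boot=200, seed=0) == (1.0, 1.0)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=80)
        y = rng.integers(0, 2, size=80)
        y[:2] = [0, 1]
        assert c.bootstrap_ci(s, y, n_boot=300, seed=7) == c.bootstrap_ci(
            s, y, n_boot=300, seed=7
        )

    def test_small_b_warns(self):
        with pytest.warns(UserWarning, match="small"):
            c.bootstrap_ci([1, 2, 3, 4], [0, 0, 1, 1], n_boot=50, seed=0)

    def test_contains_point_estimate(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=120)
        y = (s + rng.normal(0, 1.5, 120) > 0).astype(int)
        y[:2] = [0, 1]
        lo, hi = c.bootstrap_ci(s, y, n_boot=500, seed=1)
        assert lo <= c.auroc(s, y) <= hi


class TestContingency:
    def test_four_point_example_at_035(self):
        t = c.contingency(SCORES4, LABELS4, 0.35)
        assert (t.tp, t.fp, t.fn, t.tn) == (2, 1, 0, 1)

    def test_cutoff_above_max(self):
        t = c.contingency(SCORES4, LABELS4, 2.0)
        assert t.tp == 0 and t.fp == 0

    def test_counts_partition(self):
        rng = np.random.default_rng(6)
        s = rng.normal(size=33)
        y = rng.integers(0, 2, size=33)
        t = c.contingency(s, y, 0.1)
        assert t.n == 33

    def test_nonfinite_cutoff_rejected(self):
        with pytest.raises(ValueError):
            c.contingency(SCORES4, LABELS4, np.inf)


class TestSensSpec:
    def test_occult_vs_classic_development_counts(self):
        # 341 true / 41 missed occult calls; 32 false calls over 163 negatives
        sens, spec = c.sens_spec(ContingencyTable(tp=341, fn=41, fp=32, tn=131))
        assert round(sens, 2) == 0.89
        assert sens == pytest.approx(341 / 382)
        assert spec == pytest.approx(131 / 163)

    def test_external_validation_counts(self):
        sens, spec = c.sens_spec(ContingencyTable(tp=102, fn=24, fp=7, tn=32))
        assert round(sens, 2) == 0.81
        assert sens == pytest.approx(102 / 126)
        assert spec == pytest.approx(32 / 39)

    def test_trivial_perfect(self):
        assert c.sens_spec(ContingencyTable(1, 0, 0, 1)) == (1.0, 1.0)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            c.sens_spec(ContingencyTable(0, 1, 0, 1))


class TestDice:
    def _mask(self, flat):
        geom = c.VoxelGeometry(1, 1, 8)
        return c.PathologyMask(geom, np.array(flat, dtype=np.uint8).reshape(1, 1, 8))

    def test_identical_masks(self):
        m = self._mask([1, 1, 0, 0, 2, 0, 0, 0])
        assert c.dice(m, m, "IRF") == 1.0

    def test_disjoint(self):
        a = self._mask([1, 1, 0, 0, 0, 0, 0, 0])
        b = self._mask([0, 0, 1, 1, 0, 0, 0, 0])
        assert c.dice(a, b, "IRF") == 0.0

    def test_half_overlap(self):
        a = self._mask([1, 1, 1, 1, 0, 0, 0, 0])
        b = self._mask([0, 0, 1, 1, 1, 1, 0, 0])
        assert c.dice(a, b, "IRF") == 0.5

    def test_symmetry(self):
        a = self._mask([1, 1, 1, 0, 0, 0, 0, 0])
        b = self._mask([0, 1, 1, 1, 1, 0, 0, 0])
        assert c.dice(a, b, "IRF") == c.dice(b, a, "IRF")

    def test_both_empty_convention(self):
        a = self._mask([0] * 8)
        assert c.dice(a, a, "SHRM") == 1.0
        assert c.dice(a, a, "SHRM", both_empty=0.0) == 0.0

    def test_geometry_mismatch(self):
        a = self._mask([0] * 8)
        geom = c.VoxelGeometry(1, 2, 8)
        b = c.PathologyMask(geom, np.zeros((1, 2, 8), dtype=np.uint8))
        with pytest.raises(ValueError):
            c.dice(a, b, "IRF")


class TestSpearman:
    def test_perfect_and_reversed(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert c.spearman(x, [2.0, 3.0, 8.0, 20.0]) == pytest.approx(1.0)
        assert c.spearman(x, [20.0, 8.0, 3.0, 2.0]) == pytest.approx(-1.0)

    def test_midrank_ties_match_rank_then_pearson(self):
        x = np.array([1.0, 2.0, 2.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert c.spearman(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            c.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            c.spearman([1.0, 2.0], [1.0, 2.0])
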