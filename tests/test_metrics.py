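"""Transferability and mismatch statistics: AUC, Swets grades, IE,
TI_H/TI_W, equal sensitivity-specificity threshold, RRS, OI, t-tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nichetransfer as nt
from nichetransfer.metrics import (BinaryRange, EvaluationRecord, auc,
                                   binary_range, equal_ss_threshold,
                                   overlap_index, paired_t,
                                   relative_range_size, swets_grade,
                                   transferability_indices, two_sample_t)


def auc_pair_counting(p, b):
    """Brute-force oracle: count concordant pairs directly."""
    wins = sum((x > y) + 0.5 * (x == y) for x in p for y in b)
    return wins / (len(p) * len(b))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.2, 0.1]) == 1.0

    def test_all_ties(self):
        assert auc([0.5] * 4, [0.5] * 6) == 0.5

    def test_enumerated_example(self):
        assert auc([0.6, 0.4], [0.5, 0.3]) == pytest.approx(0.75)

    def test_matches_pair_counting_oracle_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.normal(0.2, 1, rng.integers(2, 30))
            b = rng.normal(0, 1, rng.integers(2, 30))
            assert auc(p, b) == pytest.approx(auc_pair_counting(p, b),
                                              abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            auc([], [0.1])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=20),
           st.lists(st.floats(-5, 5), min_size=2, max_size=20),
           st.floats(0.1, 3.0))
    def test_monotone_transform_invariance(self, p, b, k):
        # round so distinct scores stay distinct under the transform
        p = np.round(np.asarray(p), 3)
        b = np.round(np.asarray(b), 3)
        base = auc(p, b)
        f = lambda x: k * np.asarray(x) + np.asarray(x) ** 3
        assert auc(f(p), f(b)) == pytest.approx(base, abs=1e-12)


class TestSwetsGrade:
    @pytest.mark.parametrize("a,grade", [
        (0.95, "excellent"), (0.9, "good"), (0.85, "good"), (0.8, "fair"),
        (0.75, "fair"), (0.7, "poor"), (0.65, "poor"), (0.6, "fail"),
        (0.3, "fail"), (1.0, "excellent"),
    ])
    def test_bins(self, a, grade):
        assert swets_grade(a) == grade

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            swets_grade(1.2)


class TestInternalEvaluation:
    @pytest.mark.parametrize("tr,te,ie,diff", [
        (0.9, 0.9, 1.0, 0.0),
        (0.9, 0.81, 0.9, 0.09),
        (0.8, 0.88, 1.1, -0.08),   # IE > 1: over-parameterization flag
    ])
    def test_formulas(self, tr, te, ie, diff):
        got = nt.internal_evaluation(tr, te)
        assert got[0] == pytest.approx(ie)
        assert got[1] == pytest.approx(diff)

    def test_zero_train_auc_rejected(self):
        with pytest.raises(ValueError):
            nt.internal_evaluation(0.0, 0.5)


class TestTransferabilityIndices:
    def test_identity(self):
        rec = EvaluationRecord(0.9, 0.85)
        ti_h, ti_w = transferability_indices(rec, rec)
        assert ti_h == 1.0 and ti_w == 1.0

    def test_ti_h_arithmetic(self):
        im = EvaluationRecord(0.9, 0.9)
        em = EvaluationRecord(0.9, 0.85)
        ti_h, _ = transferability_indices(im, em)
        assert ti_h == pytest.approx(0.85 / 0.9)

    def test_ti_w_arithmetic(self):
        im = EvaluationRecord(0.9, 0.88)    # AUC_Diff = 0.02
        em = EvaluationRecord(0.9, 0.85)    # AUC_Diff = 0.05
        _, ti_w = transferability_indices(im, em)
        assert ti_w == pytest.approx(0.95 / 0.98)


class TestEqualSsThreshold:
    def test_separable_case(self):
        t = equal_ss_threshold([0.8, 0.7], [0.3, 0.2])
        assert t == 0.7
        # sens = spec = 1 at the returned threshold
        assert all(p >= t for p in [0.8, 0.7])
        assert all(a < t for a in [0.3, 0.2])

    def test_enumerated_six_candidates(self):
        t = equal_ss_threshold([0.9, 0.6, 0.55], [0.5, 0.4, 0.35])
        assert t == 0.55

    def test_identical_multisets_balance_near_median(self):
        """presences == absences: exhaustive-scan oracle confirms the
        minimizer of |sens - spec|."""
        rng = np.random.default_rng(1)
        scores = rng.normal(size=31)
        t = equal_ss_threshold(scores, scores)
        p = np.sort(scores)

        def gap(c):
            sens = (p >= c).mean()
            spec = (p < c).mean()
            return abs(sens - spec)

        best = min(gap(c) for c in np.unique(scores))
        assert gap(t) == pytest.approx(best)


class TestRangeMismatch:
    def grid(self, ones):
        g = np.zeros((4, 4), bool)
        for r, c in ones:
            g[r, c] = True
        return g

    def test_rrs_equal_areas(self):
        a = BinaryRange(self.grid([(0, 0), (1, 1)]), 0.5)
        b = BinaryRange(self.grid([(2, 2), (3, 3)]), 0.5)
        assert relative_range_size(a, b) == 0.0

    def test_rrs_over_and_under_prediction(self):
        im = BinaryRange(self.grid([(0, 0)]), 0.5)
        em = BinaryRange(self.grid([(0, 0), (1, 1)]), 0.5)
        assert relative_range_size(im, em) == pytest.approx(1.0)
        assert relative_range_size(em, im) == pytest.approx(-1.0)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(1, 15), st.integers(1, 15))
    def test_rrs_antisymmetry(self, n1, n2):
        rng = np.random.default_rng(n1 * 31 + n2)
        g1 = self.grid([])
        g2 = self.grid([])
        g1.ravel()[rng.choice(16, n1, replace=False)] = True
        g2.ravel()[rng.choice(16, n2, replace=False)] = True
        a, b = BinaryRange(g1, 0.5), BinaryRange(g2, 0.5)
        assert relative_range_size(a, b) == pytest.approx(
            -relative_range_size(b, a))

    def test_oi_identity_disjoint_superset(self):
        im = BinaryRange(self.grid([(0, 0), (1, 1)]), 0.5)
        disjoint = BinaryRange(self.grid([(2, 2)]), 0.5)
        superset = BinaryRange(self.grid([(0, 0), (1, 1), (2, 2)]), 0.5)
        assert overlap_index(im, im) == 1.0
        assert overlap_index(im, disjoint) == 0.0
        assert overlap_index(im, superset) == 1.0   # blind to over-prediction

    def test_rrs_zero_and_oi_one_iff_equal_maps(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            g1 = rng.random((5, 5)) < 0.4
            g2 = rng.random((5, 5)) < 0.4
            if not g1.any() or not g2.any():
                continue
            a, b = BinaryRange(g1, 0.5), BinaryRange(g2, 0.5)
            same = np.array_equal(g1, g2)
            both = (relative_range_size(a, b) == 0.0
                    and overlap_index(a, b) == 1.0)
            assert both == same

    def test_zero_area_rejected(self):
        empty = BinaryRange(np.zeros((2, 2), bool), 0.5)
        full = BinaryRange(np.ones((2, 2), bool), 0.5)
        with pytest.raises(ValueError):
            relative_range_size(empty, full)
        with pytest.raises(ValueError):
            overlap_index(empty, full)

    def test_binary_range_thresholding(self):
        scores = np.array([[0.1, 0.6], [0.5, 0.9]])
        br = binary_range(scores, 0.5)
        assert br.area == 3


class TestTTests:
    def test_identical_pairs(self):
        t, p, df = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0 and df == 2

    def test_constant_nonzero_differences(self):
        with pytest.warns(UserWarning, match="zero variance"):
            t, p, df = paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert np.isinf(t) and t > 0
        assert p == 0.0

    def test_constant_negative_differences(self):
        with pytest.warns(UserWarning):
            t, p, _ = paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert np.isinf(t) and t < 0

    def test_two_sample_welch(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 30)
        b = rng.normal(1, 2, 40)
        t, p, df = two_sample_t(a, b)
        assert t < 0 and 0 < p < 0.05
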