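"""FAR/FRR/EER computation, fold statistics, TOST equivalence, reporting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import stdtr

from rrverify.evaluation import (
    EvalReport,
    TOSTConfig,
    classify_pair,
    compute_eer,
    confusion_matrix,
    eer_from_scores,
    far_frr_curves,
    folded_eval,
    score_distribution_report,
    tost_equivalence,
)


def brute_force_eer(scores, labels):
    """Independent oracle: dense threshold scan + linear interpolation at the
    FAR-FRR sign change, written with explicit loops."""
    pos = sorted(s for s, y in zip(scores, labels) if y == 1)
    neg = sorted(s for s, y in zip(scores, labels) if y == 0)
    cands = sorted(set(scores)) + [max(max(scores), 1.0) + 1e-9]
    cands = [-1.0] + cands
    prev = None
    for t in cands:
        far = sum(1 for s in neg if s >= t) / len(neg)
        frr = sum(1 for s in pos if s < t) / len(pos)
        d = far - frr
        if d == 0:
            return far
        if prev is not None and prev[1] > 0 > d:
            far0, d0 = prev[0], prev[1]
            alpha = d0 / (d0 - d)
            return far0 + alpha * (far - far0)
        prev = (far, d)
    raise AssertionError("no crossing found")


def welch_tost_oracle(a, b, margin):
    """Textbook Welch two-one-sided-tests, via the independent stdtr route."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    se = np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    d = b.mean() - a.mean()
    p_lower = 1.0 - stdtr(df, (d + margin) / se)
    p_upper = stdtr(df, (d - margin) / se)
    return p_lower, p_upper


class TestClassify:
    def test_accept_reject_and_tie(self):
        assert classify_pair(0.9, 0.5) == "accept"
        assert classify_pair(-0.2, 0.5) == "reject"
        assert classify_pair(0.5, 0.5) == "accept"  # ties accept

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            classify_pair(0.0, 1.5)


class TestCurves:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.1, 0.2])
        labels = np.array([1, 1, 0, 0])
        t, far, frr = far_frr_curves(scores, labels)
        at = np.searchsorted(t, 0.5)  # any threshold between the classes
        assert far[at] == 0.0 and frr[at] == 0.0
        assert compute_eer(far, frr, t)[0] == 0.0

    def test_counting_example_at_threshold(self):
        # positives {0.9, 0.3}, negatives {0.5, 0.1}: at t=0.4, one negative
        # accepted and one positive rejected
        scores = np.array([0.9, 0.3, 0.5, 0.1])
        labels = np.array([1, 1, 0, 0])
        far_04 = np.mean(scores[labels == 0] >= 0.4)
        frr_04 = np.mean(scores[labels == 1] < 0.4)
        assert far_04 == 0.5 and frr_04 == 0.5
        eer, thr = eer_from_scores(scores, labels)
        assert eer == 0.5
        assert 0.3 <= thr <= 0.5

    def test_far_non_increasing_frr_non_decreasing(self, rng):
        scores = rng.uniform(-1, 1, 400)
        labels = rng.integers(0, 2, 400)
        t, far, frr = far_frr_curves(scores, labels)
        assert np.all(np.diff(far) <= 0)
        assert np.all(np.diff(frr) >= 0)

    def test_constant_scores_give_half(self):
        scores = np.zeros(200)
        labels = np.array([1, 0] * 100)
        assert eer_from_scores(scores, labels)[0] == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            far_frr_curves(np.array([0.1, 0.2]), np.array([1, 1]))


class TestEEROracle:
    @pytest.mark.parametrize("n, seed", [(40, 0), (500, 1), (5000, 2)])
    def test_matches_brute_force_scan(self, n, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        scores = np.where(labels == 1, rng.normal(0.3, 0.4, n), rng.normal(-0.2, 0.4, n))
        scores = np.clip(scores, -1, 1)
        eer, _ = eer_from_scores(scores, labels)
        assert eer == pytest.approx(brute_force_eer(scores.tolist(), labels.tolist()), abs=1e-9)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_eer_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        scores = np.clip(rng.normal(0.2 * labels, 0.3), -1, 1)
        base = eer_from_scores(scores, labels)[0]
        for transform in (lambda x: np.tanh(2 * x), lambda x: x**3):
            assert eer_from_scores(transform(scores), labels)[0] == pytest.approx(base, abs=1e-12)


class TestFoldedEval:
    def test_reports_fold_eers_mean_std_cv(self, rng):
        n = 500
        labels = rng.integers(0, 2, n)
        scores = np.clip(rng.normal(0.5 * labels - 0.2, 0.3), -1, 1)
        report = folded_eval(scores, labels, n_folds=5, rng=rng)
        assert len(report.fold_eers) == 5
        assert report.mean_eer == pytest.approx(np.mean(report.fold_eers))
        assert report.std_eer == pytest.approx(np.std(report.fold_eers, ddof=1))
        assert report.cv == pytest.approx(report.std_eer / report.mean_eer)
        assert report.confusion is not None and report.confusion.sum() == n

    def test_cv_definition(self):
        # sigma/mu: mean 0.2 with std 0.02 gives CV 0.1
        fold_eers = np.array([0.2, 0.2, 0.2]) + np.array([-1, 0, 1]) * 0.02
        assert np.std(fold_eers, ddof=1) / np.mean(fold_eers) == pytest.approx(0.1)

    def test_folds_partition_all_pairs(self, rng):
        n = 100
        labels = np.array([0, 1] * 50)
        scores = np.clip(rng.normal(0.4 * labels, 0.2), -1, 1)
        report = folded_eval(scores, labels, n_folds=4, rng=rng)
        assert len(report.fold_eers) == 4

    def test_confusion_orientation_rows_truth(self):
        scores = np.array([0.9, 0.1, 0.9, 0.1])
        labels = np.array([1, 1, 0, 0])
        C = confusion_matrix(scores, labels, threshold=0.5)
        # row 0 = impostor truth: one rejected (TN), one accepted (FA)
        assert C.tolist() == [[1, 1], [1, 1]]


class TestTOST:
    def test_matches_independent_welch_oracle(self, rng):
        for _ in range(20):
            a = rng.normal(0.2, 0.02, 5)
            b = rng.normal(0.21, 0.03, 5)
            margin = float(rng.uniform(0.01, 0.2))
            cfg = TOSTConfig(margin=margin)
            p_lo, p_up, _ = tost_equivalence(a, b, cfg)
            o_lo, o_up = welch_tost_oracle(a, b, margin)
            assert p_lo == pytest.approx(o_lo, abs=1e-9)
            assert p_up == pytest.approx(o_up, abs=1e-9)

    def test_same_distribution_wide_margin_is_equivalent(self, rng):
        a = rng.normal(0.2, 0.01, 8)
        b = rng.normal(0.2, 0.01, 8)
        _, _, eq = tost_equivalence(a, b, TOSTConfig(margin=0.5))
        assert eq

    def test_large_shift_is_not_equivalent(self, rng):
        a = rng.normal(0.1, 0.01, 8)
        b = rng.normal(0.45, 0.01, 8)
        _, _, eq = tost_equivalence(a, b, TOSTConfig(margin=0.05))
        assert not eq

    def test_margin_to_infinity_drives_p_to_zero(self, rng):
        a = rng.normal(0.2, 0.02, 5)
        b = rng.normal(0.25, 0.02, 5)
        p_lo, p_up, eq = tost_equivalence(a, b, TOSTConfig(margin=1e6))
        assert p_lo < 1e-12 and p_up < 1e-12 and eq

    def test_default_margin_is_three_reference_sigmas(self, rng):
        a = rng.normal(0.2, 0.02, 6)
        b = a + 0.001
        got = tost_equivalence(a, b, TOSTConfig())
        explicit = tost_equivalence(a, b, TOSTConfig(margin=3 * np.std(a, ddof=1)))
        assert got == explicit

    def test_sum_rule_vs_max_rule(self, rng):
        a = rng.normal(0.2, 0.03, 4)
        b = rng.normal(0.22, 0.03, 4)
        margin = 0.06
        p_lo, p_up, eq_sum = tost_equivalence(a, b, TOSTConfig(margin=margin))
        _, _, eq_max = tost_equivalence(a, b, TOSTConfig(margin=margin, decision_rule="max"))
        assert eq_sum == ((p_lo + p_up) < 0.05)
        assert eq_max == (max(p_lo, p_up) < 0.05)

    def test_zero_variance_both_groups_is_degenerate(self):
        with pytest.raises(ValueError):
            tost_equivalence([0.2, 0.2], [0.3, 0.3], TOSTConfig(margin=0.1))


class TestReport:
    def test_score_distribution_separates_classes_and_round_trips(self, tmp_path):
        scores = np.array([0.9, 0.8, -0.5, -0.6])
        labels = np.array([1, 1, 0, 0])
        rep1 = score_distribution_report(scores, labels)
        assert max(rep1["impostor_scores"]) < rep1["threshold"] <= min(rep1["genuine_scores"])
        rep2 = score_distribution_report(scores, labels)
        assert rep1 == rep2

    def test_json_and_csv_serialization(self, tmp_path, rng):
        labels = np.array([0, 1] * 40)
        scores = np.clip(rng.normal(0.4 * labels, 0.2), -1, 1)
        report = folded_eval(scores, labels, n_folds=4, rng=rng)
        report.to_json(str(tmp_path / "r.json"))
        report.curves_to_csv(str(tmp_path / "r.csv"))
        import json

        loaded = json.load(open(tmp_path / "r.json"))
        assert loaded["eer"] == pytest.approx(report.eer)
        rows = np.loadtxt(tmp_path / "r.csv", delimiter=",", skiprows=1)
        assert rows.shape[1] == 3
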