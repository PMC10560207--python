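"""Verification metrics: FAR/FRR curves, EER, fold-wise CV, and TOST.

Conventions: the positive class is "genuine" (same subject).  A pair is
accepted when its similarity score is at or above the acceptance threshold.
FAR is the fraction of impostor pairs accepted; FRR the fraction of genuine
pairs rejected.  The equal error rate (EER) is the common value of FAR and
FRR where the two curves cross, obtained by linear interpolation between
the bracketing thresholds when no candidate threshold gives an exact tie.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

_RETRIES = 20


@dataclass(frozen=True)
class TOSTConfig:
    """Equivalence-test settings for age robustness.

    ``margin`` is expressed in EER units; when built from reference-age fold
    EERs the conventional choice is three times their standard deviation.
    ``decision_rule`` selects the paper-style sum rule (p1 + p2 < alpha) or
    the conventional max rule (max(p1, p2) < alpha).
    """

    alpha: float = 0.05
    margin: Optional[float] = None  # None: 3 * std of the reference samples
    reference_age: float = 6.0
    decision_rule: str = "sum"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.margin is not None and self.margin <= 0:
            raise ValueError("margin must be positive")
        if self.decision_rule not in ("sum", "max"):
            raise ValueError("decision_rule must be 'sum' or 'max'")


@dataclass
class EvalReport:
    """Threshold sweep plus fold statistics for one scored test set."""

    thresholds: np.ndarray
    far_curve: np.ndarray
    frr_curve: np.ndarray
    eer: float
    eer_threshold: float
    fold_eers: List[float] = field(default_factory=list)
    mean_eer: float = float("nan")
    std_eer: float = float("nan")
    cv: float = float("nan")
    confusion: Optional[np.ndarray] = None  # rows: truth (neg, pos); cols: prediction

    def to_dict(self) -> Dict:
        return {
            "eer": self.eer,
            "eer_threshold": self.eer_threshold,
            "fold_eers": list(self.fold_eers),
            "mean_eer": self.mean_eer,
            "std_eer": self.std_eer,
            "cv": self.cv,
            "thresholds": self.thresholds.tolist(),
            "far_curve": self.far_curve.tolist(),
            "frr_curve": self.frr_curve.tolist(),
            "confusion": None if self.confusion is None else self.confusion.tolist(),
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def curves_to_csv(self, path: str) -> None:
        arr = np.column_stack([self.thresholds, self.far_curve, self.frr_curve])
        np.savetxt(path, arr, delimiter=",", header="threshold,far,frr", comments="")


def classify_pair(score: float, threshold: float) -> str:
    """Accept (same subject) iff score >= threshold; ties accept."""
    if not (-1.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [-1, 1]")
    return "accept" if score >= threshold else "reject"


def _split_scores(scores: np.ndarray, labels: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal shape")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both genuine and impostor pairs are required")
    return pos, neg


def far_frr_curves(
    scores: np.ndarray, labels: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """FAR and FRR as functions of the acceptance threshold.

    Candidate thresholds are the sorted unique scores with sentinels at -1
    (accept everything) and just above the top score (reject everything), so
    the FAR - FRR sign change is always bracketed.
    """
    pos, neg = _split_scores(scores, labels)
    uniq = np.unique(np.concatenate([pos, neg]))
    top = np.nextafter(max(uniq[-1], 1.0), np.inf)
    thresholds = np.concatenate([[-1.0], uniq, [top]])
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    # accepted iff score >= t
    far = 1.0 - np.searchsorted(neg_sorted, thresholds, side="left") / neg.size
    frr = np.searchsorted(pos_sorted, thresholds, side="left") / pos.size
    return thresholds, far, frr


def compute_eer(
    far: np.ndarray, frr: np.ndarray, thresholds: np.ndarray
) -> Tuple[float, float]:
    """EER at the FAR/FRR crossing, linearly interpolated between candidates."""
    far = np.asarray(far, dtype=float)
    frr = np.asarray(frr, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    d = far - frr  # non-increasing in the threshold
    exact = np.flatnonzero(d == 0.0)
    if exact.size:
        i = int(exact[0])
        return float(far[i]), float(thresholds[i])
    below = np.flatnonzero(d < 0.0)
    if not below.size:  # FAR stays above FRR everywhere (degenerate input)
        i = int(np.argmin(np.abs(d)))
        return float((far[i] + frr[i]) / 2.0), float(thresholds[i])
    j = int(below[0])
    i = j - 1
    if i < 0:
        return float((far[j] + frr[j]) / 2.0), float(thresholds[j])
    alpha = d[i] / (d[i] - d[j])
    eer = far[i] + alpha * (far[j] - far[i])
    thr = thresholds[i] + alpha * (thresholds[j] - thresholds[i])
    return float(eer), float(thr)


def eer_from_scores(scores: np.ndarray, labels: np.ndarray) -> Tuple[float, float]:
    """Convenience wrapper: sweep thresholds and return (EER, EER threshold)."""
    t, far, frr = far_frr_curves(scores, labels)
    return compute_eer(far, frr, t)


def confusion_matrix(scores: np.ndarray, labels: np.ndarray, threshold: float) -> np.ndarray:
    """2x2 counts at a threshold; rows = ground truth (0, 1), cols = prediction."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = (scores >= threshold).astype(int)
    out = np.zeros((2, 2), dtype=int)
    for t, p in ((0, 0), (0, 1), (1, 0), (1, 1)):
        out[t, p] = int(np.sum((labels == t) & (pred == p)))
    return out


def folded_eval(
    scores: np.ndarray,
    labels: np.ndarray,
    n_folds: int = 5,
    rng: Optional[np.random.Generator] = None,
    threshold: Optional[float] = None,
) -> EvalReport:
    """Overall curves plus per-fold EERs over a random disjoint partition.

    Reports mean, standard deviation (sample, ddof=1) and the coefficient of
    variation CV = σ/μ of the fold EERs.  A partition leaving any fold with
    a single class is redrawn a bounded number of times.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _split_scores(scores, labels)  # validates both classes present
    rng = rng if rng is not None else np.random.default_rng(0)
    n = scores.size
    if n < 2 * n_folds:
        raise ValueError("not enough scored pairs for the requested folds")

    fold_ids = None
    for _ in range(_RETRIES):
        perm = rng.permutation(n)
        cand = np.empty(n, dtype=int)
        cand[perm] = np.arange(n) % n_folds
        ok = all(
            len(np.unique(labels[cand == k])) == 2 for k in range(n_folds)
        )
        if ok:
            fold_ids = cand
            break
    if fold_ids is None:
        raise ValueError("could not build folds containing both classes")

    fold_eers = [
        eer_from_scores(scores[fold_ids == k], labels[fold_ids == k])[0]
        for k in range(n_folds)
    ]
    thresholds, far, frr = far_frr_curves(scores, labels)
    eer, eer_thr = compute_eer(far, frr, thresholds)
    mean = float(np.mean(fold_eers))
    std = float(np.std(fold_eers, ddof=1))
    cv = std / mean if mean > 0 else float("nan")
    chosen = eer_thr if threshold is None else threshold
    return EvalReport(
        thresholds=thresholds,
        far_curve=far,
        frr_curve=frr,
        eer=eer,
        eer_threshold=eer_thr,
        fold_eers=[float(e) for e in fold_eers],
        mean_eer=mean,
        std_eer=std,
        cv=float(cv),
        confusion=confusion_matrix(scores, labels, chosen),
    )


def tost_equivalence(
    eer_samples_ref: Sequence[float],
    eer_samples_test: Sequence[float],
    config: TOSTConfig = TOSTConfig(),
) -> Tuple[float, float, bool]:
    """Two one-sided Welch t-tests of equivalence within ±margin.

    Tests H0: |μ_test - μ_ref| >= margin against equivalence, using unpaired
    t statistics with unequal variances (Welch-Satterthwaite degrees of
    freedom).  Equivalence is declared when p_lower + p_upper < alpha (sum
    rule) or max(p_lower, p_upper) < alpha (max rule).
    """
    a = np.asarray(eer_samples_ref, dtype=float)
    b = np.asarray(eer_samples_test, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two EER samples per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise ValueError("degenerate test: zero variance in both groups")
    margin = config.margin
    if margin is None:
        sd = float(a.std(ddof=1))
        if sd == 0.0:
            raise ValueError("reference group has zero spread; supply an explicit margin")
        margin = 3.0 * sd
    se = np.sqrt(va / a.size + vb / b.size)
    df = (va / a.size + vb / b.size) ** 2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    d = b.mean() - a.mean()
    # H0_lower: d <= -margin (alt: d > -margin); H0_upper: d >= +margin
    t_lower = (d + margin) / se
    t_upper = (d - margin) / se
    p_lower = float(stats.t.sf(t_lower, df))
    p_upper = float(stats.t.cdf(t_upper, df))
    if config.decision_rule == "sum":
        equivalent = (p_lower + p_upper) < config.alpha
    else:
        equivalent = max(p_lower, p_upper) < config.alpha
    return p_lower, p_upper, bool(equivalent)


def score_distribution_report(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: Optional[float] = None,
    n_bins: int = 40,
    plot_path: Optional[str] = None,
) -> Dict:
    """Per-class score histograms and the decision boundary (pure reporting).

    A perfect verifier shows the genuine and impostor distributions fully on
    opposite sides of the threshold; overlap quantifies confusability.
    Optionally renders the two histograms with the boundary to ``plot_path``.
    """
    pos, neg = _split_scores(scores, labels)
    if threshold is None:
        threshold = eer_from_scores(scores, labels)[1]
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    report = {
        "threshold": float(threshold),
        "bin_edges": edges.tolist(),
        "genuine_counts": np.histogram(pos, bins=edges)[0].tolist(),
        "impostor_counts": np.histogram(neg, bins=edges)[0].tolist(),
        "genuine_scores": np.sort(pos).tolist(),
        "impostor_scores": np.sort(neg).tolist(),
    }
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 3.5))
        ax.hist(neg, bins=edges, alpha=0.6, label="impostor (y=0)")
        ax.hist(pos, bins=edges, alpha=0.6, label="genuine (y=1)")
        ax.axvline(threshold, color="red", linestyle="--", label="decision boundary")
        ax.set_xlabel("cosine similarity")
        ax.set_ylabel("pairs")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return report
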