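"""Window balancing, labeled pair construction, CD/PD splits and batching.

Two evaluation protocols are supported.  Complete dataset (CD): every
subject contributes windows to both training and testing, so the verifier is
tested on unseen windows of known subjects.  Partial dataset (PD): training
and testing subject sets are disjoint, testing generalization to entirely
unseen individuals.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from rrverify.types import BASAL, HeartbeatWindow, WindowPair

CD = "CD"
PD = "PD"


@dataclass(frozen=True)
class SplitSpec:
    """How to partition windows (CD) or subjects (PD) into train/test."""

    protocol: str = CD
    train_fraction: float = 0.8
    seed: int = 0
    val_fraction: float = 0.0  # PD only: subject-disjoint validation share of train

    def __post_init__(self) -> None:
        if self.protocol not in (CD, PD):
            raise ValueError(f"protocol must be {CD!r} or {PD!r}")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if not (0.0 <= self.val_fraction < 1.0):
            raise ValueError("val_fraction must lie in [0, 1)")


def _by_subject(windows: Iterable[HeartbeatWindow]) -> Dict[str, List[HeartbeatWindow]]:
    groups: Dict[str, List[HeartbeatWindow]] = defaultdict(list)
    for w in windows:
        groups[w.subject_id].append(w)
    return groups


def balance_window_counts(windows: Sequence[HeartbeatWindow]) -> List[HeartbeatWindow]:
    """Equalize window counts across subjects.

    The subject with the fewest basal windows defines N; every subject keeps
    its first N windows (by window index) in each condition it has.  A
    subject without any basal window is an error.
    """
    if not windows:
        return []
    groups: Dict[Tuple[str, str], List[HeartbeatWindow]] = defaultdict(list)
    subjects = set()
    for w in windows:
        subjects.add(w.subject_id)
        groups[(w.subject_id, w.condition)].append(w)
    basal_counts = {s: len(groups.get((s, BASAL), [])) for s in subjects}
    missing = sorted(s for s, c in basal_counts.items() if c == 0)
    if missing:
        raise ValueError(f"subject(s) without basal windows: {missing}")
    n = min(basal_counts.values())
    out: List[HeartbeatWindow] = []
    for key in sorted(groups):
        kept = sorted(groups[key], key=lambda w: w.window_index)[:n]
        out.extend(kept)
    return out


def split_cd(
    windows: Sequence[HeartbeatWindow], spec: SplitSpec
) -> Tuple[List[HeartbeatWindow], List[HeartbeatWindow]]:
    """Per-subject window split at train_fraction (default 80%-20%).

    The test share is rounded up so every subject with at least one window
    contributes at least one test window; a subject with a single window
    lands entirely in test (its positive pair duplicates the window).
    """
    if spec.protocol != CD:
        raise ValueError("split_cd requires protocol CD")
    rng = np.random.default_rng(spec.seed)
    train: List[HeartbeatWindow] = []
    test: List[HeartbeatWindow] = []
    for subject in sorted(_by_subject(windows)):
        group = sorted(_by_subject(windows)[subject], key=lambda w: (w.condition, w.window_index))
        order = rng.permutation(len(group))
        n_test = max(1, math.ceil(len(group) * (1.0 - spec.train_fraction)))
        test_idx = set(order[:n_test].tolist())
        for i, w in enumerate(group):
            (test if i in test_idx else train).append(w)
    return train, test


def split_pd(
    subjects: Sequence[str], spec: SplitSpec
) -> Tuple[List[str], List[str]]:
    """Disjoint subject-level split at train_fraction (e.g. 30 -> 24 + 6).

    When ``val_fraction`` > 0, a subject-disjoint validation slice is carved
    out of the training side; it is returned appended as a third element via
    :func:`split_pd_with_validation` — this function returns train/test only.
    """
    if spec.protocol != PD:
        raise ValueError("split_pd requires protocol PD")
    uniq = sorted(set(subjects))
    if len(uniq) < 2:
        raise ValueError("PD split needs at least two subjects")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(uniq))
    n_train = int(round(len(uniq) * spec.train_fraction))
    n_train = min(max(n_train, 1), len(uniq) - 1)
    train = sorted(uniq[i] for i in order[:n_train])
    test = sorted(uniq[i] for i in order[n_train:])
    return train, test


def split_pd_with_validation(
    subjects: Sequence[str], spec: SplitSpec
) -> Tuple[List[str], List[str], List[str]]:
    """PD split with an optional subject-disjoint validation slice."""
    train, test = split_pd(subjects, spec)
    if spec.val_fraction <= 0.0 or len(train) < 2:
        return train, [], test
    rng = np.random.default_rng(spec.seed + 1)
    order = rng.permutation(len(train))
    n_val = min(max(int(round(len(train) * spec.val_fraction)), 1), len(train) - 1)
    val = sorted(train[i] for i in order[:n_val])
    kept = sorted(train[i] for i in order[n_val:])
    return kept, val, test


def enumerate_pairs(
    windows: Sequence[HeartbeatWindow],
    condition_policy: str = "same",
    rng: Optional[np.random.Generator] = None,
    max_positive_pairs: Optional[int] = None,
) -> List[WindowPair]:
    """Build labeled pairs: all same-subject combinations plus matched negatives.

    Positive pairs are all distinct-window combinations within a subject; a
    subject with a single window contributes the duplicated pair (w, w).
    Negative pairs are sampled uniformly over cross-subject window pairs,
    without replacement until the space is exhausted and with replacement
    after, to match the positive count.  Under ``condition_policy='same'``
    both members of every pair share the recording condition.
    """
    if condition_policy not in ("same", "mixed"):
        raise ValueError("condition_policy must be 'same' or 'mixed'")
    if len(windows) < 2:
        raise ValueError("need at least two windows to build pairs")
    rng = rng if rng is not None else np.random.default_rng(0)

    def pool_key(w: HeartbeatWindow) -> Tuple:
        return (w.subject_id, w.condition) if condition_policy == "same" else (w.subject_id,)

    pools: Dict[Tuple, List[HeartbeatWindow]] = defaultdict(list)
    for w in windows:
        pools[pool_key(w)].append(w)

    positives: List[WindowPair] = []
    for key in sorted(pools):
        group = sorted(pools[key], key=lambda w: w.window_index)
        if len(group) == 1:
            positives.append(WindowPair(group[0], group[0]))
        else:
            positives.extend(WindowPair(a, b) for a, b in itertools.combinations(group, 2))
    if max_positive_pairs is not None and len(positives) > max_positive_pairs:
        keep = rng.choice(len(positives), size=max_positive_pairs, replace=False)
        positives = [positives[i] for i in sorted(keep.tolist())]

    n_neg = len(positives)
    subjects = sorted({w.subject_id for w in windows})
    if len(subjects) < 2:
        raise ValueError("cannot sample negative pairs from a single subject")

    # enumerate the cross-subject pair space lazily by sampling indices
    if condition_policy == "same":
        conditions = sorted({w.condition for w in windows})
        cand: List[Tuple[int, int]] = []
        by_cond: Dict[str, List[int]] = defaultdict(list)
        for i, w in enumerate(windows):
            by_cond[w.condition].append(i)
        for cond in conditions:
            idxs = by_cond[cond]
            cand.extend(
                (i, j)
                for i, j in itertools.combinations(idxs, 2)
                if windows[i].subject_id != windows[j].subject_id
            )
    else:
        cand = [
            (i, j)
            for i, j in itertools.combinations(range(len(windows)), 2)
            if windows[i].subject_id != windows[j].subject_id
        ]
    if not cand:
        raise ValueError("no cross-subject pair exists under the requested policy")

    negatives: List[WindowPair] = []
    order = rng.permutation(len(cand))
    for k in order[: min(n_neg, len(cand))]:
        i, j = cand[k]
        negatives.append(WindowPair(windows[i], windows[j]))
    while len(negatives) < n_neg:  # exhausted: continue with replacement
        i, j = cand[int(rng.integers(len(cand)))]
        negatives.append(WindowPair(windows[i], windows[j]))

    return positives + negatives


def balanced_minibatches(
    pairs: Sequence[WindowPair],
    batch_size: int,
    rng: Optional[np.random.Generator] = None,
) -> Iterator[List[WindowPair]]:
    """Serve minibatches holding exactly 50% positive and 50% negative pairs.

    One epoch is one shuffled pass over all positive pairs; negatives (and,
    in the final batch, positives) are resampled with replacement as needed
    so that every emitted batch is full and exactly balanced.
    """
    if batch_size % 2 != 0 or batch_size < 2:
        raise ValueError("batch_size must be a positive even number")
    rng = rng if rng is not None else np.random.default_rng(0)
    pos = [p for p in pairs if p.y == 1]
    neg = [p for p in pairs if p.y == 0]
    if not pos or not neg:
        raise ValueError("both positive and negative pairs are required")
    half = batch_size // 2
    pos_order = rng.permutation(len(pos))
    n_batches = math.ceil(len(pos) / half)
    for b in range(n_batches):
        chunk = pos_order[b * half : (b + 1) * half]
        batch_pos = [pos[i] for i in chunk]
        while len(batch_pos) < half:  # pad the ragged final batch
            batch_pos.append(pos[int(rng.integers(len(pos)))])
        batch_neg = [neg[int(i)] for i in rng.integers(len(neg), size=half)]
        batch = batch_pos + batch_neg
        order = rng.permutation(batch_size)
        yield [batch[i] for i in order]


def pairs_to_records(pairs: Sequence[WindowPair], condition_policy: str = "same") -> List[dict]:
    """Serializable audit records for a pair list."""
    return [
        {
            "first_window_ref": p.first.key,
            "second_window_ref": p.second.key,
            "y": p.y,
            "condition_policy": condition_policy,
        }
        for p in pairs
    ]
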