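"""Experiment runner: the three study designs over a cohort of RR series.

Designs:

* ``window_sweep`` — train and test at one age, scanning the heartbeat
  window length over a grid (default 25-600 beats in steps of 25).
* ``age_sweep`` — train at a reference age (default 6 months) with a fixed
  window length, test at older ages, and attach a TOST equivalence verdict
  of each test age against the reference.
* ``drug_conditions`` — train on basal, drug or combined windows and always
  test on the drug-condition test set, scanning window lengths.

Every cell is fully determined by the experiment seed: splits, pair
sampling, weight initialization and fold assignment all derive from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from rrverify.evaluation import EvalReport, TOSTConfig, folded_eval, tost_equivalence
from rrverify.model import (
    LossParams,
    SiameseConfig,
    TrainHyperparams,
    score_pairs,
    train,
)
from rrverify.pairing import (
    CD,
    PD,
    SplitSpec,
    balance_window_counts,
    enumerate_pairs,
    split_cd,
    split_pd,
)
from rrverify.preprocess import preprocess_series
from rrverify.types import BASAL, DRUG, HeartbeatWindow, RRSeries

DESIGNS = ("window_sweep", "age_sweep", "drug_conditions")
COMBINED = "combined"

#: Default window-length grid: 25 to 600 beats in steps of 25.
DEFAULT_GRID = tuple(range(25, 601, 25))


@dataclass(frozen=True)
class ExperimentSpec:
    design: str = "window_sweep"
    protocol: str = CD
    n_beats_grid: Tuple[int, ...] = DEFAULT_GRID
    n_beats: int = 50  # fixed length used by age_sweep
    train_age: float = 6.0
    test_ages: Tuple[float, ...] = ()
    train_condition: str = BASAL
    test_condition: str = BASAL
    n_folds: int = 5
    seeds: Tuple[int, ...] = (0,)
    train_fraction: float = 0.8
    max_train_pairs: Optional[int] = 2000

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"design must be one of {DESIGNS}")
        if self.design == "age_sweep" and not self.test_ages:
            raise ValueError("age_sweep needs test_ages")
        if not self.n_beats_grid:
            raise ValueError("n_beats_grid must be non-empty")
        if not self.seeds:
            raise ValueError("seeds must be non-empty")
        if self.train_condition not in (BASAL, DRUG, COMBINED):
            raise ValueError("train_condition must be basal, drug or combined")
        if self.test_condition not in (BASAL, DRUG):
            raise ValueError("test_condition must be basal or drug")


def _windows_at(
    series: Sequence[RRSeries], age: float, n_beats: int
) -> List[HeartbeatWindow]:
    out: List[HeartbeatWindow] = []
    for s in series:
        if s.age_months == age:
            out.extend(preprocess_series(s, n_beats))
    return out


def _filter_condition(
    windows: Sequence[HeartbeatWindow], condition: str
) -> List[HeartbeatWindow]:
    if condition == COMBINED:
        return list(windows)
    return [w for w in windows if w.condition == condition]


def _require(windows: Sequence[HeartbeatWindow], what: str) -> None:
    if not windows:
        raise ValueError(f"cohort has no coverage for {what}")


def run_cell(
    series: Sequence[RRSeries],
    n_beats: int,
    protocol: str,
    train_age: float,
    test_age: float,
    train_condition: str,
    test_condition: str,
    seed: int,
    n_folds: int = 5,
    train_fraction: float = 0.8,
    max_train_pairs: Optional[int] = 2000,
    hyperparams: Optional[TrainHyperparams] = None,
    loss_params: LossParams = LossParams(),
) -> EvalReport:
    """Train and evaluate one experiment cell; returns its EvalReport.

    The drug-condition designs always pair windows under matching conditions
    ('same' policy), so a combined training set still never mixes basal and
    drug windows within one pair.
    """
    rng = np.random.default_rng(seed)
    hp = hyperparams if hyperparams is not None else TrainHyperparams(seed=seed)
    hp = replace(hp, seed=seed)

    train_pool = balance_window_counts(_windows_at(series, train_age, n_beats))
    if protocol == CD:
        tr, te = split_cd(train_pool, SplitSpec(protocol=CD, train_fraction=train_fraction, seed=seed))
        train_windows = _filter_condition(tr, train_condition)
        if test_age == train_age:
            test_windows = _filter_condition(te, test_condition)
        else:
            test_pool = balance_window_counts(_windows_at(series, test_age, n_beats))
            test_windows = _filter_condition(test_pool, test_condition)
    else:
        subjects = sorted({w.subject_id for w in train_pool})
        tr_subj, te_subj = split_pd(
            subjects, SplitSpec(protocol=PD, train_fraction=train_fraction, seed=seed)
        )
        train_windows = _filter_condition(
            [w for w in train_pool if w.subject_id in set(tr_subj)], train_condition
        )
        test_pool = (
            train_pool
            if test_age == train_age
            else balance_window_counts(_windows_at(series, test_age, n_beats))
        )
        test_windows = _filter_condition(
            [w for w in test_pool if w.subject_id in set(te_subj)], test_condition
        )
    _require(train_windows, f"training (age {train_age}, condition {train_condition})")
    _require(test_windows, f"testing (age {test_age}, condition {test_condition})")

    train_pairs = enumerate_pairs(
        train_windows, "same", rng, max_positive_pairs=max_train_pairs
    )
    test_pairs = enumerate_pairs(test_windows, "same", rng)

    model = train(SiameseConfig(n_beats=n_beats), loss_params, train_pairs, hp)
    scores = score_pairs(model, test_pairs)
    labels = np.array([p.y for p in test_pairs])
    return folded_eval(scores, labels, n_folds=n_folds, rng=rng)


def run_experiment(
    spec: ExperimentSpec,
    series: Sequence[RRSeries],
    hyperparams: Optional[TrainHyperparams] = None,
    tost: TOSTConfig = TOSTConfig(),
) -> pd.DataFrame:
    """Run a full design; one row per (n_beats or age) x seed.

    ``age_sweep`` rows carry TOST p-values and the equivalence verdict of
    the test age against the reference (training) age, computed from the
    stored fold EERs with a margin of three reference standard deviations
    unless the TOST config pins one.
    """
    rows: List[Dict] = []
    if spec.design in ("window_sweep", "drug_conditions"):
        test_condition = DRUG if spec.design == "drug_conditions" else spec.test_condition
        train_condition = spec.train_condition
        for n_beats in spec.n_beats_grid:
            for seed in spec.seeds:
                report = run_cell(
                    series,
                    n_beats=n_beats,
                    protocol=spec.protocol,
                    train_age=spec.train_age,
                    test_age=spec.train_age,
                    train_condition=train_condition,
                    test_condition=test_condition,
                    seed=seed,
                    n_folds=spec.n_folds,
                    train_fraction=spec.train_fraction,
                    max_train_pairs=spec.max_train_pairs,
                    hyperparams=hyperparams,
                )
                rows.append(
                    _row(spec, report, n_beats=n_beats, test_age=spec.train_age, seed=seed,
                         train_condition=train_condition, test_condition=test_condition)
                )
    else:  # age_sweep
        for seed in spec.seeds:
            ref = run_cell(
                series,
                n_beats=spec.n_beats,
                protocol=spec.protocol,
                train_age=spec.train_age,
                test_age=spec.train_age,
                train_condition=spec.train_condition,
                test_condition=spec.test_condition,
                seed=seed,
                n_folds=spec.n_folds,
                train_fraction=spec.train_fraction,
                max_train_pairs=spec.max_train_pairs,
                hyperparams=hyperparams,
            )
            rows.append(
                _row(spec, ref, n_beats=spec.n_beats, test_age=spec.train_age, seed=seed,
                     train_condition=spec.train_condition, test_condition=spec.test_condition)
            )
            for age in spec.test_ages:
                if age == spec.train_age:
                    continue
                rep = run_cell(
                    series,
                    n_beats=spec.n_beats,
                    protocol=spec.protocol,
                    train_age=spec.train_age,
                    test_age=age,
                    train_condition=spec.train_condition,
                    test_condition=spec.test_condition,
                    seed=seed,
                    n_folds=spec.n_folds,
                    train_fraction=spec.train_fraction,
                    max_train_pairs=spec.max_train_pairs,
                    hyperparams=hyperparams,
                )
                row = _row(spec, rep, n_beats=spec.n_beats, test_age=age, seed=seed,
                           train_condition=spec.train_condition, test_condition=spec.test_condition)
                try:
                    p_lo, p_up, eq = tost_equivalence(ref.fold_eers, rep.fold_eers, tost)
                except ValueError:
                    # degenerate fold spread: the 3-sigma margin is undefined
                    p_lo, p_up, eq = float("nan"), float("nan"), None
                row.update({"tost_p_lower": p_lo, "tost_p_upper": p_up, "tost_equivalent": eq})
                rows.append(row)
    return pd.DataFrame(rows)


def _row(
    spec: ExperimentSpec,
    report: EvalReport,
    n_beats: int,
    test_age: float,
    seed: int,
    train_condition: str,
    test_condition: str,
) -> Dict:
    return {
        "design": spec.design,
        "protocol": spec.protocol,
        "n_beats": n_beats,
        "train_age": spec.train_age,
        "test_age": test_age,
        "train_condition": train_condition,
        "test_condition": test_condition,
        "seed": seed,
        "eer": report.eer,
        "mean_eer": report.mean_eer,
        "std_eer": report.std_eer,
        "cv": report.cv,
        "fold_eers": ";".join(f"{e:.6f}" for e in report.fold_eers),
    }
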