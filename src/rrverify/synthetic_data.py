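"""Synthetic mouse-like RR cohorts with per-subject biometric signatures.

The generator emulates the statistical structure a verification model must
exploit: each subject carries a stable signature (its mean RR, variability,
second-order AR(2) dynamics and a respiratory-like oscillation), ages drift
that signature slowly, and dual autonomic blockade ("drug") shrinks
variability and shifts the mean.  Occasional out-of-range artifacts exercise
the physiological range filter downstream.

The generative model is an AR(2) process around a slowly drifting mean plus
one sinusoidal oscillation — the minimal structure that gives subjects
distinguishable second-order statistics.  Defaults are calibrated so a
250-beat window spans about 33 s (mean RR 0.132 s), matching anesthetized
mouse heart rates near 450 bpm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

import numpy as np

from rrverify.types import BASAL, CONDITIONS, DRUG, RRSeries

# Artifact values are drawn from these bands so they deterministically violate
# the 0.05-0.24 s physiological filter range.
ARTIFACT_LOW = (0.01, 0.045)
ARTIFACT_HIGH = (0.26, 0.40)

_MAX_AR_REDRAWS = 100
_MIN_RR = 1e-3  # floor keeping intervals positive under extreme noise
_REFERENCE_AGE = 6.0  # months; aging drift is measured from this baseline


class NonStationaryARError(ValueError):
    """Raised when hyperparameters keep producing non-stationary AR dynamics."""


def ar2_is_stationary(phi1: float, phi2: float) -> bool:
    """Stationarity triangle for AR(2): roots of 1 - phi1 z - phi2 z^2 outside
    the unit circle, equivalently phi2 + phi1 < 1, phi2 - phi1 < 1, |phi2| < 1."""
    return (phi1 + phi2 < 1.0) and (phi2 - phi1 < 1.0) and (abs(phi2) < 1.0)


@dataclass(frozen=True)
class SubjectSignature:
    """Stable per-subject parameters of the RR generative process."""

    subject_id: str
    mean_rr: float  # seconds
    sd_rr: float  # seconds, stationary SD of the AR component
    ar_coeffs: Tuple[float, float]  # (phi1, phi2), stationary
    osc_amp: float  # seconds
    osc_freq: float  # cycles per beat
    drug_var_scale: float  # in (0, 1]: blockade shrinks HRV
    drug_mean_shift: float  # seconds
    aging_mean_drift: float  # seconds per month
    aging_var_drift: float  # fractional SD change per month

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if self.sd_rr < 0:
            raise ValueError("sd_rr must be non-negative")
        if not ar2_is_stationary(*self.ar_coeffs):
            raise NonStationaryARError(f"AR coefficients {self.ar_coeffs} are non-stationary")
        if not (0.0 < self.drug_var_scale <= 1.0):
            raise ValueError("drug_var_scale must lie in (0, 1]")


@dataclass(frozen=True)
class SignatureDistributions:
    """Cohort-level hyperparameters: each signature field is drawn independently.

    Gaussian fields are (center, spread) pairs; osc_freq is uniform on
    (lo, hi).  Setting every spread to zero collapses the cohort onto a
    single shared signature (useful as a no-information control).
    """

    mean_rr: Tuple[float, float] = (0.132, 0.010)
    sd_rr: Tuple[float, float] = (0.006, 0.002)
    phi1: Tuple[float, float] = (0.5, 0.15)
    phi2: Tuple[float, float] = (-0.1, 0.10)
    osc_amp: Tuple[float, float] = (0.002, 0.001)
    osc_freq: Tuple[float, float] = (0.05, 0.45)
    drug_var_scale: Tuple[float, float] = (0.4, 0.05)
    drug_mean_shift: Tuple[float, float] = (0.005, 0.003)
    aging_mean_drift: Tuple[float, float] = (0.0015, 0.0005)
    aging_var_drift: Tuple[float, float] = (0.02, 0.01)


def default_distributions() -> SignatureDistributions:
    """Cohort hyperparameters emulating anesthetized aging mice."""
    return SignatureDistributions()


def high_separability_distributions() -> SignatureDistributions:
    """Wide between-subject signature variance, small within-subject noise.

    Used as a positive control: a working verifier must separate this cohort.
    """
    return SignatureDistributions(
        mean_rr=(0.132, 0.020),
        sd_rr=(0.003, 0.0005),
        phi1=(0.5, 0.30),
        phi2=(-0.1, 0.20),
        osc_amp=(0.004, 0.002),
        osc_freq=(0.05, 0.45),
    )


def degenerate_distributions() -> SignatureDistributions:
    """Zero between-subject variance: all subjects share one signature.

    A verifier on this cohort carries no identity information, so its EER
    must be statistically indistinguishable from 0.5.
    """
    return SignatureDistributions(
        mean_rr=(0.132, 0.0),
        sd_rr=(0.006, 0.0),
        phi1=(0.5, 0.0),
        phi2=(-0.1, 0.0),
        osc_amp=(0.002, 0.0),
        osc_freq=(0.25, 0.25),  # degenerate uniform: single point
        drug_var_scale=(0.4, 0.0),
        drug_mean_shift=(0.005, 0.0),
        aging_mean_drift=(0.0015, 0.0),
        aging_var_drift=(0.02, 0.0),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Design of a longitudinal cohort simulation.

    ``segment_duration`` may be a single number (seconds, applied to every
    condition) or a mapping {condition: seconds}.  Defaults mirror a 10 min
    basal recording and a 40 min drug recording per session.
    """

    n_subjects: int = 30
    ages_months: Tuple[float, ...] = (6.0,)
    conditions: Tuple[str, ...] = (BASAL,)
    segment_duration: Union[float, Mapping[str, float]] = field(
        default_factory=lambda: {BASAL: 600.0, DRUG: 2400.0}
    )
    artifact_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if not self.ages_months:
            raise ValueError("ages_months must be non-empty")
        if not self.conditions:
            raise ValueError("conditions must be non-empty")
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ValueError(f"unknown condition {c!r}")
        if not (0.0 <= self.artifact_rate < 1.0):
            raise ValueError("artifact_rate must lie in [0, 1)")
        for c in self.conditions:
            if self.duration_for(c) <= 0:
                raise ValueError("segment_duration must be positive")

    def duration_for(self, condition: str) -> float:
        if isinstance(self.segment_duration, Mapping):
            return float(self.segment_duration[condition])
        return float(self.segment_duration)


def _gauss(rng: np.random.Generator, center_spread: Tuple[float, float]) -> float:
    center, spread = center_spread
    return float(center + spread * rng.standard_normal()) if spread else float(center)


def draw_signature(
    cohort_params: SignatureDistributions,
    rng: np.random.Generator,
    subject_id: str = "S0",
) -> SubjectSignature:
    """Draw one subject's signature from the cohort distributions.

    AR coefficients are redrawn (bounded number of times) until stationary;
    scale parameters are clipped to their valid ranges rather than redrawn,
    so the draw consumes a deterministic amount of the random stream for
    every field except the AR pair.
    """
    mean_rr = max(_gauss(rng, cohort_params.mean_rr), 0.02)
    sd_rr = max(_gauss(rng, cohort_params.sd_rr), 0.0)
    phi = None
    for _ in range(_MAX_AR_REDRAWS):
        cand = (_gauss(rng, cohort_params.phi1), _gauss(rng, cohort_params.phi2))
        if ar2_is_stationary(*cand):
            phi = cand
            break
    if phi is None:
        raise NonStationaryARError(
            f"no stationary AR(2) draw within {_MAX_AR_REDRAWS} attempts; "
            "check phi1/phi2 hyperparameters"
        )
    lo, hi = cohort_params.osc_freq
    osc_freq = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    return SubjectSignature(
        subject_id=subject_id,
        mean_rr=mean_rr,
        sd_rr=sd_rr,
        ar_coeffs=phi,
        osc_amp=max(_gauss(rng, cohort_params.osc_amp), 0.0),
        osc_freq=osc_freq,
        drug_var_scale=float(np.clip(_gauss(rng, cohort_params.drug_var_scale), 0.05, 1.0)),
        drug_mean_shift=_gauss(rng, cohort_params.drug_mean_shift),
        aging_mean_drift=_gauss(rng, cohort_params.aging_mean_drift),
        aging_var_drift=_gauss(rng, cohort_params.aging_var_drift),
    )


def _ar2_series(
    n: int, phi1: float, phi2: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(2) sample of length n with stationary SD ``sd``."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    # innovation variance giving the requested stationary variance
    num = (1.0 + phi2) * ((1.0 - phi2) ** 2 - phi1**2)
    sigma_eps = sd * math.sqrt(max(num / (1.0 - phi2), 1e-12))
    burn = 200
    eps = sigma_eps * rng.standard_normal(n + burn)
    x = np.zeros(n + burn)
    for t in range(2, n + burn):
        x[t] = phi1 * x[t - 1] + phi2 * x[t - 2] + eps[t]
    return x[burn:]


def simulate_rr_segment(
    sig: SubjectSignature,
    age: float,
    condition: str,
    duration: float,
    rng: np.random.Generator,
    artifact_rate: float = 0.0,
) -> RRSeries:
    """Simulate one recording segment for a subject at a given age/condition.

    Beats are generated until their cumulative duration reaches ``duration``.
    The generating mean is mean_rr plus linear aging drift (plus the drug
    mean shift under blockade); the generating SD is scaled by the aging
    variance drift and, under drug, by ``drug_var_scale``.  Artifacts replace
    beats at ``artifact_rate`` with values outside the physiological band.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")

    d_age = age - _REFERENCE_AGE
    mean = sig.mean_rr + sig.aging_mean_drift * d_age
    sd = sig.sd_rr * max(1.0 + sig.aging_var_drift * d_age, 0.0)
    if condition == DRUG:
        mean = mean + sig.drug_mean_shift
        sd = sd * sig.drug_var_scale
    mean = max(mean, 0.02)
    if duration < 2 * mean:
        raise ValueError("duration too short for two beats at the signature's mean RR")

    # generate a margin beyond the expected count, then cut at the duration
    n_est = int(math.ceil(duration / mean)) + 16
    noise = _ar2_series(n_est, *sig.ar_coeffs, sd, rng)
    if sig.osc_amp > 0.0:
        phase = rng.uniform(0.0, 2.0 * math.pi)
        noise = noise + sig.osc_amp * np.sin(
            2.0 * math.pi * sig.osc_freq * np.arange(n_est) + phase
        )
    intervals = np.maximum(mean + noise, _MIN_RR)

    cum = np.cumsum(intervals)
    stop = int(np.searchsorted(cum, duration, side="left")) + 1
    intervals = intervals[: min(stop, n_est)]

    if artifact_rate > 0.0:
        mask = rng.random(intervals.size) < artifact_rate
        n_art = int(mask.sum())
        if n_art:
            high = rng.random(n_art) < 0.5
            vals = np.where(
                high,
                rng.uniform(*ARTIFACT_HIGH, size=n_art),
                rng.uniform(*ARTIFACT_LOW, size=n_art),
            )
            intervals = intervals.copy()
            intervals[mask] = vals

    times = np.concatenate(([0.0], np.cumsum(intervals)))
    return RRSeries(
        subject_id=sig.subject_id,
        condition=condition,
        age_months=float(age),
        intervals=intervals,
        times=times,
    )


def simulate_cohort(
    spec: CohortSpec,
    distributions: SignatureDistributions | None = None,
) -> List[RRSeries]:
    """Simulate one RRSeries per (subject, age, condition).

    Fully reproducible: each subject owns an independent child stream of the
    cohort seed, and segments are generated in a fixed (age, condition)
    order, so the output is bitwise identical across runs with equal specs.
    """
    dists = distributions if distributions is not None else default_distributions()
    width = max(3, len(str(spec.n_subjects)))
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)
    conditions = sorted(spec.conditions, key=CONDITIONS.index)
    out: List[RRSeries] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        sig = draw_signature(dists, rng, subject_id=f"M{i + 1:0{width}d}")
        for age in spec.ages_months:
            for cond in conditions:
                out.append(
                    simulate_rr_segment(
                        sig,
                        age=age,
                        condition=cond,
                        duration=spec.duration_for(cond),
                        rng=rng,
                        artifact_rate=spec.artifact_rate,
                    )
                )
    return out
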