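# Methods

`rrverify` asks a narrow question: can two windows of beat-to-beat (RR)
intervals be attributed to the same individual using only their timing
statistics?  The package implements the full verification pipeline — RR
preprocessing, pair construction, a Siamese convolutional encoder trained
with a contrastive cosine loss, and FAR/FRR/EER evaluation with equivalence
testing across ages — together with a synthetic cohort generator that
supplies mouse-like longitudinal data, since comparable real recordings are
restricted.

## Verification model

Each heartbeat window is a vector of `n_beats` consecutive RR intervals in
raw seconds (no resampling, detrending or normalization is applied before
the network; batch normalization inside the encoder handles scale).  The
shared encoder branch f(·;Θ) is:

* three blocks of 1-D convolution → batch normalization → max pooling
  (window 2) → ReLU.  All convolutions use the same kernel, one tenth of
  the window length (floored, minimum 1), with "same" padding so the
  temporal extent is reduced only by pooling.  Default channel widths are
  16 → 32 → 64.
* three linear layers, 128 → 64 → 32, the first two preceded by dropout and
  followed by batch normalization and ReLU; the last is purely linear and
  its 32-dimensional output is the embedding.

Both pair members pass through the *same* encoder object, so weight sharing
holds by construction rather than by synchronization.  Similarity is the
cosine of the angle between the two embeddings, c = cos(γ) ∈ [−1, 1].

Training minimizes the mean batch loss over B labeled pairs

    L(Θ) = (1/B) Σᵢ (1 − yᵢ)·cᵢ − λ·yᵢ·(b + cᵢ),   λ > 0, b ∈ [−1, 1],

with y = 1 for genuine (same-subject) pairs.  The loss is linear in c: its
gradient pulls genuine pairs toward c = 1 and pushes impostor pairs toward
c = −1.  A consequence worth stating explicitly: because the loss is affine
in c, the offset b contributes only the constant −λ·y·b to the loss value
and has *zero* gradient with respect to Θ — under plain gradient descent b
cannot change the learned embedding, only the reported loss.  The property
tests assert exactly this behavior; b is retained in the interface because
it defines the intended FAR/FRR weighting and becomes active under any loss
variant with a nonlinearity in c (e.g. hinging), which this package does
not implement.

Optimization is stochastic gradient descent with classical momentum and
weight decay; all layers and their backward passes are implemented directly
in numpy with analytic gradients (verified against central finite
differences in the test suite).  Minibatches are served exactly
class-balanced: one epoch is a shuffled pass over all positive pairs, with
the negative half of each batch resampled with replacement.  Defaults:
batch 32, learning rate 0.01, momentum 0.9, weight decay 10⁻⁴, dropout
0.2, 15 epochs, λ = 1, b = 0.  These are deliberately plain settings that
train a 50-beat model on a 30-subject cohort in well under a minute on one
CPU core; per-condition tuning is exposed through `TrainHyperparams` and
the YAML config.

Numerical details: cosine similarity raises a degenerate-embedding error
for zero-norm vectors rather than returning NaN; linear and convolutional
biases are initialized uniformly in ±1/√fan_in so an untrained or dead-ReLU
trunk maps to a shared nonzero bias vector rather than the exact zero
embedding; convolutional biases that feed a batch-normalization layer have
identically zero gradient (normalization removes per-channel constants) and
are kept only for architectural regularity.

## Preprocessing

RR intervals are differences of R-peak times, RR(tᵢ) = tᵢ₊₁ − tᵢ.  The
physiological range filter keeps intervals in the closed band
[0.05 s, 0.24 s] (1200 down to 250 bpm, the plausible murine range) and
replaces out-of-range values by linear interpolation between the nearest
in-range beats.  Interpolation is linear in *beat index* over interval
values; with no in-range neighbor on one side the nearest in-range value is
carried flat.  Both choices are determinate on unevenly spaced data and
make the filter idempotent and length-preserving.  Drug segments lose their
first 120 s (measured in cumulative RR time from segment start, with a
10⁻⁹ s tolerance against floating-point accumulation at the boundary) to
avoid pharmacological transients.  Windows are consecutive, non-overlapping
blocks of `n_beats` intervals; the trailing remainder is discarded.

## Protocols, balancing and pairing

Window counts are balanced before any split: the subject with the fewest
basal windows defines N, and every subject keeps its first N windows per
condition.  The complete-dataset (CD) protocol splits each subject's
windows 80%/20% into train/test (test share rounded up, so a single-window
subject lands in test and its genuine pair duplicates the window); it
measures verification of enrolled subjects on unseen windows.  The
partial-dataset (PD) protocol splits *subjects* 80%/20% (30 → 24 + 6), so
test individuals are never seen in training; an optional subject-disjoint
validation slice can be carved from the training side.  Genuine pairs are
all distinct-window combinations within a subject; impostor pairs are
sampled uniformly from cross-subject combinations, without replacement
until that space is exhausted, to match the genuine count.  Under the
`same` condition policy (the default, and forced for the drug designs) both
members of a pair share the recording condition.

## Evaluation

A pair is accepted as genuine when its score is at or above the threshold
(ties accept).  FAR is the acceptance rate over impostor pairs, FRR the
rejection rate over genuine pairs; candidate thresholds are the unique
observed scores plus sentinels that accept and reject everything, which
guarantees the FAR − FRR sign change is bracketed.  The EER is read at the
crossing, linearly interpolated between the bracketing candidates; it
agrees with an exhaustive scan to 10⁻⁹ and is invariant under strictly
increasing transforms of the scores.  Test sets are split into 5 random
disjoint folds; the mean, sample standard deviation and coefficient of
variation CV = σ/μ of fold EERs quantify stability.  The confusion matrix
is oriented rows = ground truth, columns = prediction.

Age robustness uses TOST (two one-sided tests) with unpaired unequal
variance (Welch) t statistics against an equivalence margin of three
standard deviations of the reference-age fold EERs.  The decision rule
declares equivalence when the *sum* of the two one-sided p-values falls
below α; the conventional max(p₁, p₂) < α rule is available behind a
config switch.  When the reference folds have zero spread the 3σ margin is
undefined and the experiment runner reports the verdict as undefined
rather than inventing a margin.

## Synthetic cohort generator

The generator stands in for a restricted longitudinal dataset of
anesthetized aging mice, and defines the study conditions under which the
pipeline is exercised.  Each subject carries a fixed signature: mean RR,
HRV magnitude, AR(2) coefficients (drawn inside the stationarity triangle,
with a bounded redraw), one sinusoidal respiratory-like oscillation
(amplitude and a per-subject frequency in cycles/beat), a drug response
(variance shrinkage, default scale 0.4, plus a small mean shift — dual
autonomic blockade suppresses HRV), and linear aging drifts of mean and
variance per month from the 6-month baseline.  A segment is generated beat
by beat as mean + AR(2) noise + oscillation until the cumulative interval
sum covers the requested duration; artifacts replace beats at a configured
rate with uniform draws from [0.01, 0.045] ∪ [0.26, 0.40] s, which
deterministically violate the range filter.  The default mean RR of
0.132 s makes a 250-beat window span ≈ 33 s, matching murine heart rates
near 450 bpm; default segment durations are 10 min (basal) and 40 min
(drug).  Reproducibility is bitwise: each subject owns a spawned child of
the cohort seed and segments are generated in fixed order.

Three presets matter: `default` (moderate between-subject separation),
`high_separability` (wide between-subject signature variance, low
within-subject noise — a positive control the model must verify with EER
≤ 0.25), and `degenerate` (all subjects share one signature — a negative
control whose EER must be statistically indistinguishable from 0.5).  No
within- or between-subject HRV statistics are available for the real
cohort, so separability is a preset, not a calibration; passing tests on
synthetic data therefore demonstrate that the pipeline extracts identity
information *when it is present* and extracts none when it is absent, not
any particular error rate on real recordings.  The generator also omits
features of real data — circadian and activity-state variation,
anesthesia depth, recording noise in peak detection, non-linear aging —
so absolute EERs here do not transfer to real cohorts.

## Problem sizes in the shipped tests

The end-to-end controls train a 50-beat CD model on 30 synthetic subjects
with 100 s of basal recording each (≈ 15 windows per subject, with the
training positive-pair pool capped at 2000) for 10 epochs — small enough
to run comfortably on a laptop core, large enough that the separable
cohort reaches EER well under the 0.25 bar and the degenerate cohort's
test set (~180 pairs) gives a usable binomial interval around 0.5.  The
experiment-runner tests use 6-subject cohorts and 1-2 epochs: they check
plumbing (row counts, reproducibility, TOST columns), not performance.

## Known limitations

* The loss's b parameter is inert during training (see above).
* Impostor-pair subsampling means pair counts are emergent, not matched to
  any external tally.
* The generator's AR(2)-plus-oscillation structure is the minimal model
  giving subjects distinguishable second-order statistics; it does not
  claim physiological completeness.
* EER resolution is limited by test-pair count (≈ 1/n_pairs per fold), so
  fold CVs on small synthetic cohorts are noisy.
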