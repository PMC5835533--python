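# Methods

## Scope and model of the data

`mttpipe` analyses stimulus-locked intracranial EEG epochs from
self-projection experiments, in which a participant implanted with depth
electrodes judges events either from their actual position in time or
space ("now" / "here") or from an imagined one ("then" / "there"). The
scientific question — do lateral temporal cortex (LTC) and hippocampal
electrodes carry the condition contrast at different latencies? — is
answered not by averaging across subjects but by *classifying electrodes*
from per-electrode response features, with significance obtained by
exhaustive label permutation. Because patient recordings of this kind
cannot be redistributed, the package ships a trial-level simulator whose
defaults encode the study conditions, and every statistical guarantee is
demonstrated on simulated data.

## The simulator

Each electrode's evoked response is a sum of Gaussian deflections
A·exp(−(t−μ)²/2σ²). The default kernel has an early positivity
(μ = 150 ms, σ = 40 ms, 10 µV) and a later slow wave of opposite polarity
(μ = 500 ms, σ = 58 ms, −6.9 µV). Two properties motivated this choice:

* **Biphasic morphology.** Depth-electrode iEPs typically show an early
  sharp deflection followed by a slower wave of opposite sign.
* **Near-zero net epoch area.** The 1–120 Hz zero-phase band-pass is
  applied to the −100…+800 ms epoch directly (simulating a continuous
  recording is out of scope). A high-pass at 1 Hz forces the filtered
  epoch towards zero mean, so a kernel with large net area would see its
  window integrals — the raw material of the modulation features —
  collapse or change sign. With balanced areas the filter perturbs the
  integrals only mildly. This was measured, not assumed: an all-positive
  two-component kernel loses its early-window area almost entirely
  (947 → −28 µV·ms) to the high-pass.

Condition effects are multiplicative: inside its effect window the
non-baseline condition equals the baseline template times (1 + effect).
LTC electrodes carry the effect in 100–300 ms, hippocampal electrodes in
400–600 ms, each with a 20 ms raised-cosine taper at the window edges so
the band-pass sees no steps. The secondary factor of the 2×2 design
("before"/"after") is carried as metadata with no injected effect, since
the analysis collapses it.

Default study conditions: 6 LTC + 6 hippocampal electrodes on the left,
3 + 5 on the right; 60 trials per collapsed condition (120 per block);
512 Hz sampling; effects of 0.5; i.i.d. Gaussian sensor noise of
σ = 1.5 µV per sample. The noise level is a calibration choice — no
published µV effect magnitudes or noise levels exist to copy for this
kind of recording — set so that the left-hemisphere separation is clear
at the evoked level
(evoked-level noise ≈ 1.5/√60 ≈ 0.2 µV against ~5 µV condition
differences) but single-trial statistics remain noisy, which matches the
qualitative situation described for real recordings. Each electrode's
polarity is flipped with probability 0.3 (depth contacts on opposite
sides of a generator record inverted potentials; all downstream features
are sign-invariant). A fraction 0.02 of trials receives a widespread
Gaussian transient of 10× noise SD at a random latency, *not* flagged at
generation — artifact rejection has to find it.

Per-electrode RNG substreams are derived from the top-level seed with
`SeedSequence(seed, spawn_key=(electrode_index,))`, so enlarging the
montage never perturbs existing electrodes, and a given seed reproduces
the dataset bit for bit.

What the simulator deliberately does not model: epileptic background
rhythms, 50/60 Hz line noise, inter-electrode correlation, latency
jitter across trials, and reaction-time-locked components. Passing tests
therefore demonstrate correctness of the *procedures* and their
statistical calibration under clean assumptions, not performance on real
clinical recordings.

## Preprocessing

Order: band-pass → artifact rejection → (optional condition collapsing,
optional baseline) → condition averaging.

* **Filter.** 4th-order Butterworth, 1–120 Hz, applied forward and
  backward (`sosfiltfilt`, zero phase). The upper corner must stay below
  Nyquist; at 512 Hz the 120 Hz corner passes. Zero-phase filtering of a
  0.9-s epoch leaves low-frequency transients at the epoch edges, so the
  first and last 50 ms are treated as untrusted: artifact rejection does
  not scan them, and they lie outside every analysis window.
* **Rejection.** Automated stand-in for the visual screening used with
  clinical recordings: per electrode and condition, each trial's
  deviation from the across-trial median waveform is z-scored against a
  robust scale (median absolute deviation / 0.6745, pooled over the
  trusted samples); a trial is dropped everywhere if any electrode shows
  |z| > 6. On artifact-free simulated data this flags well under 5 % of
  trials; a planted 10× transient is flagged reliably. Rejection refuses
  to leave fewer than two usable trials in any condition.
* **Baseline.** Subtracting the mean of −100…0 ms per trial is
  implemented but **off by default**. Measurement showed why it must be:
  the high-pass leaves an undershoot in the pre-stimulus segment, and
  subtracting that segment's mean re-injects the undershoot as a
  whole-epoch offset of several hundred µV·ms per analysis window —
  enough to invert the early/late feature structure the simulator
  constructs. After a 1 Hz high-pass, baseline correction is redundant
  at best and harmful here. The flag remains available and its state is
  echoed into every report, because on data filtered differently the
  opposite choice can be right.

## Task-modulation features

For one electrode with mean waveforms S_a (baseline condition: "now" or
"here") and S_b, and a window w:

    modulation(w) = |∫_w (S_b − S_a) dt| / |∫_w S_a dt|

computed with the early window [100, 400) ms and the late window
[400, 800) ms. Integrals are trapezoidal on the sample grid with the
window boundaries hit exactly by linear interpolation, so 512 Hz and
1024 Hz recordings are commensurable and boundary samples cannot be
double-counted between the two windows. The feature is dimensionless,
≥ 0, and invariant under any common rescaling or sign flip of both
waveforms — the property that makes polarity-reversed electrodes
comparable.

The denominator follows the defining equation literally: the absolute
value of the *signed* integral of the baseline waveform. The phrase
"area under the curve" admits a rectified reading ∫|S_a|; it is
available as `abs_auc=True` and differs whenever the baseline waveform
changes sign inside the window. If the signed baseline integral is
numerically zero (below 1e−9 × window length × max|S_a|), the electrode
is excluded with a warning rather than given a fabricated feature value.

## Electrode classification and permutation inference

Within one hemisphere × task cell, electrodes are points in the
(early, late) plane labelled by region. The analysis:

1. z-score each feature across the electrode set (population SD; a
   constant feature becomes zeros with a warning). Scaling is done once
   on the full set — the small-sample convention this analysis follows —
   which lets the held-out electrode influence the scaler; a
   `fold_safe_scaling` mode rescales inside every fold for readers who
   want the leakage-free variant. Both modes are tested.
2. Select the soft-margin penalty C of a linear SVM over exactly
   10^linspace(−3, 3, 10) by leave-one-out accuracy; ties go to the
   smallest C (strongest regularization, deterministic).
3. Report the LOO accuracy at the selected C. A training fold containing
   one class predicts that class instead of crashing.
4. Exhaustive permutation test: every distinct labelling with the
   observed class sizes (n choose n₁ of them — permuting identical
   labels is a no-op, so full n! enumeration is redundant) is scored by
   the same LOO procedure with C held fixed at the observed-data
   selection; p is the fraction of labelings, the observed one included,
   reaching at least the observed accuracy. This convention keeps
   p ≥ 1/total > 0. With 6 vs 6 electrodes the null has 924 labelings
   and a perfect separation yields p = 2/924 ≈ 0.0022 (the true
   labelling and its complement). Beyond 20 000 labelings the test
   switches to a seeded Monte-Carlo sample with the add-one convention.
   Re-selecting C inside each permutation is available as a sensitivity
   analysis (`reselect_C=True`).

The SVM solver is scikit-learn's `SVC(kernel="linear")`; the test suite
checks it fold-by-fold against an independent dual-QP implementation, and
the whole pipeline (scaling + LOO + exhaustive null) against a naive
from-scratch reimplementation for small n.

## Cluster-based permutation statistics

Single-trial amplitudes at one electrode are compared between conditions
with an independent two-sample t per time sample (pooled variance,
df = n_a + n_b − 2; Welch available). Samples with |t| above the
two-tailed 5 % critical value form the uncorrected mask. Contiguous
suprathreshold runs of consistent sign are clusters; a cluster's mass is
its summed t. The family-wise-corrected p of each cluster is the add-one
proportion of label permutations (class sizes preserved, 1000 by
default) whose *maximum absolute* cluster mass reaches the cluster's
|mass|. Building the null from the maximum over both signs makes the
test two-sided at cluster level. The permutation scheme is canonical in
the original trial order and keyed to the alphabetically first condition
label, so swapping the condition arguments reproduces the identical null
distribution exactly rather than only in distribution.

## Reduced-electrode power analysis

To probe whether a null result in the sparser hemisphere reflects
missing physiology or missing power, the richer hemisphere is subsampled
to the sparser one's composition: all C(6,5) × C(6,3) = 120 subsets of
5 hippocampal + 3 LTC electrodes, enumerated exhaustively in
lexicographic order. Each subset is treated as a complete dataset —
z-scoring, C selection and the exhaustive 56-labelling permutation test
are all redone within it — and the report gives the fraction of subsets
with accuracy strictly above 75 % and the fraction significant at 0.05.
With 5 vs 3 the smallest attainable p is 2/56 ≈ 0.036, which is itself
the power story: even perfect separation barely clears 0.05.

## Numerical conventions and degenerate inputs

* Windows are half-open [start, end) so 400 ms belongs to the late
  window only; numerically the shared boundary has measure zero.
* Permutation p-values always include the observed statistic (exact
  enumeration) or add one to numerator and denominator (Monte-Carlo),
  so p = 0 never occurs.
* Comparisons against "accuracy ≥ observed" use a 1e−12 tolerance to
  absorb float error in k/n fractions.
* Degenerate cases that return instead of crashing: one-class training
  folds (predict the training label), constant feature columns (zeros +
  warning), infinite rejection threshold (no-op). Degenerate cases that
  raise: empty or inverted integration windows, windows outside the time
  axis, non-binary labels, n_perm ≤ 0, rejection emptying a condition,
  fewer than 2 electrodes per class.

## Problem sizes used in the test suite

Statistical-calibration tests run at deliberately small sizes chosen for
tight Monte-Carlo bounds at reasonable cost: classifier null calibration
uses 4 + 4 electrodes × 200 seeds (70-labelling exhaustive null per
seed); cluster-test calibration uses 20–30 trials per condition with 200
permutations × 200 seeds (null) and 100 seeds (localization); the
oracle-equivalence checks use 3 + 3 and 4 + 4 electrodes where exhaustive
enumeration is exact. The headline configuration (12 electrodes, 924
labelings, 120 subsets) runs at full size.

## Known limitations

* Epoch-level filtering is an approximation to filtering a continuous
  recording; its edge effects are quarantined rather than absent, and
  slow (late-window) effects are attenuated more than sharp early ones.
* Permutation-test p-value conventions vary across the literature
  (observed labelling included or not, complement counted or not); the
  convention here (observed included, complement counted) is documented
  and fixed.
* Automated rejection approximates expert visual screening only to first
  order (amplitude outliers); it will not catch morphologically unusual
  but low-amplitude artifacts.
* The space task is simulated with zero effects by default, reproducing
  a null-control *scenario*; nothing is claimed about real spatial-task
  physiology.
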