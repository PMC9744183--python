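# Methods

This note records the scientific and numerical choices behind
`deltaspike`: what each stage computes, which knobs matter, what the
synthetic data do and do not emulate, and where the design was genuinely
open.

## Signal model and preprocessing

A unit is a set of spike times (s) plus per-spike snippets of 32 samples per
channel at 20 kHz (1.6 ms). The mean waveform is computed per channel and
upsampled eightfold by Fourier interpolation (`scipy.signal.resample`),
giving 256 samples at 6.25 μs resolution; averaging and interpolation are
both linear, so their order is immaterial. The *main channel* is the one
with the largest trough-to-peak (TTP) magnitude, ties going to the lowest
channel index. Polarity is decided once per unit on the main channel —
units whose peak exceeds their trough in absolute value are inverted as a
whole, preserving inter-channel sign relations — and the multichannel
waveform is divided by the absolute main-channel minimum, pinning the
main-channel trough at exactly −1.

## Waveform features (8)

All computed on the scaled 256-sample main channel; derivatives are
adjacent-sample differences with no smoothing, and the i-th derivative
sample is aligned with waveform sample i. Choices where the definitions
admit more than one reading:

* **TTP duration/magnitude** — the peak is the *ensuing* maximal positivity
  (global maximum strictly after the trough, used even if non-positive).
* **FWHM** — duration of the contiguous region around the trough where the
  value is ≤ −0.5. The sub-threshold reading (rather than "at least −0.5")
  is the one consistent with half-of-trough semantics on a [−1, 1] scale.
* **Maximum speed** — length of the longest contiguous post-trough stretch
  where the first derivative stays within 5% (configurable) of its
  post-trough maximum. "Maintains the same change rate" needs a tolerance;
  5% is the default band.
* **Second-derivative windows** — break measure 0.3–0.08 ms before the
  trough, acceleration 0.08–0.25 ms after, smile-cry 0.26–0.76 ms after.
  Boundaries snap to the 6.25 μs grid toward the trough; each window is
  closed on the trough-near side and half-open on the far side. Sums are
  reported on 10⁻¹ / 10⁻⁶ / 10⁻² AU scales respectively.

These features are invariant to positive rescaling and to inversion of the
raw waveform, and the test suite checks each against an independent
direct-formula implementation.

## Spike-timing features (8)

The autocorrelation histogram (ACH) counts all ordered spike pairs with
|Δt| ≤ 1000 ms (zero-lag self-pairs excluded) at 0.5 ms resolution. The
positive- and negative-lag histograms are averaged into a single-sided
0–1000 ms ACH and upsampled eightfold by polyphase filtering
(`scipy.signal.resample_poly`); small negative ringing values are clipped
at zero since counts are non-negative.

High-frequency features use the mass-normalized 0–50 ms window,
low-frequency the 50–1000 ms window (per-window normalization; the
whole-ACH alternative was rejected because it couples the two windows
through the firing rate). D_KL against the uniform distribution uses base-2
logarithms with 0·log 0 := 0. *Rise time* is the time at which the window
CDF first exceeds 1/e — under this reading a flat (renewal) ACH gives
50/e ≈ 18.4 ms, matching the near-uniform fast-spiking regime, whereas a
"duration above threshold" reading would not. PSD features use the squared
FFT magnitude of the full single-sided ACH with the DC bin excluded
(otherwise total pair count dominates and all centroids collapse toward
0 Hz); the PSD′ centroid uses the absolute adjacent-difference derivative,
since the signed derivative integrates to ≈0 and its centroid is ill-posed.
Whole-unit firing rate is (n−1)/(t_last − t_first); in chunk mode each
spike contributes the mean of its inverse pre- and post-ISIs.

## δ-transformation and spatial features (18)

Three events are detected per channel on the polarity-corrected mean
waveform: NEG (argmin), FMC and SMC (median crossings before/after NEG).
The "median" is a single global level — the median voltage over all
channels and all samples — the only reading that yields one crossing level
for every channel. A crossing is the first sample strictly on the far side
of the median scanning outward from NEG; a channel that never crosses
within the window has the event pinned to the window edge and is excluded
from time- and graph-based features for that event.

The δ-transformation replaces each channel by an impulse at its event time
whose value is the channel's maximal negativity divided by the absolute
global minimum, then shifts all channels together so the main-channel event
sits at sample index 128 (129th sample, 1-based). If the max-TTP channel is
also the max-negativity channel this leaves the main channel identical for
every unit — the "information destruction" property the control analysis
verifies by training forests on waveform features of transformed spikes
(unit AUC exactly 0.5). Residual variability can remain when the two
channels differ; no correction is applied.

Channels whose TTP magnitude is below 25% of the per-unit maximum are
ignored by time- and graph-based features (≥ comparison; ties included;
main channel always kept). Value-based (SPD) features use all channels.

* **Time-based** — offsets of usable non-main channels relative to the main
  channel (whose own offset is identically zero and carries no
  information). Time-lag-SS is the mean squared offset in 10³ μs²;
  Time-lag-SD the population SD in μs (both conventions configurable).
* **Graph-based** — a complete DAG over usable channels with distinct event
  times; edge weight = electrode distance (mm) / time difference (s).
  Longest and shortest paths run from an earliest-event node to a
  latest-event node (otherwise the minimum degenerates to the single
  smallest edge; the unconstrained variant is available behind a flag) and
  are computed by dynamic programming over the time-ordered DAG, verified
  against exhaustive enumeration.
* **Value-based (SPD)** — v = per-channel |maximal negativity| scaled by its
  maximum; count of v ≥ 0.5, population SD of v, and the area under the
  channel-count-versus-threshold curve, which equals Σv exactly.

Degenerate cases (fewer than two usable channels, empty edge set) produce
missing values, not zeros; the classifier imputes them with the
training-set median.

## Chunking

A unit with N spikes and chunk size C ∈ {25, 50, 100, 200, 400, 800, 1600}
is randomly split into ⌊N/C⌋ chunks with sizes in [C, 2C−1] differing by at
most one spike; units with N < C contribute one chunk of N spikes (rather
than being dropped, which would perturb label balance). Chunk waveforms are
averages over chunk members; chunk ACHs are sums of the members'
single-spike ACHs (each taken over the full ±1 s neighborhood in the whole
train). Five across-chunk statistics per feature (mean, SD, 25/50/75%
quantiles) are appended to every row — identical within a unit — and the
no-chunking table carries the same statistics computed from its single
chunk so column sets match. Unit predictions pool chunk votes by majority,
ties toward PV; the continuous unit score for ROC is the PV-vote fraction
(the pooling rule defines only a binary vote, so a continuous score had to
be chosen).

## Classification

Random forests (scikit-learn) over n = 50 stratified 80:20 unit-disjoint
partitions; per class, floor(0.8·count) units train. Class weights follow
n_samples/(n_classes·n_class_samples). The fivefold grid search is grouped
by unit and maximizes mean ROC AUC, ties keeping the earliest grid member;
chunked runs reuse the hyperparameters found by the no-chunking search on
the same partition. The full default grid is n_estimators {10, 50, 100,
500} × depth {None, 5, 10, 20} × min-split {2, 5, 10} × min-leaf {1, 2, 5};
the test suite and the acceptance script use reduced grids (two to four
members) as their problem-size choice — with tens of units and a handful of
features the selected member is insensitive to the grid's extent, and the
chance-level results do not depend on hyperparameters at all. Partition
seeds derive deterministically from a master seed. Chance baselines shuffle
training labels at the unit level, leaving test labels intact.

Region generalization trains on ~80% of one region's units and evaluates on
the held-out same-region test set and on all other-region units;
generalization error is (AUC_train − AUC_other)/AUC_train. When the
development set exceeds 5000 chunks the grid search subsamples to 5000.

## Statistics and attribution

* **A_w** — common-language effect size by pair counting with half-weight
  ties, folded to [0.5, 1]; the two-tailed Mann–Whitney U p-value
  accompanies it.
* **Mutual information** — plug-in estimate in bits on a 10×10 contingency
  of equal-count (quantile) bins; variables with <10 unique values keep
  their natural categories. Quantile binning makes MI(x, x) reach the
  log₂10 ≈ 3.32-bit cap and renders the estimate invariant under strictly
  monotone transforms (equal-width binning is available). Permutation
  p-values use the add-one estimator (k+1)/(n_perm+1), never exactly zero.
* **Group tests** — Mann–Whitney U (two groups), Wilcoxon signed-rank
  (paired/one-sample), Kruskal–Wallis with Tukey's HSD on pooled ranks for
  pairwise correction (a Dunn-type correction is a noted alternative).
  Fully tied inputs return p = 1 with a warning.
* **Attribution** — exact path-dependent TreeSHAP implemented in-package
  for sklearn forests, validated against brute-force Shapley subset
  enumeration on small trees and satisfying per-sample additivity to 1e-6.
  Chunk-statistic attributions are folded into their base feature;
  significance is one-tailed against shuffled-label runs (the shipped
  default of 100 null partitions keeps run times modest; 1000 via config).

## Synthetic populations

The generator emulates the class contrasts, not the biophysics. Each
channel's spike is a smooth monotone-cubic (PCHIP) template — baseline,
small positive pre-hump, zero crossing at the FMC anchor, trough −1 at
NEG, zero crossing at SMC, positive peak one TTP later, decay to baseline —
sampled at 20 kHz. Per-channel event offsets are drawn per unit
(N(0, jitter), truncated at 2.3 SD so draws cannot collide with
neighboring anchors and saturate) and realized as a piecewise-linear time
warp with anchors at the three events; the trough translates rigidly within
±35 μs so its local shape stays symmetric (an asymmetric warp biases the
band-limited minimum toward the wider flank). The soma channel — drawn from
the middle of the shank — has offset zero and the largest amplitude
(exponential decay, 0.022/μm, leaving a plausible 1–5 sub-threshold
channels per unit), so the configured jitters are directly the offset SDs
relative to the main channel and the max-TTP channel equals the
max-negativity channel. Per-spike jitter (`intraunit_drift` × jitter, 0.2
for PYR and 0.5 for PV) plus additive noise (SD 0.05 of the trough) create
across-chunk variability, larger for PV.

Class defaults target the recorded medians: TTP 0.77/0.29 ms, trough width
0.21/0.16 ms, rates 0.69/8.95 spikes/s, FMC jitter 15.9/40.6 μs, NEG
13.5/9.4 μs, SMC 26/24 μs (PYR/PV). PYR trains are bursty — Poisson burst
onsets at rate·(1−b), geometric burst extensions (b = 0.5) with intra-burst
ISIs of refractory + Exp(4 ms) — PV trains are refractory-modified Poisson.
A "null" preset gives both classes one shared parameter set, deleting all
label information. Spike counts per unit are capped at 600 (recovery
stabilizes well below that; the cap bounds run time), and recordings
shorter than 25 spikes are re-extended so every unit is chunkable.

**What the generator does not emulate:** electrode drift over hours,
overlapping-spike collisions, non-stationary firing (theta or state
modulation), correlated noise across channels, LFP, or any dendritic
morphology. Passing tests therefore show that the *pipeline* recovers the
statistics it is built to measure and separates classes that differ in
them — not that real recordings satisfy the generator's assumptions.

Parameter-recovery accuracy: configured firing rates are recovered within
Poisson error; median per-event Time-lag-SDs recover the configured jitters
within 25% at 50 units per class (detection on the 6.25 μs grid, the 2.3 SD
truncation, and the median-level crossing each shave a few percent, all
downward).

## Problem sizes

The shipped tests and the acceptance script run desk-scale versions of the
analyses: populations of 50–100 units (400 s, ≤600 spikes per unit), 50
partitions, and two-member hyperparameter grids. These sizes were chosen so
the full suite completes in minutes while every statistical conclusion
(orderings, chance levels, recovery tolerances) is already stable at them.

## Known limitations

* The δ-transformation's information-destruction guarantee is exact only
  when the max-TTP and max-negativity channels coincide (the generator
  enforces this; real units need not).
* Event detection is grid-limited to 6.25 μs; jitters well below the grid
  step are not resolvable.
* The ACH upsampling can ring near sharp burst peaks; clipping at zero is a
  pragmatic, not principled, remedy.
* TreeSHAP is pure Python and O(trees × leaves × depth²) per sample; cap
  the explained sample count (default 1000) for large forests.
* The generator's region tags are labels only — both regions share one
  generative model unless the caller parameterizes them differently — so
  cross-region generalization on default synthetic data is trivially good.
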