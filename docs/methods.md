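# Methods

This note documents the models, estimators and design choices behind
`szdetect`, in the spirit of the methods sections of the packages it takes
after. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

Intracranial EEG from focal epilepsy is monitored for seizures. A detector
must combine very high sensitivity on the rare ictal windows with a
near-zero false-positive rate on the many interictal hours: at a 1 s
decision rate, even 99.9% specificity means several false positives per
hour, so the pipeline is built around (i) extreme class imbalance and (ii)
explicit false-alarm accounting on seizure-free recordings.

## Preprocessing

Recordings are `channels x samples` matrices in microvolts at a nominal
256 Hz. The chain is:

1. **Notch** — second-order IIR notch at 50 Hz, quality factor 30, applied
   zero-phase (`filtfilt`). The filter family and order are the package's
   choice; only the 50 Hz target is dictated by the line-noise problem.
2. **Band-pass bank** — order-4 Butterworth per band, zero-phase, for the
   six rhythms: B8 (8–13 Hz, α), B13 (13–21, β1), B21 (21–30, β2),
   B30 (30–40, low γ), B40 (40–70, medium γ), B70 (70–120 Hz, high γ).
3. **Sliding window** — length L = 2 s, shift S = 1 s (both configurable;
   L·fs and S·fs must be integral). The window at instant t covers
   (t − L, t]; the stream emits `floor((duration − L)/S)` instants at
   t = L + S, L + 2S, …. The raw first instant t = L is dropped because it
   has no previous segment, and method-A bivariate features would be
   undefined there.

**Labeling convention.** A window is ictal ("Y") iff its *terminal* sample
time lies inside an annotated interval, intervals being half-open
`[start, end)`. Overlap- or midpoint-based rules are equally defensible;
the terminal rule was chosen because it reproduces the few-second onset
delay seen in clinical error analyses (the first windows after onset are
mostly pre-ictal signal) and makes "one Y instant per ictal second" exact:
a 90 s seizure yields exactly 90 positive instants at S = 1.

## Feature engine

Each instant is described by 22 descriptor families on each of the 36
(electrode, band) segments — 14 univariate and 8 bivariate codes, the
bivariate ones computed twice: **method A** against the segment shifted
back by S seconds, **method B** against the null vector. That yields
14·36 + 8·72 = 1080 columns plus the binary target `Actual YN`.

Estimator choices (all configurable via `FeatureConfig`):

- **Entropies** (SH, LE, JE, CE, MI): Q = 16 equal-width amplitude bins
  over each segment's own range, natural logarithm. JE uses the Q×Q joint
  histogram; CE = JE − SH(y); MI = SH(x) + SH(y) − JE. Against a constant
  y the joint histogram degenerates to the x-marginal, so JE-MB and CE-MB
  equal SH *exactly* — a redundancy the correlation filter later exposes
  (their pairwise Pearson correlation is 1), and MI-MB is identically 0.
  LE = Σ ln(x² + ε) with ε = 1e−12 guarding ln 0.
- **Complexity** (KC, LL, LU): the segment is binarized at its median and
  parsed by LZ76. The phrase count convention is that a trailing run fully
  reproducible from history is not counted, so a constant segment has
  exactly one phrase. KC = c·log2(n)/n; LL and LU divide c by the
  asymptotic bound n/log2(n) rounded up and down respectively, so
  LL ≤ LU always. "Kolmogorov complexity" is of course uncomputable; the
  LZ76 surrogate is standard practice on biosignals.
- **Seismic-analogy descriptors** (AP, IP, PD, PP, SG, SP), borrowed from
  earthquake early warning: with i* = argmax |x| and t* = i*/fs, PD is the
  peak displacement, IP = 1/t*, SP = t*², SG = (PD/t*)² (the three
  time-to-peak transforms are 0 when the peak is the first sample). PP is
  the recursive predominant-period estimate τᵢ = 2π√(Xᵢ/Dᵢ) with
  exponentially smoothed squared displacement X and squared velocity D
  (first difference × fs), forgetting factor α = 0.99, reported at the
  window end; AP is the mean of τᵢ over the window. On a pure sinusoid PP
  converges to the period 1/f (verified to 10%).
- **Statistical** (HM, KU, SD): population SD; Hjorth mobility
  √(var(Δx)/var(x)); Pearson kurtosis m₄/m₂². Zero-variance segments map
  to 0 for the ratio forms.
- **Distances** (ED, CC, DT): Euclidean distance; cross-correlation index
  = maximum over all lags of the biased normalized cross-correlation
  (zero-lag-only is the other defensible reading; max-lag was chosen
  because it is shift-tolerant, which is the point of comparing a window
  with its predecessor); DTW with |·| local cost, full window.
- **Symbolic** (LC, LD): both segments quantized to 8 equal-width levels
  over the union of their ranges; LC = LCS length / n, LD = unit-cost edit
  distance (a count, per the original feature inventory).

**Null-vector closed forms.** Against the all-zero method-B partner,
DTW = Σ|xᵢ| (any warping path must visit every i at cost ≥ |xᵢ|, and the
diagonal achieves it), LCS = count of the zero symbol in x (a common
subsequence with a constant string is a run of that symbol), and
LD = n − that count (lower bound n − LCS, met by substitutions). These are
used as exact fast paths and pinned to the generic dynamic programs in the
unit tests.

Degenerate inputs never produce NaN/∞: ratio-type features map to 0 and
the table is checked for finiteness after assembly.

Performance: the quadratic kernels (LZ76, DTW, LCS) are numba-compiled;
Levenshtein goes through `edlib`. Windows are exposed as views into the
band-filtered arrays, so multi-hour recordings never materialize their
overlapping windows.

## Feature selection

Stage 1 scores every column by Information Gain with the binary class,
IG = H(Class) − H(Class|X) in nats, after min-max normalization. The
discretization is supervised entropy minimization with the MDL stopping
rule (Fayyad–Irani), capped at `n_bins` bins. Unsupervised equal-frequency
binning was evaluated and rejected: unless the class prevalence happens to
align with a bin edge, the boundary bin mixes classes and caps the
normalized IG of even a perfectly separating feature at ≈ 0.82 for 15%
prevalence — and ≈ 0.59 at a 1:25 imbalance — so a high IG threshold would
reject *everything* regardless of feature quality. MDL cuts fall only
between points of distinct feature value and depend only on the sort order
and class sequence, so the IG score keeps the desired invariance under
strictly monotone transforms; features with no accepted cut get IG = 0.

The retention test compares the *normalized* ratio IG/H(Class) ∈ [0, 1]
against the threshold (default 0.85). Raw natural-log IG is bounded by
H(Class) ≤ ln 2 ≈ 0.693 — and far lower under class imbalance — so a
threshold of 0.85 can only be meant on the normalized scale.

Stage 2 computes the point-biserial Pearson correlation between each
stage-1 survivor and the class (Y = 1, N = 0) and keeps |PCC| ≥ 0.75.
Values exactly at either threshold are retained; constant features get
PCC = 0.

## Class imbalance: Matthews-optimized undersampling

With hours of interictal signal against minutes of seizures, training
tables reach imbalance ratios (IR = #N/#Y) in the hundreds. OMU draws, per
requested IR, n = 10 random undersamples that keep *every* minority row
and `round(#Y · IR)` majority rows without replacement, scores each by the
Matthews correlation of a 1-NN under stratified 10-fold CV, and selects
the argmax (ties to the lowest resample index). The untouched original
table is carried along under its native IR. Per-resample MCC is computed
on the pooled out-of-fold confusion matrix rather than averaged fold-wise
— pooling is variance-minimal when positives are rare and keeps per-fold
0/0 cases from ever arising. MCC of a degenerate matrix (any zero
marginal) is defined as 0 so the argmax is total.

Seeding is a ladder: the master seed spawns one stream per (IR, resample)
keyed by the IR *value*, so extending the IR list never perturbs existing
draws.

## The k-NN detector

k-NN is lazy: fitting stores per-feature min-max bounds from the training
table and the normalized reference points. Features are normalized before
distance computation (queries clipped to [0, 1]) because the 1080 columns
span wildly different scales — entropies in nats next to microvolt
distances — and unnormalized Euclidean distance would be dominated by a
few large-magnitude families. Prediction enumerates distances to all
references (brute force is the reference path; any accelerated search must
agree exactly), breaks distance ties at the k-th neighbor by reference-row
order, and reports the fraction of Y votes as a score; with k odd the
majority label is Y exactly when the score exceeds ½. The vote fraction
(k + 1 distinct levels) is also what the ROC area is computed from, via
the tie-corrected Mann–Whitney statistic.

## Evaluation protocol and the model grid

The held-out design is phase-aware: the training table T, an IKTAL test
set containing a seizure (for sensitivity), and an INTERIKTAL set of
seizure-free hours (for false-positive counting) are disjoint. Each
(IR, k) cell of the grid records stratified 10-fold CV metrics on its
training set, test metrics on IKTAL, and the INTERIKTAL FP count. Cells
pass CV when Recall-on-Y ≥ 0.92, Precision-on-Y ≥ 0.95 and TNR ≥ 0.998;
candidates additionally need IR ≤ 20. The final model minimizes INTERIKTAL
false positives, breaking ties by higher IKTAL recall, then smaller k,
then smaller IR (the last two make the pick deterministic). If no cell
clears every threshold the selection falls back to all valid cells with a
`thresholds_met=False` flag, keeping the rule total on arbitrary data.

**Alarm rule.** Window positives become alarms only when a maximal run of
consecutive Y predictions spans at least 3 s (run length × S). A run over
instants t_a..t_b covers (t_a − S, t_b]. Isolated one- and two-window
positives — the artifact signature — are suppressed; raising the minimum
duration can only remove alarms.

## Synthetic EEG generator

The generator provides labeled signal with the statistical structure the
pipeline assumes, *not* physiological EEG:

- background: Gaussian 1/f noise (power ∝ 1/f, flattened below 1 Hz,
  RMS 20 µV) plus a 10 Hz alpha sinusoid (default 10 µV) with a random
  phase per channel;
- seizures: on the InFokus channels only, band-limited 45–115 Hz noise at
  RMS `ictal_gamma_amp` (default 100 µV ≈ 4.5× the background RMS), with
  2 s linear onset/offset ramps that reproduce the fuzzy-onset detection
  delay;
- artifacts: isolated 0.5 s broadband transients on all channels at 10×
  the background RMS, at a default rate of 6 per hour — enough to provoke
  the short false-positive runs the alarm rule must suppress.

What passing tests on this signal do show: correct wiring of every stage,
the spectral contract (ictal high-γ power exceeds interictal), exact label
bookkeeping, and that model selection plus the alarm rule deliver
zero-false-alarm behavior under clean class structure. What they do not
show: performance on real iEEG, whose artifacts, drowsiness rhythms and
patient-specific seizure morphologies are far richer; no claim of clinical
sensitivity or specificity follows from these tests.

## Study scale

The default end-to-end study (`szdetect.study`, also what
`scripts/acceptance.py` runs) uses 10 min of ictal training signal with
one 90 s seizure plus 30 seizure-free minutes (~90 Y / ~2300 N windows),
a 10 min held-out seizure recording, and one seizure-free hour. At this
scale imbalance ratios up to 25 are feasible; the larger ratios of the
full protocol (50, 100, and the native ~284) require clinical-scale hours
and are exercised structurally by the same code path. These sizes are the
package's chosen defaults for a desk-scale study; every knob is in
`StudyConfig`.

## Known limitations

- The seismic evaluators and the LL/LU normalizations are documented
  reconstructions from the earthquake-early-warning literature and LZ76
  conventions; the original closed-source feature tool is not public, so
  exact numeric replication of its outputs is a non-goal.
- Whether the cross-correlation index should be zero-lag and whether CV
  confusion matrices should be pooled or fold-averaged are underdetermined
  by the protocol; the choices here (max-lag, pooled) are argued above.
- The histogram MI estimator carries the usual upward plug-in bias
  (≈ (Q−1)²/2n nats for independent inputs); tests account for it rather
  than pretending MI of noise is zero.
- EDF input relies on `mne` when installed; the ASCII matrix dialect is
  the native interchange format.
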