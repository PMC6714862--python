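# Methods

## Problem and pipeline

The package classifies binary emotional valence (positive vs negative)
from multichannel EEG in the *cross-subject* regime: every evaluation
holds out all trials of one subject (leave-one-subject-out, LOSO), so the
reported accuracy measures generalization to unseen people. Cross-subject
accuracy is typically far below within-subject accuracy because feature
distributions shift between individuals; the pipeline attacks this with
aggressive feature selection over a deliberately high-dimensional feature
set.

Stages: label processing → per-channel feature extraction → significance
filter → SVM-driven sequential backward selection → RBF-SVM, evaluated
under LOSO against six baselines on identical folds.

## Data model and label processing

A `TrialSet` is a dense `(n_trials, n_channels, n_samples)` block with a
sampling rate and per-trial subject, session and rating metadata. Two
canonical layouts are described by descriptor factories: a 32-subject
single-session layout (40 trials/subject, 32 channels, 128 Hz, 60 s
trials, continuous 1–9 valence ratings) and a 15-subject × 3-session
layout (15 trials/session, 62 channels, 200 Hz, 240 s trials, categorical
positive/neutral/negative labels). Signals are assumed pre-cleaned
(artifact removal and re-referencing are out of scope).

Continuous ratings binarize around 5: above → positive (1), below →
negative (0). A rating exactly at 5 belongs to neither rule; the default
**excludes** such trials (a flag assigns them to negative instead) —
inventing a class for an unspecified boundary case seemed worse than
dropping it. Categorical sets drop neutral trials. For long categorical
trials a centered window (half-open `[start, start+len)`,
`start = floor((n−len)/2)`) aligns trial length across layouts.

I/O: an HDF5 container (`/signals`, `/fs`, `/subject_id`, `/session_id`,
`/ratings`, `/channel_names`), a CSV directory (one file per trial,
channels as columns, `metadata.json` sidecar) and read-only EDF via mne
(one recording = one trial; labels must then be supplied by the caller).
CSV writers use `%.17g` and readers `float_precision="round_trip"` so
round-trips are bit-exact. Native readers for the license-gated benchmark
distributions are deliberately absent; converting them amounts to filling
the HDF5 container from their arrays with the metadata above.

## Feature extraction

Ten features per channel and trial, computed on the whole trial:

* **Hjorth activity / mobility / complexity** on the broadband signal;
  population-variance convention, constant signals map to (0, 0, 0).
* **Standard deviation**, population (`ddof=0`, configurable).
* **Band power** per rhythm (theta 3–7, alpha 8–13, beta 14–29, gamma
  30–47 Hz): the signal is first band-filtered with a zero-phase 4th-order
  Butterworth (forward–backward `sosfiltfilt`; standard EEG practice, no
  phase distortion), then the mean Welch PSD over the in-band bins is
  taken (Hann windows of 2 s, 50% overlap — 0.5 Hz resolution resolves the
  3–7 Hz band; inclusive band edges).
* **Sample entropy** SampEn(m=2, r=0.2·σ), the Richman–Moorman
  convention: −ln(A/B) with B (A) the number of unordered pairs of
  m-length ((m+1)-length) templates within Chebyshev distance r, self
  matches excluded, `n−m−1` templates per length. Degenerate cases are
  defined, not errors: constant → 0; A=0 → capped at ln B + ln n; B=0 →
  2 ln n. Pair counting uses a k-d tree; the test suite pins it to an
  exact O(n²) enumeration.
* **Wavelet entropy**: db4 discrete wavelet decomposition at 4 levels,
  relative energy p_j per component (one approximation + four details),
  Shannon entropy −Σ p_j ln p_j ∈ [0, ln 5]. The Shannon form (with the
  minus sign, over all components) is used; a non-negative "entropy" is
  the only reading consistent with an order/disorder measure.

Whether the non-PSD features should be computed on band-filtered or
broadband signals is an open choice; broadband is the default (and
configurable), matching the convention that only the PSD features are
rhythm-specific. Columns are channel-major in the fixed order activity,
mobility, complexity, std, PSD-alpha/beta/gamma/theta, SampEn, WE, named
`<channel>__<feature>`; the matrix is validated finite.

## Selection

**Filter stage.** Every column is split by class. One two-sample test is
chosen for *all* columns: Shapiro–Wilk (subsampled to ≤ 500 values per
column-half for stability) decides normality per column-half; if more
than half pass, a pooled-variance two-sided Student's t-test is used,
otherwise the two-sample Kolmogorov–Smirnov test (ties go to the
nonparametric branch). Columns with p < α (default 0.05) are retained in
order. No multiple-testing correction is applied by design — the filter
is a screening step, and its null retention rate ≈ α is itself a tested
property. Welch's t and a KS-against-fitted-normal normality variant sit
behind flags.

**Wrapper stage.** Greedy sequential backward selection: from the
retained set, remove the feature whose removal maximizes the evaluator's
accuracy; repeat to a single feature; keep the best visited subset.
Tie-breaks are deterministic: equal-accuracy removals drop the
largest-index column; equal-accuracy subsets prefer the larger subset
(retain more information). A p-column run visits exactly p subsets and
costs at most p(p+1)/2 − 1 candidate evaluations.

**Leakage control.** By default both stages run *inside* each LOSO
training fold, so the held-out subject never influences selection or
normalization; `paper_faithful=True` instead applies the filter once to
the full matrix before LOSO, reproducing the published variant. If a
training fold retains no columns (plausible under the null), the pipeline
falls back to the full feature set with a warning rather than aborting
the fold, keeping chance-level evaluations defined; the standalone filter
still raises on empty selections.

## Classification and evaluation

Features are z-scored with training-fold statistics (zero-variance
columns pass through centered, with a warning). The classifier is an
RBF-kernel SVM with C = 1 and the `scale` gamma (1/(n_features·var)) —
library-standard defaults, stated for reproducibility and configurable.
Inside a training fold, SBS scores candidate subsets by subject-grouped
k-fold cross-validation (k = min(5, training subjects)); inner grouping
keeps even the inner validation cross-subject.

Baselines on the full unselected matrix: SVM, PCA(95% variance)+SVM,
KNN (k = 5), PCA+KNN, random forest (100 trees, seeded), and SBS-SVM
without the filter stage. Accuracy is the trial-level correct fraction of
the held-out subject; the mean over subjects is unweighted. The
comparison report gives reference-minus-baseline differences in
percentage points and their arithmetic mean, and can also aggregate
externally supplied accuracies or differences. Per-stage wall-clock times
go to the log and run record, not into result files, so identical reruns
are byte-identical.

## Synthetic data

The generator provides ground truth the license-gated benchmarks cannot:
each trial is 1/f^β noise (β = 1, the canonical EEG slope; σ = 5 µV-scale)
plus one sinusoid per rhythm (5, 10, 21, 38 Hz at amplitudes 4, 5, 3,
2) with random phases per trial/channel. The class effect multiplies the
chosen band's amplitude by `effect_size` on the discriminative channels
of positive trials; cross-subject nuisance is a persistent per-subject
amplitude factor ~ Normal(1, `subject_sd`). Valence-mode ratings are
drawn from U(6, 9) for positive and U(1, 4) for negative trials (clear of
the boundary at 5, balanced within subject); categorical mode emits equal
thirds per session in shuffled order. A direct tabular generator
(informative columns mean-shifted by δ, per-subject random intercepts)
serves the fast selection/classification tests.

What this does *not* emulate: volume conduction and electrode geometry,
non-stationarity, artifacts, realistic rating noise, or subject-specific
*spectral* (rather than amplitude) idiosyncrasies. Passing tests
therefore show the pipeline recovers a band-limited amplitude effect
under multiplicative subject variation — not that it attains any
particular accuracy on real recordings. Planted-effect recovery is scored
at channel level (an amplitude change perturbs several features of the
same channel): precision = share of selected columns on discriminative
channels, recall = share of discriminative channels selected at all.

## Problem sizes and numerical choices

Examples, tests and the acceptance script run the two canonical layouts
at shortened trial durations — 2 s for the 128 Hz layout and 6 s (with a
2 s centered window) for the 200 Hz layout — chosen as the package's
desk-scale default: the matrix dimensions (1280 × 320 and 450 × 620) are
duration-independent, and 2 s is the minimum supporting one Welch
segment. Pipeline statistics use small layouts (4–6 subjects, 3–6
channels) where LOSO with per-fold SBS completes in seconds.

Determinism: all randomness flows through `numpy.random.default_rng`
seeds; SBS and subset tie-breaks are fully deterministic; repeated runs
with the same config produce byte-identical artifacts (except the
wall-clock log in the run record).

Known limitations: the SBS wrapper is O(p²) SVM fits per fold and is
meant to run *after* the filter stage, as in the method's design —
applying it to hundreds of columns is possible but slow; sample entropy
on very long trials dominates extraction time; and the published retained
column counts and absolute accuracies on the real benchmarks depend on
the licensed data and are not targets of the synthetic validation (the
published per-method *aggregation* arithmetic is reproduced exactly).
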