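# Methods

This note records the models, numerical choices and limitations behind each
stage of the pipeline. Units: voltages in microvolts (µV), times in seconds
unless marked ms, current source density (CSD) in arbitrary units (a.u.).

## Slow-oscillation detection

The detector operates per electrode on the 0.1–4 Hz band. The filter is a
4th-order Butterworth applied forward–backward (`sosfiltfilt`), chosen
because zero-phase filtering preserves trough timing — the anchor for every
downstream step. Candidates span a positive-to-negative zero crossing to
the following negative-to-positive crossing; the trough is the minimum of
that span and the peak the maximum up to the next positive-to-negative
crossing. Acceptance requires, in order:

1. trough ≤ −80 µV (the threshold is on the filtered signal; the printed
   criterion is read as a *negativity* bound — a literal "below 80 µV"
   would accept almost everything),
2. peak-to-peak ≥ 80 µV,
3. zero-crossing interval in [0.3, 1] s,
4. full candidate span (down state plus following up state, i.e. to the
   next positive-to-negative crossing) ≤ 10 s. The zero-crossing criterion
   already bounds the negative half-wave, so the duration criterion is
   only meaningful on this longer span.

Rejections carry the first violated criterion. A practical observation
from the synthetic experiments: with a 0.1 Hz zero-phase high-pass, the
duration criterion is nearly vacuous — any waveform positive for more than
about 9 s has its spectral mass below the passband and is suppressed or
reshaped into a shorter event, so >10-s candidates essentially cannot
occur in the filtered signal. The criterion is retained (and tested on
constructed candidates) for fidelity and for configurations with a wider
band.

The amplitude screen uses the trough referenced to the mean of the raw
signal within ±10 s (window clipped at recording edges rather than
dropping edge events): events above mean + 4 SD of their electrode's
distribution are discarded (electrodes with fewer than two events are
skipped — the SD is undefined), then the pooled distribution of stage-1
survivors is screened once more at mean + 4 SD. The screen is one-sided
(large-amplitude artifacts are the target) and uses the sample SD
(ddof = 1). Event troughs must fall inside a selected, artifact-free
30-s epoch; the waveform may extend beyond it.

## Scalp space-time typing

Co-detection vectors are binary over the montage: electrode *e* is set
when it holds any SO trough within ±400 ms of the reference trough
(boundary inclusive). Clustering is k-means under Hamming distance
(proportion of mismatched bits): kmeans++ initialization with squared
Hamming weights, assignment ties to the lowest cluster index, centroid
update by per-column majority vote with ties resolved to 1 (a fixed rule
keeps runs deterministic), empty clusters dropped, best of 200 replicates
by total within-cluster distance (ties to the lowest replicate index).
`k` defaults to 3 — the number of scalp types the clustering is meant to
expose — but is configurable, as is the replicate count.

Cluster naming is threshold-based on the mean topography: grand mean
≥ 0.8 → Global; else frontal-subset mean ≥ 0.6 with non-frontal mean
< 0.6 → Frontal; else Local. The thresholds are package defaults (the
published practice is visual inspection of the cluster topographies) and
are exposed in the API and CLI. The frontal subset is derived from 10–20
labels (Fp/AF rows and the F row proper, excluding FC/FT), also
configurable.

## Inverse modeling

The inverse kernel is minimum-norm with identity noise covariance,
M = Lᵀ(LLᵀ + λI)⁻¹, followed by sLORETA standardization: each source row
divided by the square root of its resolution-matrix diagonal entry
(R = ML). The kernel depends only on the lead field, never on data, and is
computed once per head model.

* λ defaults to trace(LLᵀ)/(n_sensors · SNR²) with SNR = 3, a standard
  regularization heuristic; any non-negative value can be passed.
* Lead field and data are projected to the average reference before
  inversion by default (minimum-norm solvers conventionally operate there,
  and it makes common sensor offsets map to exactly zero CSD); the flag
  can be disabled for analytic checks such as the orthogonal-lead-field
  identity limit.
* Sources are scalar (fixed-orientation) dipoles, one per location.
* Region/time aggregation uses the magnitude of the standardized estimate,
  so depth profiles are non-negative; signed estimates remain available.
* A `DipoleGridConfig` validator carries the bookkeeping for template-grid
  configurations (default: 15,002 cortical + 5,095 subcortical vertices,
  20,097 single-dipole voxels).

sLORETA's zero-localization-error property — for noiseless single-source
data the standardized estimate peaks exactly at the active source — is
verified exhaustively on the toy head models. The guarantee does not
extend to simultaneous multi-source activity: nearby sources interfere,
and with the toy model's nearly collinear within-region columns the
runner-up estimate often sits beside rather than at a second source. The
two-source test therefore uses a brute-force-verified well-separated pair.

## Depth embedding and cohort statistics

Seventeen regions (eight bilateral structures plus the unlateralized
brainstem) × three 200-ms bins — pre-trough [−300, −100) ms, trough
[−100, +100) ms, post-trough [+100, +300) ms, half-open so every sample
belongs to exactly one bin and the trough sample itself lands in the
trough bin — yield a 17 × 3 matrix per SO, flattened row-major to 51
features named `<Region>_<L|R>_<pre|trough|post>`. CSD is sampled at the
native EEG rate inside the ±300 ms window with no interpolation (kernel
linearity makes per-sample application cheap).

The cohort contrast takes, per participant, the mean Global and mean
non-Global CSD per region within one bin, and compares the paired series
across participants with a Wilcoxon signed-rank test — exact null
distribution for cohorts of ≤ 25 participants, normal approximation
beyond — flagged at the Bonferroni level 0.05/17 ≈ 2.9·10⁻³. Participants
lacking one class are dropped from the pairing with a warning. Omnibus
repeated-measures ANOVA layers are out of scope; only this post-hoc layer
is implemented.

## Classification battery

Thirty named learners cover the classical categories: three decision-tree
presets, LDA/QDA, logistic regression, Gaussian and kernel naive Bayes,
six SVMs (linear, polynomial degree 2 and 3, three RBF presets), six
nearest-neighbor variants (k = 1, 10, 100, cosine, Minkowski-3,
distance-weighted), five ensembles (boosted, bagged trees, random-subspace
LDA and KNN, boosting on an undersampled majority class), and five small
multilayer perceptrons. `DEFAULT_BATTERY` is a 16-learner subset that
skips the slowest presets. Kernel naive Bayes is a per-feature
Gaussian-KDE estimator (Scott bandwidths) written here; the
undersample-boost learner pairs AdaBoost with a seeded random undersample.
Exact hyperparameter equivalence with any external toolbox is not claimed;
every preset is replaceable by passing `(name, factory)` pairs.

Scoring is MCC with the explicit convention that a non-positive
square-root argument yields 0 — chosen because the Global class is
typically the minority and accuracy-style metrics mislead under imbalance.
No resampling is applied. Validation schemes: stratified 5-fold CV with
per-fold confusions summed before a single MCC (per-fold MCCs on small
folds are unstable; the per-fold-mean mode is still available), stratified
25 % holdout, and train-equals-test. Features are z-scored with statistics
from the training split only. Datasets with fewer than five events in
either class are recorded as skipped rather than raised, so cohort runs
survive participants without Global SOs. All splits and stochastic
learners are seeded; deterministic learners are bit-reproducible across
runs at a fixed seed.

## Feature ranking

Each feature is discretized into up to 10 quantile bins computed on the
combined sample — quantile binning makes the score invariant under any
strictly monotone rescaling of the feature — then adjacent cells with
expected count < 5 are merged before a chi-square independence test
against the class label. Scores are −log₁₀ p with p clamped at 1e−300
(perfect separations underflow); constant features score 0. Raw score
magnitude grows with the number of events, so per-individual score
vectors are normalized to unit sum before averaging into the
across-individuals ranking (SEM retained for error bars). The retained
top set ends at the largest gap between consecutive sorted scores, ties
to the smallest index; when multiple comparable peaks exist, the full gap
profile is available for choosing alternate cutoffs, and equal-score
degenerate input retains everything with a warning.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *acquisition geometry and statistical
structure* the pipeline assumes: 58 channels at 500 Hz with 10–20 labels,
30-s staged epochs, SOs as biphasic half-sine down/up states (trough
≤ −80 µV, down-state duration 0.3–1 s) planted Globally (all channels,
per-electrode delays within ±400 ms), Frontally (frontal row only) or
Locally (three scattered channels), over i.i.d. Gaussian noise (default
SD 15 µV, the scale of broadband background EEG in the slow band; a 1/f
option exists). The default up state (25 µV, 0.5 s) is deliberately
smaller than the down state, as in real SOs; it also keeps the filtered
trough within one sample of the planted time, which the planting tests
rely on. Plans whose events overlap on an electrode are rejected at
validation.

The toy head model places sensors on the upper unit hemisphere, 17
regional source blobs on an inner sphere, and an analytic distance-decay
gain g = 1/(ε + r²). It is deliberately not a boundary-element model: its
purpose is a full-sensor-rank forward operator on which inverse-kernel
properties are *exactly* testable at desk scale.

Depth datasets draw features as |N(1, 0.2)| a.u., with Global rows
shifted by `effect_size · SD` on exactly the planted features (scalar or
graded per feature).

What passing tests therefore show: the detector, clustering, inverse
operator, embedding, classifiers and ranking implement their definitions
correctly and recover planted structure under controlled conditions. What
they do not show: performance on real polysomnography — real EEG has
non-Gaussian artifacts, non-stationary background, correlated noise
across channels, realistic cortical geometry and volume conduction, none
of which the generator models.

## Problem sizes

Default experiment sizes were chosen to make every property measurable
with comfortable statistical margins at desk scale: 10-minute noiseless
recordings for the detection oracle (34 planted SOs, 902
electrode-detections, 33 decoys), 300 co-detection rows for clustering
recovery, 100 random draws over the 85-source model for localization,
2000 + 2000 profiles for classifier recovery (weighted-KNN cv5 MCC ≈ 0.9
at a d = 1 shift on 15 features, against a Bayes-optimal MCC ≈ 0.95 for
that generative model), and 50 seeded replicates of the 15-strong/36-weak
ranking experiment.

## Known limitations

* The EDF writer emits a minimal 16-bit header sufficient for standard
  readers; annotations, discontinuous records and EDF+ are not supported.
* Hamming k-means is exact but dense; co-detection matrices beyond ~10⁵
  rows would need a mini-batch variant.
* The duration criterion is unfalsifiable at the EEG level under the
  default band (see above).
* Cluster-naming thresholds are heuristics standing in for expert review
  of topographies; atypical montages may need tuning.
* The kernel naive Bayes learner is O(n_train · n_test) per feature and is
  the slowest battery member at large n.
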