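# Methods

This note documents the models implemented in `swdeemd`, the parameter
choices that matter, what the synthetic generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Wavelet denoising (`swdeemd.wavelet`)

The noise model is additive: the observed signal is the clean signal plus
white Gaussian noise.  Denoising decomposes the signal with a db7 discrete
wavelet transform to level 4 (symmetric boundary extension), shrinks the
**D2** detail band only, and inverts the transform.

* **Threshold.** Universal rule λ = σ·√(2 ln N) with N the *signal*
  length (not the coefficient count).  σ is estimated from the D2 band
  itself as the median absolute deviation about the median divided by
  0.6745 — the Gaussian consistency constant of the **median** absolute
  deviation.  A mean-absolute-deviation reading of that estimator is
  inconsistent with the 0.6745 constant, so the median convention is
  used.
* **Shrinkage.** Non-negative garrote, c → c − λ²/c for |c| > λ and 0
  below: odd, continuous at |c| = λ, and always a contraction.  Soft and
  hard rules are available through `WdConfig.shrinkage`.
* **Why only D2?** The denoising stage targets high-frequency noise in a
  single band; the EEMD stage afterwards handles the low-frequency
  contaminants.  Thresholding every band with a λ estimated from D2 is a
  selectable deviation a user can build from the primitives, but the
  default is the literal single-band rule.
* Padding is symmetric; with it the transform is slightly redundant, so
  "energy never increases" holds only up to boundary terms (observed well
  within 1e-8 on random signals, and asserted at that tolerance).

## EMD and EEMD (`swdeemd.emd`)

EMD extracts intrinsic mode functions (IMFs) by sifting: subtract the
mean of the upper (maxima) and lower (minima) cubic-spline envelopes
until the candidate is an IMF, then recurse on the remainder.  The
residual absorbs whatever cannot be decomposed, so the additive identity
signal = Σ IMFs + residual holds to machine precision by construction.

* **Stopping.** A sift ends when the Cauchy criterion
  SD = Σ(h_prev − h_new)²/Σh_prev² < 0.2 holds **and** the candidate
  satisfies the IMF counting property |#extrema − #zero-crossings| ≤ 1,
  with a 50-sift cap.  The SD criterion alone (Huang's convention) does
  not guarantee the counting property, which downstream consumers of
  IMFs reasonably assume, hence the conjunction.
* **End effects.** Before spline fitting, the two edge extrema of each
  envelope are mirrored about the signal boundaries.  This tames the
  divergence of free cubic splines outside the extremal support.
* **EEMD.** T independent white-noise perturbations of amplitude
  noise_scale·std(signal) are decomposed and averaged per IMF *ordinal
  position*; members producing fewer IMFs contribute zeros.  Defaults
  T = 100, noise_scale = 0.2 (the canonical ensemble settings); the
  reconstruction then differs from the input by the ensemble-mean of the
  added noise, O(noise_scale/√T).  Everything is seeded through
  `EEMDConfig.seed` via independent per-member bit streams.
* **Degenerate configuration.** noise_scale = 0 with T = 1 short-circuits
  to plain EMD, exactly.

## Hybrid preprocessing and features (`swdeemd.features`)

The WD-EEMD arm wavelet-denoises the signal, decomposes the result with
EEMD, and keeps **IMF1 + IMF2 + IMF3** as the analysis signal.  Because
only three modes are kept, the EEMD is run with `max_imfs = 3`; the
residual then absorbs exactly what deeper sifting would have produced,
and the kept sum is unchanged.  PLI residue and baseline wander land in
the discarded low-frequency content: on contaminated synthetic data the
kept sum loses ≳95 % of sub-5 Hz band power.  Features are computed on
the summed modes, not per mode: the 4-channel × 11-feature = 44-column
accounting only works without a per-IMF expansion (a per-IMF mode is not
provided).

Windows are W = round(256 ms · fs) samples with step
S = round(W·(1 − overlap)); the default 25 % overlap gives S = 192 at
1000 Hz.  The overlap itself is a free parameter of the protocol — the
source material never quantifies it — and it has a measurable
consequence discussed under *Known limitations*.

The nine default features implement the printed window formulas exactly,
including two deliberate literalisms:

* **VAR** is Σy²/(M−1) *without* mean subtraction.  That is the formula
  as stated, not the statistical variance; `central_variance=True`
  selects the conventional estimator.
* **ZC** counts strict sign alternations of consecutive samples — an
  exactly-zero sample breaks a crossing.  **SSC** counts strict interior
  extrema.  Both accept an optional deadband, defaulting to 0 (the
  printed predicates have none).

Skewness and kurtosis use the population σ; a zero-variance window
leaves both undefined, so they are reported as 0 and the row is flagged
`degenerate` rather than leaking NaN into classifiers.  The extended bank
adds waveform length (WL = Σ|Δy|) and integrated EMG (IEMG = Σ|y|) to
realise the 44-column layout; the two extra features are conventional
choices, as the source bank names only nine formulas for its eleven
features.

## SMOTE (`swdeemd.resampling`)

Classic single-u SMOTE: base rows cycle round-robin through the minority
class (keeping synthesis counts exact and coverage even), one of the k = 5
Euclidean nearest minority neighbours is drawn uniformly, and the
synthetic row is x + u·(neighbour − x) with one u ~ U(0,1) shared across
features — so every synthetic row lies on the segment between its two
parents, a property the tests verify by solving for u coordinate-wise.
A per-feature-u variant and a standardise-before-kNN option exist behind
flags (feature magnitudes span orders of magnitude; the default matches
the published algorithm, which does not scale).  Oversampling stops when
the minority count reaches round(target_ratio · majority count).
Synthetic rows are flagged in provenance and carry `synthetic_*` subject
ids, which is how the flag survives CSV round-trips.

## Evaluation (`swdeemd.evaluation`)

Seeded stratified k-fold (default 10) cross-validation.  When SMOTE is
enabled it is applied to the training rows of each fold only, strictly
after the split; the input matrix must contain no synthetic rows, and
each fold's report records the number of synthetic rows in its test set
(structurally always 0) so the no-leakage contract is auditable from the
output.

Because precision and recall on imbalanced data change meaning with the
positive-class convention — and a majority-only predictor shows
recall 100 % under one convention and precision 0 % under the other —
reports always carry **both** conventions (positive = healthy minority
and positive = abnormal majority), per fold and pooled.  Per-fold metrics
are macro-averaged; the pooled confusion matrix and ROC (threshold sweep
over pooled positive-class scores) are reported separately.  Classifier
defaults follow the study grid (entropy tree, Gini tree, bagging with 10
estimators, gradient boosting with 100 depth-3 trees, random forest and
extra trees with 100 trees, RBF SVM, one-hidden-layer-of-100 MLP); a
single stratified holdout is available alongside k-fold.

## The synthetic generator (`swdeemd.synthetic`)

What it emulates: 4 muscle channels at 1000 Hz; clean activity as white
Gaussian noise band-passed to 20–460 Hz (zero-phase, order-4 Butterworth)
and amplitude-modulated by a raised-cosine burst per gait cycle
(1.1 cycles/s, duty 0.4) on a tonic floor of 0.1 — real walking sEMG has
baseline muscle tone, and the floor also avoids identically-zero
inter-burst windows; additive white noise at 15 dB SNR; a 50 Hz PLI tone
at 0.2× the clean process RMS; baseline wander (<4 Hz filtered noise) at
0.3×.  Contaminant scales reference the *analytic* process RMS (filter
noise gain × closed-form envelope RMS), never a recording's realized RMS:
a realized-RMS reference imprints a per-recording amplitude fingerprint
that window-level cross-validation can exploit.

Gait is deliberately non-stationary: each recording starts at a random
cycle phase and successive cycle durations jitter with a CV of 5 %
(stride-time variability is a robust property of real gait), and the
mains phase wanders slowly.  Without these, recordings of different
lengths sample *different discrete sets* of gait phases, which is
class-distinguishable under duration-driven imbalance even with zero
class effect.

The class effect (default 0.4) scales per-channel amplitudes by
1 + effect·(0.8, −0.4, 0.5, −0.6) — a quadriceps/hamstring imbalance
pattern — and lengthens the burst duty by 20 %·effect (prolonged muscle
activation).  At effect 0 the two classes are generated by the identical
process.  Imbalance comes from duration, not subject count: 11 subjects
per class, healthy recordings 6.1 s and abnormal 4.48× longer, chosen so
the default windowing yields 341 healthy and 1562 abnormal windows —
within 2 % of the 342/1533 window split of the motivating study data.

What it does **not** emulate: motor-unit physiology, electrode placement
and crosstalk, per-subject anatomical variability (all subjects of a
class are draws from one process — deliberately, so the null condition is
exactly null), transition-state movements, and non-Gaussian artifact
bursts.  Passing tests therefore show the pipeline's *mechanics* are
correct and its qualitative behaviour (denoising benefit, SMOTE's
minority F-score effect, null calibration) is right; they do not predict
absolute accuracies on real clinical data.

## Problem sizes used by the tests and acceptance script

All chosen as the package's own desk-scale study conditions: null
calibration uses 10 subjects/class × 6 s with adjacent windows and an
extra-trees classifier (1280 windows); the SMOTE effect-direction
experiment uses 6 subjects/class × 4 s across 10 generator seeds; the
determinism rerun uses 2 subjects/class with a T = 5 ensemble; EEMD
ensemble contracts use 512-sample two-tone signals at T = 10 vs 100; the
separability ceiling uses 8 subjects/class × 6 s, no contaminants, class
effect 1.0, and a depth-6 class-weighted decision tree (class-weighted
because the probe scores *balanced* accuracy on ~4.5:1 imbalanced rows).

## Known limitations

* **Window-overlap leakage.** With 25 % overlap, adjacent windows share
  64 ms of signal and slow processes correlate across neighbours, so
  window-level cross-validation puts correlated copies of the same
  stretch in train and test folds.  Under a null class effect this
  inflates AUROC by a few hundredths — a protocol artifact, not class
  signal.  The null-calibration experiment therefore uses adjacent
  (non-overlapping) windows; results obtained with overlapping windows
  should be read with this caveat, on real data as much as on synthetic.
* Subject-level generalisation is not measured: folds stratify windows,
  not subjects, mirroring the evaluated protocol.  A grouped-by-subject
  CV would be the stricter design.
* EMD is a numerical procedure without a convergence guarantee; the
  sifting cap (50) is a pragmatic bound, and decompositions of signals
  with plateau artifacts may be sensitive to the extrema convention
  (plateaus count once, at their trailing edge).
* The garrote/universal-threshold stage assumes roughly Gaussian D2
  noise; heavy-tailed artifacts inflate the MAD estimate and weaken
  shrinkage.
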