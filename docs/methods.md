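# Methods

`rrbscope` implements a simultaneous EEG functional-connectivity and
eye-tracking analysis for the restricted-interest stimulus paradigm in young
children: two groups (ASD, typically developing), two stimulus classes
(high/low restricted-interest images, HRIS/LRIS), 12 trials per class, 10 s
per stimulus.  This note records the models, the numerical choices, and what
the synthetic benchmark does and does not establish.

## EEG preprocessing

Epochs cover −1 to +2 s around stimulus onset at 250 Hz (the sampling rate is
configurable; 250 Hz is the package default) on a 20-channel 10-20 montage.
The chain is: band-pass 0.1–30 Hz → 50 Hz line removal (2 harmonics) →
baseline correction over the full prestimulus second → ±100 μV threshold
rejection (closed interval; "exceeding" is read strictly) → spherical-spline
interpolation of bad channels → average reference → surface Laplacian.

**Band-pass.** The squared magnitude response of a 4th-order Butterworth is
applied in the frequency domain.  This is the zero-phase forward–backward
equivalent, chosen deliberately over time-domain `filtfilt`: a 0.1 Hz
high-pass pole settles over roughly 10 s, longer than a 3 s epoch, so
filtfilt's initial-condition transient contaminates the entire segment (in
measurements, a pure 45 Hz tone emerged with only ~4 dB RMS attenuation, all
residual energy below 5 Hz).  Frequency-domain application removes DC exactly
(the digital high-pass has a zero at z = 1) and attenuates 45 Hz by >28 dB.
The cost is circular-convolution leakage at the epoch edges, which the
wavelet edge guard (below) already excludes from every analysis window.

**Line noise** is removed by least-squares regression of sine/cosine pairs at
50 and 100 Hz per trial and channel — exact for deterministic mains
interference and near-orthogonal to broadband EEG, much simpler than a
multitaper approach and fully testable.

**Surface Laplacian / interpolation.** Both use Perrin-style spherical
splines with the series kernels

    g(x) = Σ_{n≥1} (2n+1) / (n(n+1))^m · P_n(x) / 4π
    h(x) = Σ_{n≥1} (2n+1) / (n(n+1))^(m−1) · P_n(x) / 4π

with m = 4, 50 terms, and regularization λ = 1e−5 (the CSD literature's
standard defaults).  The spline is fitted under the Σc = 0 constraint via an
augmented (KKT) linear system, which makes the current-source-density output
exactly invariant to adding a constant across channels and exactly zero for a
spatially uniform potential.  Electrode positions come from the idealized
10-20 sphere (classical arc fractions; F3/F4/P3/P4 at great-circle midpoints
of their neighbours).

## Time–frequency analysis and connectivity

**Morlet transform.** Complex Morlet wavelets, 3 cycles, 4–30 Hz in 1 Hz
steps, unit L2 norm, truncated at ±5σ_t.  Points within n_cycles/(2f) of the
epoch edges are excluded from all analysis windows (edge guard); the
−624…−376 ms baseline and 500–1400 ms analysis windows are interior at these
settings, so the guard protects against misuse rather than changing results.

**ERD.** Percent change of trial-mean power relative to the
−624…−376 ms baseline mean, per channel and frequency; negative = 
desynchronization.  The synthetic generator scales post-stimulus carrier
amplitude by 0.7, so alpha ERD ≈ 100·(0.49−1) = −51% at low noise (measured
≈ −48.5% at the default noise level because band-limited background noise
dilutes the ratio).

**WPLI.** At each (frequency, time) grid point within 8–13 Hz × 500–1400 ms,
with cross-spectrum X_k = c_i(k)·conj(c_j(k)) across trials k:

    WPLI = |Σ_k Im X_k| / Σ_k |Im X_k|,   0/0 → 0.

The matrix entry is the unweighted mean over the grid (per-point-then-mean;
the pooled alternative differs only in weighting).  The estimator is the
standard (non-debiased) form; a debiased variant is available behind a flag.
The baseline window plays no role in WPLI (it is baseline-free); it enters
only the ERD.  One numerical convention: imaginary parts smaller than
1e−12·|X| are treated as zero — on FMA hardware, `Im(z·conj(z))` evaluates to
~1e−16 rather than 0, and without the guard two identical channels would
score WPLI ≈ 1 instead of the defined 0.

## NBS inference

Edge-level pooled-variance t tests (Welch behind a flag; paired contrasts as
one-sample t on per-subject condition differences), thresholded at two-tailed
p < 0.005 with the t sign matched to the contrast direction; connected
components of the suprathreshold graph are measured in **edges** (the
standard extent statistic).  The null permutes group labels (two-sample) or
flips per-subject difference signs (paired), recording the maximal component
extent; per-component FWER p = (1 + #{null ≥ observed}) / (n_perm + 1), with
exact enumeration whenever the permutation space is smaller than the
requested permutation count.  Defaults: edge α 0.005, component α 0.05,
10,000 permutations.

Degenerate edges: zero pooled variance with equal means gives t = 0, p = 1,
flagged; zero variance with *different* means is perfect separation and is
capped at |t| = 1e6 rather than zeroed — treating it as null would make a
perfectly discriminative edge invisible to selection.

## NBS-Predict

Stratified 5-fold cross-validation repeated 10 times.  Inside each training
fold only: per-edge two-sample t test, edges with p < 0.01 retained, and the
**largest connected component** of the surviving edges becomes the feature
subnetwork (plain thresholding is available behind a flag).  Features are
standardized with training-fold statistics; classifiers are logistic
regression (L2, C=1), a linear SVM (C=1), and LDA without shrinkage —
hyperparameters are never tuned.  AUC is computed per fold from pooled
decision scores, then averaged; the best model is the one with the highest
mean AUC.  Folds with no surviving edge score 0.5 (chance) and are logged.
If LDA's svd factorization fails on a zero-within-class-variance feature, the
fold falls back to the nearest-centroid discriminant (LDA's limit under
vanishing scatter).  Significance comes from rerunning the CV under label
permutation (5,000 permutations by default; a reduced single-repeat
configuration is used inside the permutation loop, and smaller counts are
available for desk-scale runs); p = (1 + #{null mean AUC ≥ observed}) /
(n_perm + 1).  The weighted network is each edge's selection frequency over
all (repeat, fold) pairs.

## Eye tracking

Fixation reports are parsed header-driven (column order free, extra columns
preserved); rows with malformed numeric fields are kept but flagged invalid
and count toward missingness.  A trial is *missing* when it has no valid
fixation longer than 100 ms — defining missingness after the duration filter
keeps the invariant that adding a sub-100 ms fixation can never change any
feature.  A subject × condition cell with more than 30% missing trials is
discarded (exactly 30% is retained); otherwise missing trials are imputed
with the mean of the observed per-trial totals when |sample skewness| ≤ 1,
with the median otherwise.  TFT is the per-trial sum of retained fixation
durations averaged over trials (the group-level magnitudes of 2.2–5.9 s fit a
per-trial quantity under 10 s stimuli, not a 12-trial total); pupil size is
the pooled mean over retained fixations (imputed trials contribute no
fixations and therefore do not enter the pupil pool).

## Statistics and reporting

Welch t from summary statistics (mean ± SEM) with Satterthwaite df — the form
needed to check published group tables; pooled-variance t for raw data.
Pearson correlations with Benjamini–Hochberg adjustment, the FDR family being
exactly the set of pairs submitted in one call (the family size is logged);
ADOS-related correlations are computed within the ASD group only, since TD
subjects carry no scores.  ROC analysis uses the midrank Mann–Whitney AUC
(identical to the trapezoidal area, ties included), a stratified percentile
bootstrap CI (2,000 resamples, seeded), and the Youden-optimal cutoff with
ties broken toward higher sensitivity.

## Synthetic data generator

The generator defines the study conditions every test runs under:

* **EEG**: each channel carries a 10 Hz carrier (5 μV) with a per-trial
  random phase on 1/f pink noise (SD 2 μV, β = 1, independent per channel).
  On a Bernoulli(κ) fraction of trials, the second channel of each planted
  edge inherits the first channel's phase plus a fixed lag (default π/4;
  0 and π are WPLI-invisible and trigger a warning).  The default planted
  set is a 5-edge parieto-occipital *star* around Pz — a star keeps the
  configured lag exact on every edge, whereas chained edges compound it (two
  π/2 steps land at π).  Post-stimulus carrier amplitude ×0.7 induces ERD.
  Default coupling: ASD 0.80/0.45 (HRIS/LRIS), TD 0.35/0.60 — the ASD group
  couples more under high restricted-interest stimuli, TD under low, and TD
  baseline coupling is nonzero so between-group tests are nondegenerate.
* **Eye tracking**: per-trial total fixation time is drawn around a
  subject-level mean; group × condition means follow the reported
  restricted-interest magnitudes (e.g. ASD/HRIS 4853.30 ms, TD/HRIS
  2628.98 ms) and between-subject SDs are the printed SEMs scaled by √n, so
  group-level t statistics land on the reported scale.  Within a trial,
  durations are lognormal weights rescaled above a 150 ms floor so the trial
  sum is exact and every generated fixation survives the 100 ms filter.  A
  configurable fraction of subjects (default 10%) receives 4 of 12 trials
  missing in both conditions to exercise the discard rule.
* **Clinical scores**: the RRB sub-score is an affine function of each ASD
  subject's planted-edge WPLI plus Gaussian noise with SD solved analytically
  from the target correlation (default r = 0.77): σ_ε = σ_RRB·√(1−r²).  If
  any score would be negative the whole vector is shifted up — an affine
  shift preserves the correlation exactly, where clipping would not.  SA is
  independent; total = SA + RRB; TD records carry no scores.

What the generator does **not** emulate: ocular/EMG artifacts (so the
threshold-rejection stage is exercised only by planted excursions, and no
ICA stage exists), saccade dynamics or gaze position, volume conduction
between non-planted channels, and realistic dense-net geometry.  Passing
tests therefore demonstrate the correctness and calibration of the
estimators and inference machinery under the planted-effect model — not that
real infant EEG would yield the same effect sizes.

## Problem sizes in the validation suite

Calibration and error-control checks run at sizes chosen to make their
Monte-Carlo error small while keeping the suite quick: WPLI κ-calibration at
200 trials; NBS family-wise error on 1,000 null datasets (15/15 subjects,
20 channels, 500 permutations each) against the 0.05 + 2·binomial-SE bound;
NBS power on 100 replicates of a planted 5-edge star at Cohen's d = 2
(20/20); NBS-Predict chance calibration over 500 folds and recovery at d = 2
(30/30).  The null and planted datasets for the NBS/NBS-Predict checks are
drawn directly at the connectivity-matrix level (symmetric Beta(2,8) noise):
FWER control and selection behaviour are properties of the permutation and
cross-validation machinery under exchangeability, and matrix-level nulls
make a 1,000-dataset simulation feasible where full EEG synthesis would not
be.  The end-to-end determinism check runs the whole pipeline twice at a
reduced scale (6/6 subjects, 6 trials per condition, 100/10 permutations)
and compares manifests byte for byte.

## Known limitations

* The paired HRIS-vs-LRIS and group contrasts share one planted mechanism;
  no interaction model beyond the 2×2 κ table is provided.
* The ET↔ADOS correlations are not planted; only connectivity↔RRB is.
* `simulate_clinical` calibrates against the empirical variance of the
  supplied connectivity summaries, so the realized correlation at small n
  fluctuates around the target (≈ ±(1−r²)/√n).
* Channel-level bad-channel detection is not implemented; bad channels are
  an input flag (the synthetic data generates none).
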