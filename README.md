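# rrbscope

Simultaneous EEG functional-connectivity and eye-tracking analysis of
restricted-interest stimuli, for researchers studying restricted and
repetitive behaviors (RRBs) as early biomarkers of autism spectrum disorder.

Young children view images that either strongly engage circumscribed
("autistic") interests — vehicles, appliances — or neutral objects (high vs
low restricted-interest stimuli, HRIS/LRIS), while EEG and gaze are recorded
together.  `rrbscope` implements the full analysis stack for this paradigm:

* **Preprocessing** — 0.1–30 Hz zero-phase band-pass, 50 Hz line removal,
  baseline correction, ±100 μV artifact rejection, spherical-spline
  bad-channel interpolation, average reference, and a surface-Laplacian
  (current source density) transform on a 20-channel 10-20 montage.
* **Connectivity** — 3-cycle Morlet decomposition (4–30 Hz), event-related
  desynchronization (ERD), and the **weighted phase-lag index**

      WPLI(i,j) = |Σ_k Im X_k| / Σ_k |Im X_k|,   X_k = c_i(k)·conj(c_j(k)),

  across trials at every time–frequency point, averaged over the alpha band
  (8–13 Hz) and the 500–1400 ms post-stimulus window.  WPLI is blind to
  zero-lag (volume-conduction) coupling.
* **NBS inference** — per-edge t tests thresholded at p < 0.005, connected
  components of the suprathreshold graph, and family-wise error control by
  permutation of the maximal component extent (10,000 permutations).
* **NBS-Predict** — connectome-based classification: repeated stratified
  5-fold CV with fold-internal suprathreshold-component edge selection
  (p < 0.01), linear classifiers (logistic, linear SVM, LDA), an
  edge-selection-frequency weighted network, and label-permutation
  significance.
* **Eye tracking** — fixation-report parsing, the 30%-missingness discard
  rule with mean/median imputation, the >100 ms fixation filter, total
  fixation time (TFT) and pupil-size features.
* **Statistics** — group t tests, Pearson correlations between
  connectivity, gaze and ADOS-2 clinical scores with Benjamini–Hochberg FDR,
  and ROC/Youden biomarker evaluation with bootstrap CIs.
* **Synthetic data** — a generator that plants phase-coupled alpha
  oscillations on a parieto-occipital edge set (group × condition coupling
  strengths), Table-scale fixation/pupil effects, and clinical scores
  correlated with the planted connectivity, so the entire pipeline is
  testable end to end without any recording hardware.

## Worked example

```python
from rrbscope import SimulationConfig, two_sample_t_summary
from rrbscope.simulate import simulate_eeg, planted_edge_wpli

# Group comparison from published summary statistics (mean ± SEM):
# total fixation time under HRIS, ASD (n=32) vs TD (n=27)
t, df, p = two_sample_t_summary(4853.30, 227.43, 32, 2628.98, 203.61, 27)
print(f"HRIS TFT contrast: t = {t:.2f}, df = {df:.1f}, p = {p:.2e}")

# Synthetic cohort: ASD couples more strongly under HRIS on the planted edges
cfg = SimulationConfig(n_asd=4, n_td=4, n_trials_per_condition=12, seed=7)
eeg = simulate_eeg(cfg)
for sid, w in planted_edge_wpli(eeg, cfg, condition="HRIS").items():
    print(f"{sid}: planted-edge alpha WPLI (HRIS) = {w:.3f}")
```

prints

```
HRIS TFT contrast: t = 7.29, df = 57.0, p = 1.06e-09
ASD001: planted-edge alpha WPLI (HRIS) = 0.776
ASD002: planted-edge alpha WPLI (HRIS) = 0.761
ASD003: planted-edge alpha WPLI (HRIS) = 0.869
ASD004: planted-edge alpha WPLI (HRIS) = 0.891
TD001: planted-edge alpha WPLI (HRIS) = 0.271
TD002: planted-edge alpha WPLI (HRIS) = 0.401
TD003: planted-edge alpha WPLI (HRIS) = 0.267
TD004: planted-edge alpha WPLI (HRIS) = 0.414
```

The t statistic is the Welch test computed from the printed group summaries;
the WPLI values show the planted group separation (ASD coupling κ = 0.80 vs
TD κ = 0.35 under HRIS) that the NBS and prediction stages then detect.

The full pipeline runs from the shell:

```bash
rrbscope run --out runs/demo --seed 7
```

which simulates the cohort, preprocesses, computes WPLI matrices, runs the
NBS contrasts and NBS-Predict classification, extracts eye-tracking
features, and writes `group_tests.csv`, `correlations.csv`, `roc.csv` and a
reproducibility manifest (config hash + per-file checksums) under
`runs/demo/`.  Individual stages are available as subcommands
(`simulate`, `preprocess`, `connectivity`, `nbs`, `nbs-predict`,
`et-features`, `stats`); settings come from a YAML config via `--config`.

## Layout

```
src/rrbscope/
  simulate.py     synthetic EEG / eye-tracking / clinical generators
  montage.py      10-20 unit-sphere montage
  epochs.py       epoched-EEG container (+ npz round trip)
  preprocess.py   filters, rejection, interpolation, average ref, CSD
  spectral.py     Morlet transform, ERD, WPLI
  nbs.py          edge t tests, components, NBS permutation inference
  predict.py      NBS-Predict cross-validated classification
  eyetracking.py  fixation parsing, QC/imputation, TFT & pupil features
  stats.py        t tests, Pearson+FDR, ROC/Youden, report bundle
  pipeline.py     stage orchestration, seeds, manifest
  cli.py          `rrbscope` command-line interface
docs/methods.md   model and design notes
tests/            unit, property and end-to-end validation suite
```
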