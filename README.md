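# batecg

Bat-algorithm feature selection and beat classification for single-lead
ECG, end-to-end testable on synthetic data with known ground truth.

The package implements:

- **`batecg.bat_core`** — a standard bat-algorithm optimizer (scalar
  loudness/pulse-rate per bat) and an improved variant that carries
  loudness and pulse rate *per search dimension*, gating the local
  random walk, loudness decay and pulse growth coordinate-wise. Both
  engines are seed-deterministic and emit a full per-iteration trace.
- **`batecg.feature_select`** — wrapper feature selection: continuous
  bat positions map to k-of-D feature subsets via top-k magnitude;
  fitness is cross-validated 1-NN error on the masked columns (a
  label-blind Rosenbrock mode is kept for comparison). Includes an
  exhaustive-enumeration oracle for small instances.
- **`batecg.ecg_preprocess`** — Savitzky–Golay denoising, R-peak
  detection (band-pass/differentiate/square/integrate with adaptive
  threshold and refractory period), beat segmentation taking 1/3 of the
  reference RR interval left of each R peak and 2/3 right, and linear
  resampling of every beat to 200 samples.
- **`batecg.synthetic_ecg`** — Gaussian-sum PQRST beat templates with a
  configurable ST-segment elevation and R-wave attenuation ("mi"
  preset), per-beat amplitude/alignment jitter, record synthesis with
  exact R ground truth, and labelled beat-matrix datasets that expose
  their discriminative sample window.
- **`batecg.classify_eval`** — 1-NN classification (Euclidean), SVM/MLP
  comparators behind the same harness, confusion counts and
  sensitivity/specificity/accuracy percentages. Note: the positive
  class defaults to `normal` (configurable), so sensitivity scores
  normal beats and specificity abnormal ones.
- **`batecg.cli_io`** — the `batecg` command-line front end and CSV/JSON
  readers and writers (atomic writes, config+seed embedded in every
  artifact). WFDB input is an optional extra (`pip install batecg[wfdb]`).

## CLI

```sh
# synthesize a labelled beat matrix (CSV + JSON sidecar)
batecg simulate-dataset --n-normal 200 --n-mi 200 --seed 1 --out beats.csv

# or go through the raw-signal pipeline
batecg simulate --class mi --beats 20 --fs 1000 --seed 1 --out rec.csv
batecg preprocess --in rec.csv --label mi --out beats_mi.csv

# select 20 of 200 samples with the improved optimizer
batecg select --beats beats.csv --k 20 --mode iba --fitness wrapper \
    --seed 1 --out mask.json

# train/test evaluation with the built-in 1-NN
batecg classify --beats beats.csv --mask mask.json --clf knn \
    --train-frac 0.64 --seed 1 --out report.json

# recompute metrics from a report's stored counts
batecg evaluate --report report.json

# optimizer benchmark trace
batecg optimize-benchmark --mode iba --dim 2 --pop 25 --iters 1000 \
    --seed 1 --out trace.json
```

All commands honour `--seed`; rerunning with the same seed reproduces
artifacts byte-for-byte.

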