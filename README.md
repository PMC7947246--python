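# otloc

Localize the origin of outflow-tract ventricular arrhythmia — right (RVOT)
vs left (LVOT) ventricular outflow tract — from a standard 12-lead ECG,
using exactly one sinus-rhythm (SR) beat and one premature ventricular
complex (PVC) per patient.

The pipeline mirrors a four-phase design:

1. **Preprocessing** — coif5 wavelet denoising with per-level SURE soft
   thresholds (power-line interference, white noise) and coarsest-band
   zeroing (baseline wander below 0.5 Hz); optional mains notch.
2. **Feature extraction** — two interchangeable extractors:
   * *automated*: every peak/valley of each beat window is measured by
     location, prominence, left/right prominence-base distances, width at
     half prominence, span, amplitude and contour height; the extremum
     nearest the lead-V6 reference plus 3 predecessors and 4 successors
     fill 8 slots per lead, giving a 192 × 8 matrix
     (2 beats × 12 leads × 8 slots) that is expanded into a named
     ratio/difference feature vector;
   * *conventional*: Q/R/S amplitudes and durations, precordial
     transition scores and the published localization indices
     (V2 transition ratio, V2S/V3R, TZ index, R-duration and R/S amplitude
     indices, R-deflection interval, Y-score), plus a ratio expansion.
3. **Training/validation** — histogram gradient-boosted trees (RVOT
   positive); features with non-zero mean absolute tree-path attribution
   are retained and the model refitted; the decision threshold maximizes
   Youden's J on the validation ROC.
4. **Testing** — ACC/SE/SP/F1/AUC with percentile-bootstrap CIs
   (20,000 replicates by default), DeLong AUC CIs and the paired DeLong
   test for comparing feature modes.

A fully parameterized synthetic generator (sum-of-Gaussians beats whose
precordial R/S balance encodes the latent origin class, plus the three
noise types) provides labeled cohorts for every test.

Records are read/written as plain CSV (one column per lead, mV) with a
JSON annotation sidecar, or as a minimal WFDB format-16 subset.

## CLI

```sh
otloc synth --n 450 --seed 1 --out data/            # synthetic cohort
otloc extract --input data/ --out features.csv      # feature table
otloc pipeline --synth-n 450 --seed 1 --out run/    # all four phases
otloc pipeline --input data/ --feature-mode conventional --seed 1
otloc criteria --synth-n 200 --seed 1               # published criteria
otloc train --features features.csv --out model.pkl
otloc evaluate --features features.csv --bundle model.pkl
```

Exit codes: 0 ok, 2 usage/config error, 3 data error.

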