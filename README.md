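# glyco

Reconciliation of free-living CGM/insulin-pump time series and
detection of unannounced meal and physical-activity events.

People with type 1 diabetes who use an insulin pump and a continuous
glucose monitor (CGM) produce long, messy records: 5-minute glucose
readings with dropouts, spikes and duplicates, sparse diary entries
(carbohydrates, boluses, activity), and events that were simply never
logged. Automated insulin delivery works markedly better when meals and
exercise are announced — and people often don't. `glyco` is a pipeline
that (1) cleans and completes such records and (2) learns to detect
unannounced meal/exercise events from the glucose–insulin dynamics
alone.

The stages, each usable as a library call or CLI subcommand:

| stage | method |
|---|---|
| `ingest` | parse raw exports, canonical units (mg/dL, Unix time), uniform 5-min grid with explicit missing markers |
| `reconcile` | physiological outlier rules (calibration range, unexplained ±30 mg/dL jumps, fingerstick disagreement > 18 mg/dL); Hankel/SVD (SSA) denoising at 95% singular-spectrum energy |
| `impute` | forward/daily-pattern fill for basal, median fill for sparse channels, probabilistic-PCA (EM with missing data) on 125-row lagged matrices for CGM gaps up to 2 h |
| `physio` | Hovorka glucose–insulin compartment model; body weight from modal daily insulin ÷ 0.5 U·kg⁻¹·day⁻¹; particle filter estimating plasma insulin concentration (PIC) and gut absorption rate U_G |
| `features` | derivatives (4th-order backward differences), trend products, windowed statistics, periodogram peaks, PIC/U_G — 31 causal features; deviance screen + SFFS/random-forest selection of the top 20 |
| `label` | four classes per sample from diary channels: (meal?, exercise?) via T(k) = ⌈activity_ms/3×10⁵⌉ |
| `detect` | LSTM, Conv1D-LSTM, ConvLSTM and Conv1D-BiLSTM sequence classifiers (NumPy, manual backprop, bitwise-deterministic) on 24-sample windows, class-weighted, stratified CV |
| `simulate` | synthetic free-living generator with known ground truth: behavioral scenario → Hovorka simulation → sensor/diary channels → realistic corruption with a defect ledger |

The core state-estimation idea: extend the Hovorka state
x = [S1, S2, I, x1, x2, x3, Q1, Q2, Gsub] with (t_maxI, k_e, U_G) as
bounded random walks and run a bootstrap particle filter against the
CGM signal. An unannounced meal then shows up as a rising U_G estimate
— a model-based feature the sequence classifiers consume alongside the
statistical ones.

## Worked example

Simulate two weeks of free-living data, clean it, and train a detector:

```python
import numpy as np
from glyco import synthdata, pipeline, features, label, detect, physio

corrupted, rendered, ledger = synthdata.generate_dataset(
    synthdata.Scenario(days=14), seed=1)

series, reports = pipeline.preprocess(corrupted, seed=2)
print(reports["outliers"]["rejected"])
# {'calibration': 1, 'rise': 15, 'drop': 20, 'smbg': 4}

table, pf, params = pipeline.extract_features(
    series, pf_cfg=physio.PFConfig(n_particles=300, seed=3))
labels = label.label_events(series)
print(labels.counts())
# {'C00': 3937, 'C01': 44, 'C10': 40, 'C11': 11}

kept = features.deviance_filter(table, labels.classes)
names, _ = features.sffs_select(table.select(kept), labels.classes,
                                k_out=20, seed=4, folds=2, max_rows=1200)
batch = pipeline.build_training_batch(table, names, labels)
cfg = detect.DetectorConfig(lstm_units=24, dense_units=16,
                            conv_filters=(16, 24), epochs=30,
                            patience=6, folds=2, seeds=1)
dets, report = detect.train_detector(batch, "conv1d_bilstm", cfg, seed=5)
print(round(report["test"]["accuracy"], 3),
      round(report["test"]["weighted_f1"], 3))
# 0.967 0.951
```

The rejection counts show the rule-based cleaner catching the injected
spikes and range violations; the label counts reflect the strong class
imbalance of free-living data (meals and exercise are rare at 5-minute
resolution, which is why training uses inverse-class-size weights); the
final two numbers are held-out accuracy and support-weighted F1 of the
Conv1D-BiLSTM detector on the chronologically last 12.5% of windows.

The same flow from a shell:

```sh
glyco simulate runs/sim --days 14 --seed 11
glyco run config.yaml --out runs/full
```

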