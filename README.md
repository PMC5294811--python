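# armpulse

Cuff-less systolic blood pressure (SBP) and heart-rate (HR) estimation from
a single-arm ECG + PPG sensor band.

Wearable blood-pressure monitors exploit the fact that the pulse transit
time (PTT) — the delay between the heart's electrical beat (the ECG R peak)
and the pressure pulse's arrival at a distal site (the PPG waveform foot) —
shortens as arterial pressure rises. Putting *both* sensors on one upper
arm maximizes wearability but leaves an ECG about ten times weaker than a
chest lead and riddled with EMG noise and motion artifacts, so naive R-peak
detection fails. This package implements the full estimation chain for that
setting, for researchers working on wearable cardiovascular monitoring:

* **Preprocessing** — zero-phase Butterworth band-pass (ECG 2–30 Hz,
  PPG 0.5–8 Hz) and polyphase resampling of the PPG to the ECG's 500 Hz
  grid (`armpulse.preprocess`).
* **Beat identification** — candidates from local maxima above an adaptive
  threshold `θ + κ·P2P₂₀ₛ(t)` that tracks the signal fluctuation, ten
  morphology features per candidate, and a linear soft-margin SVM (C = 1)
  whose dual

  max<sub>α</sub> Σαᵢ − ½ ΣΣ αᵢαⱼyᵢyⱼ⟨xᵢ,xⱼ⟩  s.t. Σαᵢyᵢ = 0, 0 ≤ αᵢ ≤ C

  is solved by an in-package SMO solver with second-order working-set
  selection (`armpulse.beat_detection`).
* **Pulse timing** — PPG foot = minimum between adjacent R peaks,
  PTTᵢ = footᵢ − Rᵢ, instantaneous HR = 60/RR, and per-trial window means
  (`armpulse.pulse_timing`).
* **Calibration** — ten per-subject SBP models (seven PTT-only: log,
  inverse, linear, quadratic, exponential, inverse-square forms; three
  PTT&HR), e.g. model 10: SBP = a·PTT + b·HR + c (`armpulse.sbp_models`).
* **Evaluation** — ME ± SD, MAE, RMSE, Bland–Altman limits of agreement,
  AAMI device criterion, correlation matrices (`armpulse.evaluation`).
* **Synthetic sessions** — a seeded generator of coupled chest-ECG /
  arm-ECG / arm-PPG recordings with full ground truth (beats, PTT, HR,
  SBP), emulating the 13-trial exercise/rest protocol
  (`armpulse.synthetic_data`), since no recording of this device class is
  publicly deposited.

A thin `armpulse` CLI wraps the library (`simulate`, `filter`,
`train-detector`, `detect-beats`, `compute-ptt`, `windows`, `fit-sbp`,
`predict-sbp`, `evaluate`, `run-study`); `examples/` holds one short
narrative script per capability. The model and generator details are in
[docs/methods.md](docs/methods.md).

## Worked example

```python
from armpulse import SyntheticConfig, generate_session, run_study

train = generate_session(SyntheticConfig(seed=41))   # 26-min session
test  = generate_session(SyntheticConfig(seed=42))   # unseen session
report = run_study(train, test)
print(report.test_table.round(2).loc[[1, 10]])
hr = report.hr_stats
print(f"windowed HR: MAE {hr.mae:.2f} BPM, RMSE {hr.rmse:.2f} BPM")
print("AAMI pass:", report.aami[10])
```

prints

```
            ME   STD   MAE  RMSE
model_id
1        -0.23  4.83  4.13  4.65
10        0.48  2.18  1.87  2.15
windowed HR: MAE 0.45 BPM, RMSE 0.52 BPM
AAMI pass: True
```

Every number on the `test` rows comes from models frozen before the test
session was touched. Model 1 (SBP from PTT alone) is roughly twice as far
from the cuff reference as model 10 (PTT and HR): heart rate carries
pressure information that transit time misses, which is the core
comparative finding this pipeline reproduces. The windowed HR errors are
the agreement between the weak-arm-ECG estimate and the chest-lead
reference; the AAMI verdict checks |ME| ≤ 5 mmHg and SD ≤ 8 mmHg. Or, from
a shell:

```sh
armpulse simulate --seed 41 --out train/
armpulse simulate --seed 42 --out test/
armpulse run-study --train train/ --test test/ --out report/
```

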