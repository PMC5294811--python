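# Methods

`armpulse` implements the estimation chain of a cuff-less single-arm
blood-pressure and heart-rate monitor: both the ECG electrodes and the
reflective PPG sensor sit on one upper arm, which makes the device highly
wearable but leaves an ECG roughly ten times weaker than a chest lead and
heavily contaminated by EMG noise and motion artifacts. The pipeline turns
the two raw waveforms into beat-by-beat pulse transit times (PTT), windowed
heart rate (HR), and calibrated systolic blood pressure (SBP) estimates.

## Signal model and preprocessing

Channels are uniformly sampled (`SignalChannel`): ECG at 500 Hz, PPG at
128 Hz, shared time origin, sample *k* at *k/f*<sub>s</sub> seconds. A
session is 13 two-minute trials; in the middle trials the subject exercises
during minute one and rests during minute two, which is the analysis window
where the cuff reference SBP is taken. All intervals are half-open
`[start, end)` so windowed averages never double-count a boundary event.

The ECG is band-passed at 2–30 Hz and the PPG at 0.5–8 Hz with 4th-order
Butterworth filters applied forward–backward. Zero-phase filtering is a
deliberate choice: PTT subtracts time stamps *across* the two channels, and
causal filters would add modality-dependent group delay that biases PTT by
tens of milliseconds. The PPG is then resampled to 500 Hz by polyphase
band-limited interpolation so both channels share one 2 ms time grid.

## Heartbeat identification in the weak arm ECG

A four-stage framework:

1. **Candidate generation.** Local maxima above an adaptive threshold
   `thr(t) = θ + κ · P2P₂₀ₛ(t)`, where `P2P₂₀ₛ` is the peak-to-peak range of
   the surrounding 20 s window. When motion inflates the signal range the
   threshold rises with it, so true beats stay above threshold in both quiet
   and corrupted stretches (sensitivity first; precision is the classifier's
   job). Within any 200 ms refractory span only the largest maximum
   survives. Defaults: `θ` = 0.3× the median beat apex amplitude of the
   training record, `κ` = 0.15. The structure (fixed plus fluctuation-tracking
   term) is the method's; the two constants are this package's choices, fixed
   once. Candidate output is invariant to rescaling the signal and `θ`
   by a common positive factor.
2. **Feature extraction.** Ten morphology features per candidate. The field
   names them (R/S angles, R−S voltage difference, R/S symmetry, skewness,
   variance, RMS of the R region, and two local slope angles) without fixing
   formulas, so the definitions here are explicit package choices: the R
   region is ±60 ms around the apex; the S valley is the minimum within
   100 ms after the apex; angle features normalize voltage by the region
   peak-to-peak and time by the region half-width and take the apex angle of
   the triangle formed with the points 20 ms to each side; symmetry is the
   Pearson correlation of the left half-region with the time-reversed right
   half; skewness is the bias-corrected sample skewness (0 for flat
   regions); variance uses the n−1 denominator; the slope angles are
   arctangents of the normalized first differences at samples (r−3, r−2) and
   (r+1, r+2). Degenerate flat regions get the conventions angle = π,
   symmetry = 1, skewness = 0.
3. **Classification.** A linear soft-margin SVM, C = 1, on z-scored features
   (scaler frozen from the training set and stored in the model). The dual
   problem — maximize Σαᵢ − ½ΣΣαᵢαⱼyᵢyⱼ⟨xᵢ,xⱼ⟩ subject to Σαᵢyᵢ = 0 and
   0 ≤ αᵢ ≤ C — is solved by sequential minimal optimization with
   second-order working-set selection: the first index maximizes the KKT
   violation, the second maximizes the guaranteed dual decrease along the
   pair direction. The gradient is maintained incrementally (two kernel-row
   products per iteration); termination at a maximal violating pair gap
   below 1e−6, which leaves a primal–dual gap around 1e−6 even on
   ~2 300-point training sets. The bias is the mean of `yᵢ − w·xᵢ` over
   unbounded (0 < α < C) support vectors. A decision value of exactly zero
   maps to "beat": downstream PTT averaging prefers recall. The solver is
   validated in the tests against a brute-force QP oracle (SLSQP on the same
   dual) and, during development, against an independent linear-SVM
   implementation, with which it agrees to ~1e−3 in the weight vector.
4. **Confident-beat output.** Candidates classified +1, in time order. If a
   training session is so clean that every candidate is a true beat (single
   class), there is nothing to learn and the detector passes candidates
   through unchanged.

Training labels pair candidates with reference beats (from the chest lead
or the generator truth) by greedy nearest-first one-to-one matching within
±75 ms.

## Pulse timing

The PPG-based heartbeat location is the *global minimum of the PPG strictly
between two adjacent R peaks* — exactly the stated rule, with ties broken
earliest; no tangent-intersection refinement is applied. Per beat,
`PTT = foot − R`; pairs whose foot does not fall strictly inside its R–R
interval are dropped and logged, so `0 < PTT < RR` holds for every emitted
pair, and PTT is invariant to a common time shift of both channels.
Instantaneous HR is 60/RR stamped at the later beat; R–R intervals outside
0.25–2.0 s (a physiologic gate guarding the means against residual false or
missed beats) are dropped. Per-trial means over the analysis window of PTT
(stamped at the R time) and IHR, joined with the cuff reference, form the
calibration windows.

## SBP calibration models

Ten per-subject models, PTT in seconds, HR in BPM, SBP in mmHg:

| id | equation | id | equation |
|----|-------------------------|----|------------------------------------|
| 1 | a ln(PTT) + b | 6 | a e^(b·PTT) |
| 2 | a PTT⁻¹ + b | 7 | a PTT⁻² + b |
| 3 | a PTT + b | 8 | a PTT⁻² + b HR⁻² + c |
| 4 | a PTT² + b PTT + c | 9 | a ln(PTT) + b ln(HR) + c |
| 5 | a PTT² + b | 10 | a PTT + b HR + c |

All coefficients are trainable (none pinned to empirical constants) and
fitted per subject. Models linear in coefficients are ordinary least
squares on the model's regressors plus an intercept; model 6 is nonlinear
least squares on the SBP scale — not the log scale, so its residuals are
commensurable with the other nine — initialized from the log-linear fit.
An exact-arity fit (n = number of coefficients) is allowed, which the
hand-solvable three-window fixtures in the tests rely on; rank-deficient
designs are rejected.

## Evaluation

Agreement of estimates against references is summarized by mean error (ME),
the sample (n−1) standard deviation of differences, MAE, and RMSE (n
denominator) — with this pairing `rmse² = me² + std²·(n−1)/n` is an exact
identity and is asserted for every computed statistic. Bland–Altman limits
of agreement are ME ± 1.96·SD. The AAMI device criterion (|ME| ≤ 5 mmHg and
SD ≤ 8 mmHg) is boundary-inclusive. Pearson correlation matrices over
aligned beat series (aligned by the same greedy matcher) are returned
exactly symmetric with unit diagonal. `relative_increase` computes the
percent change of one metric over a baseline at one decimal place, the
arithmetic used to compare the PTT-only and PTT&HR model columns of the
published benchmark table that ships in `armpulse.evaluation`.

The `run_study` orchestration enforces the train/test discipline: detector
threshold, SVM, feature scaler and all model coefficients are fitted on the
training session only and frozen before any test-session data is touched.

## Synthetic sessions

No recording for this device class is publicly deposited, so the package
ships a seeded generator (`synthetic_data`) that every pipeline stage is
tested against.

* **Trajectories.** Per-trial HR and SBP targets rise with an exercise
  level (rest trial, ten exercise trials ramping to the peak, two recovery
  trials) plus independent per-trial jitter (SD 3 BPM / 3 mmHg) so that HR
  and SBP are correlated but not collinear — without that jitter the
  three-coefficient models would be unidentifiable from 13 windows. Within
  a trial, minute one ramps smoothly (cosine) to the target and minute two
  holds it, mirroring exercise-then-rest. Defaults: HR 72→105 BPM,
  SBP 112→140 mmHg.
* **Beats and coupling.** Beat times integrate the HR profile with optional
  RR jitter (SD 15 ms). Each beat's true PTT inverts the generative SBP
  model — default model 10 with (a, b, c) = (−200, 0.5, 120), a < 0 so SBP
  falls as PTT rises, PTT ≈ 160–230 ms — at that beat's SBP and its own
  instantaneous HR (60/RR). Because generation couples SBP, HR and PTT
  beat-by-beat through a linear model, window means satisfy the same model
  exactly, which is what makes end-to-end coefficient recovery a sharp
  test. Window references are the true window-mean SBP plus cuff noise
  (SD 1 mmHg; zero in the clean preset).
* **Waveforms.** Chest ECG: difference-of-Gaussians QRS (R σ = 9 ms,
  amplitude 1; S deflection −0.3 at +45 ms). Arm ECG: the same waveform
  ×0.10 plus baseline wander (0.05 @ 0.3 Hz), white EMG-band noise
  (SD 0.012), powerline interference (0.02 @ 50 Hz) and Poisson motion
  artifacts (8/min at rest, doubled during exercise minutes; Gaussian
  transients, σ 5–18 ms, amplitude 0.06–0.20, ≤ 80 ms support). The PPG is
  a cosine-harmonic pulse (weights 1, 0.4, 0.15 on harmonics 1–3 of the
  beat interval) whose minima fall exactly at the feet and are locally
  symmetric. This pulse shape was chosen for timing fidelity: a shallow
  decay into the foot followed by a steep upstroke — however realistic —
  lets the 8 Hz zero-phase low-pass drag the between-beat minimum ~20 ms
  early, while a symmetric valley survives filtering unmoved, keeping foot
  recovery within one 2 ms sample. Beats start after a 2 s burn-in so
  filter edge transients never touch usable data.
* **Determinism.** One `numpy` Generator seeded from the config; identical
  config + seed gives bit-identical waveforms and ground truth.

What the generator does *not* emulate: P/T waves and morphology variation
in the ECG, dicrotic PPG structure, pre-ejection-period variability
(ECG-to-PPG transit includes PEP in reality, so real PTT–SBP coupling is
noisier than the algebraic one here), non-stationary artifact statistics,
sensor drift, and between-day recalibration drift. Passing tests therefore
demonstrate correctness of the algorithms under the stated signal model,
not clinical accuracy on real arm recordings.

## Numerical choices and problem sizes

* SMO tolerance 1e−6 on the violating-pair gap; iteration cap
  max(100 000, 50 n) with a warning on hitting it; support vectors are
  α > 1e−10.
* Model-6 fit: `curve_fit` (Levenberg–Marquardt) from the log-linear start.
* Model inversion for generation: closed forms for nine models; bisection
  on the monotone physiologic branch (0.05–0.5 s) for the quadratic
  model 4; every inverse is verified to round-trip through the forward
  model to 1e−9.
* Resampling 128→500 Hz uses the exact rational factor 125/32.
* Signal CSVs are written with `%.17g`, and annotation/reference CSVs are
  read with round-trip float parsing, so file round trips are bit-exact.
* Default problem sizes in tests and the acceptance script: full 13-trial
  (26 min) sessions for end-to-end studies (~2 300 beats, ~2 300 SVM
  training points), four-trial sessions for unit tests, and ≤ 20-point
  problems for the brute-force QP oracle comparisons.

## Known limitations

* The ten-feature set is implemented as defined above; the upstream sparse
  feature selection that produced it from 26 raw features is out of scope.
* PPG-only heart rate and SBP (without ECG) are not provided.
* The artifact classifier is feature-limited on artifact-only streams: with
  the default generator spike distribution it retains ~7–10 % of spikes
  (an independent linear-SVM implementation accepts the identical set), so
  sparse residual false beats are expected and are further suppressed by
  the R–R gate.
* Per-subject calibration only; no pooling, posture covariates, diastolic
  pressure, or multi-day recalibration.
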