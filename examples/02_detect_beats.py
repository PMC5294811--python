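"""Train the SVM beat detector on one session and test it on another.

The weak arm ECG is band-passed at 2-30 Hz; candidates are local maxima
above an adaptive threshold (fixed part + 0.15x the 20 s peak-to-peak
fluctuation); ten morphology features feed a linear soft-margin SVM
(C = 1) that separates true heartbeats from artifact spikes.
"""

import armpulse.beat_detection as bd
from armpulse import SyntheticConfig, generate_session
from armpulse.study import prepare_session

train = generate_session(SyntheticConfig(seed=1))
test = generate_session(SyntheticConfig(seed=2))

prep_tr = prepare_session(train)
theta = bd.base_threshold_from_beats(prep_tr.arm_ecg_f, train.beats.times_s)
cfg = bd.CandidateGenConfig(base_threshold=theta)

cand = bd.generate_candidates(prep_tr.arm_ecg_f, cfg)
times, X = bd.extract_feature_matrix(prep_tr.arm_ecg_f, cand)
y = bd.label_candidates(times, train.beats)
model = bd.train_svm(X, y)
print(f"training: {times.size} candidates, {(y == 1).sum()} beats, "
      f"{model.alphas.size} support vectors")

prep_te = prepare_session(test)
det = bd.detect_beats(prep_te.arm_ecg_f, model, cfg)
truth = test.truth.beat_times_s
matches = bd.greedy_match(det.times_s, truth, 0.075)
print(f"test session: {len(det)} beats detected of {truth.size} true")
print(f"sensitivity {len(matches)/truth.size:.3f}, precision {len(matches)/len(det):.3f}")
print("(candidates catch every beat; the SVM removes the artifact spikes)")
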