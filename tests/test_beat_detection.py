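"""Candidate generation, morphology features and the SVM classifier."""

import numpy as np
import pytest

import armpulse.beat_detection as bd
from armpulse.preprocess import ECG_FILTER, bandpass
from armpulse.signal_io import BeatAnnotation, SignalChannel
from armpulse.study import prepare_session
from armpulse.synthetic_data import inject_artifacts
from qp_oracle import dual_optimum, max_kkt_violation, random_problem


class TestGenerateCandidates:
    def test_all_zero_signal_yields_nothing(self):
        ch = SignalChannel(np.zeros(30000), 500.0)
        cfg = bd.CandidateGenConfig(base_threshold=0.05)
        assert bd.generate_candidates(ch, cfg).size == 0

    def test_window_longer_than_recording(self):
        ch = SignalChannel(np.zeros(1000), 500.0)
        with pytest.raises(ValueError):
            bd.generate_candidates(ch, bd.CandidateGenConfig(base_threshold=0.05, window_s=20.0))

    def test_clean_session_sensitivity_is_one(self, small_clean_session):
        prep = prepare_session(small_clean_session)
        theta = bd.base_threshold_from_beats(prep.arm_ecg_f, prep.ref_beats.times_s)
        cand = bd.generate_candidates(prep.arm_ecg_f, bd.CandidateGenConfig(base_threshold=theta))
        truth = small_clean_session.truth.beat_times_s
        matches = bd.greedy_match(cand, truth, 0.010)
        assert len(matches) == len(truth)

    def test_injected_spikes_keep_sensitivity_but_lower_precision(self, small_clean_session):
        # beat-scale spikes placed mid-diastole (outside every refractory
        # span) must all become candidates without displacing any true beat
        prep = prepare_session(small_clean_session)
        truth = small_clean_session.truth.beat_times_s
        fs = prep.arm_ecg_f.sampling_rate_hz
        x = prep.arm_ecg_f.samples.copy()
        mids = (truth[:-1] + truth[1:]) / 2.0
        spike_times = mids[::15][:20]
        tt = np.arange(-25, 26) / fs
        bump = 0.12 * np.exp(-(tt**2) / (2 * 0.008**2))
        for t in spike_times:
            k = int(round(t * fs))
            x[k - 25 : k + 26] += bump
        spiky = prep.arm_ecg_f.with_samples(x)
        theta = bd.base_threshold_from_beats(spiky, prep.ref_beats.times_s)
        cand = bd.generate_candidates(spiky, bd.CandidateGenConfig(base_threshold=theta))
        matches = bd.greedy_match(cand, truth, 0.010)
        assert len(matches) == len(truth)  # every true beat still found
        assert cand.size >= truth.size + len(spike_times)  # plus the spikes

    def test_rescaling_invariance(self, small_clean_session):
        prep = prepare_session(small_clean_session)
        theta = bd.base_threshold_from_beats(prep.arm_ecg_f, prep.ref_beats.times_s)
        base = bd.generate_candidates(prep.arm_ecg_f, bd.CandidateGenConfig(base_threshold=theta))
        scaled_ch = prep.arm_ecg_f.with_samples(prep.arm_ecg_f.samples * 7.5)
        scaled = bd.generate_candidates(
            scaled_ch, bd.CandidateGenConfig(base_threshold=theta * 7.5)
        )
        np.testing.assert_array_equal(base, scaled)


class TestExtractFeatures:
    def test_constant_region_degenerate_statistics(self):
        ch = SignalChannel(np.full(2000, 3.0), 500.0)
        f = bd.extract_features(ch, 2.0)
        named = dict(zip(bd.FEATURE_NAMES, f))
        assert named["var"] == 0.0
        assert named["rms"] == pytest.approx(3.0)
        assert named["skns"] == 0.0
        assert named["r_symmetry"] == 1.0
        assert named["alpha3"] == 0.0 and named["alpha2"] == 0.0

    def test_symmetric_triangle_has_max_symmetry(self):
        fs = 500.0
        n = 2000
        x = np.zeros(n)
        apex = 1000
        width = 30
        x[apex - width : apex + width + 1] = 1.0 - np.abs(np.arange(-width, width + 1)) / width
        f = bd.extract_features(SignalChannel(x, fs), apex / fs)
        named = dict(zip(bd.FEATURE_NAMES, f))
        assert named["r_symmetry"] == pytest.approx(1.0)

    def test_edge_candidate_raises(self):
        ch = SignalChannel(np.zeros(200), 500.0)
        with pytest.raises(bd.EdgeError):
            bd.extract_features(ch, 0.01)

    def test_features_are_finite_on_synthetic_beats(self, small_noisy_session):
        prep = prepare_session(small_noisy_session)
        times, X = bd.extract_feature_matrix(
            prep.arm_ecg_f, small_noisy_session.truth.beat_times_s[5:25]
        )
        assert X.shape == (20, 10)
        assert np.all(np.isfinite(X))


class TestLabelCandidates:
    REF = BeatAnnotation(times_s=np.array([10.02, 10.20, 11.0]))

    def test_within_tolerance_is_beat(self):
        labels = bd.label_candidates(np.array([10.00]), self.REF, 0.075)
        assert labels[0] == 1

    def test_one_to_one_matching_keeps_nearer(self):
        labels = bd.label_candidates(np.array([10.00, 10.03]), self.REF, 0.075)
        assert labels.tolist() == [-1, 1]

    def test_outside_tolerance_is_artifact(self):
        labels = bd.label_candidates(np.array([10.50]), self.REF, 0.075)
        assert labels[0] == -1


class TestSvm:
    def test_two_point_problem_matches_hand_solution(self):
        # alpha = (0.5, 0.5), w = 1, b = 0 (the scaler is the identity here)
        model = bd.train_svm(np.array([[-1.0], [1.0]]), np.array([-1.0, 1.0]), C=1.0)
        np.testing.assert_allclose(np.sort(model.alphas), [0.5, 0.5], atol=1e-9)
        np.testing.assert_allclose(model.weight_vector, [1.0], atol=1e-9)
        assert model.bias == pytest.approx(0.0, abs=1e-9)
        assert bd.classify(model, np.array([[0.5]])) == 1
        assert bd.classify(model, np.array([[-2.0]])) == -1

    def test_two_point_dual_matches_grid_oracle(self):
        # brute force over the feasible line alpha_1 = alpha_2 = a, a in [0, 1]
        model = bd.train_svm(np.array([[-1.0], [1.0]]), np.array([-1.0, 1.0]), C=1.0)
        a = np.linspace(0, 1, 100001)
        dual = 2 * a - 0.5 * (2 * a) ** 2 * 1.0  # K(x, x) = 1, y_i y_j K = -..., reduces to 2a - 2a^2
        assert model.dual_objective() == pytest.approx(np.max(dual), abs=1e-8)

    def test_separable_data_fits_exactly(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, size=(20, 2)), rng.normal(3, 0.3, size=(20, 2))])
        y = np.concatenate([-np.ones(20), np.ones(20)])
        model = bd.train_svm(X, y)
        assert np.all(np.atleast_1d(bd.classify(model, X)) == y)

    def test_duality_gap_small(self, rng):
        X, y = random_problem(rng)
        model = bd.train_svm(X, y)
        gap = model.primal_objective(X, y) - model.dual_objective()
        assert 0 <= gap <= 1e-4

    def test_kkt_conditions_hold(self, rng):
        for _ in range(5):
            X, y = random_problem(rng)
            model = bd.train_svm(X, y)
            assert max_kkt_violation(model, X, y) <= 1e-3

    def test_dual_matches_slsqp_oracle(self, rng):
        X, y = random_problem(rng)
        model = bd.train_svm(X, y)
        Xs = (X - model.scaler_mean) / model.scaler_scale
        assert model.dual_objective() == pytest.approx(dual_optimum(Xs, y), abs=1e-4)

    def test_alpha_box_and_equality_constraints(self, rng):
        X, y = random_problem(rng)
        model = bd.train_svm(X, y, C=1.0)
        assert np.all(model.alphas >= 0) and np.all(model.alphas <= 1.0 + 1e-9)
        assert abs(np.sum(model.alphas * model.sv_labels)) <= 1e-6

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            bd.train_svm(np.array([[0.0], [1.0]]), np.array([1.0, 1.0]))

    def test_dimension_mismatch_rejected(self):
        model = bd.train_svm(np.array([[-1.0], [1.0]]), np.array([-1.0, 1.0]))
        with pytest.raises(ValueError):
            bd.classify(model, np.array([[1.0, 2.0]]))

    def test_model_json_round_trip(self, tmp_path, rng):
        X, y = random_problem(rng)
        model = bd.train_svm(X, y)
        model.to_json(tmp_path / "m.json")
        back = bd.SvmModel.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(back.decision_function(X), model.decision_function(X))


class TestDetectBeats:
    def test_cross_session_detection_quality(
        self, trained_detector, small_noisy_session_b
    ):
        cfg, model = trained_detector
        prep = prepare_session(small_noisy_session_b)
        det = bd.detect_beats(prep.arm_ecg_f, model, cfg)
        truth = small_noisy_session_b.truth.beat_times_s
        matches = bd.greedy_match(det.times_s, truth, 0.075)
        sens = len(matches) / len(truth)
        prec = len(matches) / len(det)
        assert sens >= 0.95 and prec >= 0.97

    def test_clean_session_detection_is_near_perfect(
        self, trained_detector, small_clean_session
    ):
        cfg, model = trained_detector
        prep = prepare_session(small_clean_session)
        det = bd.detect_beats(prep.arm_ecg_f, model, cfg)
        truth = small_clean_session.truth.beat_times_s
        matches = bd.greedy_match(det.times_s, truth, 0.075)
        assert len(matches) / len(truth) >= 0.99
        assert len(matches) / len(det) >= 0.99

    def test_artifact_only_input_mostly_rejected(self, trained_detector, rng):
        cfg, model = trained_detector
        noise = SignalChannel(rng.normal(0, 0.012, int(300 * 500)), 500.0)
        spiky, spike_times = inject_artifacts(noise, rate_per_min=30.0, seed=11)
        det = bd.detect_beats(bandpass(spiky, ECG_FILTER), model, cfg)
        assert len(det) / len(spike_times) <= 0.10

    def test_empty_candidates_give_empty_annotation(self, trained_detector):
        cfg, model = trained_detector
        flat = SignalChannel(np.zeros(int(30 * 500)), 500.0)
        det = bd.detect_beats(flat, model, cfg)
        assert len(det) == 0

    def test_output_strictly_increasing(self, trained_detector, small_noisy_session):
        cfg, model = trained_detector
        prep = prepare_session(small_noisy_session)
        det = bd.detect_beats(prep.arm_ecg_f, model, cfg)
        assert np.all(np.diff(det.times_s) > 0)
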