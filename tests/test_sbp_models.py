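"""Design terms, calibration fits and prediction of the ten SBP models."""

import numpy as np
import pytest

from armpulse.sbp_models import (
    HR_MODEL_IDS,
    MODEL_IDS,
    CalibrationSet,
    SbpModelSpec,
    design_terms,
    fit_and_test_all,
    fit_model,
    predict,
)

# physiologically plausible true coefficients used for recovery checks
TRUE_COEFS = {
    1: (-40.0, 60.0),
    2: (25.0, 10.0),
    3: (-200.0, 160.0),
    4: (300.0, -350.0, 190.0),
    5: (-400.0, 140.0),
    6: (180.0, -2.0),
    7: (4.0, 20.0),
    8: (3.0, 40000.0, 40.0),
    9: (-40.0, 10.0, 50.0),
    10: (-200.0, 0.5, 120.0),
}


def _grid_set(model_id, coefs, n=12, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    ptt = np.linspace(0.15, 0.35, n)
    hr = 70.0 + 40.0 * rng.uniform(size=n)
    spec = SbpModelSpec(model_id=model_id, coefficients=coefs)
    sbp = predict(spec, ptt, hr if spec.uses_hr else None)
    sbp = sbp + rng.normal(0.0, noise_sd, n)
    return CalibrationSet(ptt_s=ptt, hr_bpm=hr, sbp_mmhg=sbp)


class TestDesignTerms:
    def test_identity_regressor(self):
        np.testing.assert_allclose(design_terms(3, 0.25), [0.25])

    def test_reciprocal_regressor(self):
        np.testing.assert_allclose(design_terms(2, 0.25), [4.0])

    def test_ptt_hr_inverse_square(self):
        np.testing.assert_allclose(design_terms(8, 0.5, 60.0), [4.0, 1.0 / 3600.0])

    def test_nonpositive_ptt_rejected(self):
        with pytest.raises(ValueError):
            design_terms(1, -0.1)

    def test_missing_hr_rejected(self):
        with pytest.raises(ValueError):
            design_terms(10, 0.25)


class TestFitModel:
    def test_linear_model_on_collinear_triples(self):
        # hand solution: slope (110-120)/(0.25-0.20) = -200, intercept 160
        data = CalibrationSet(
            ptt_s=[0.20, 0.25, 0.30], hr_bpm=[70.0] * 3, sbp_mmhg=[120.0, 110.0, 100.0]
        )
        spec = fit_model(3, data)
        np.testing.assert_allclose(spec.coefficients, (-200.0, 160.0), atol=1e-9)
        assert spec.rss == pytest.approx(0.0, abs=1e-18)
        assert predict(spec, 0.22) == pytest.approx(116.0, abs=1e-9)

    def test_planar_model_on_exact_triples(self):
        # hand-solved 3x3 system: a = -100, b = 0.5, c = 100
        data = CalibrationSet(
            ptt_s=[0.20, 0.25, 0.30],
            hr_bpm=[80.0, 100.0, 60.0],
            sbp_mmhg=[120.0, 125.0, 100.0],
        )
        spec = fit_model(10, data)
        np.testing.assert_allclose(spec.coefficients, (-100.0, 0.5, 100.0), atol=1e-8)
        assert predict(spec, 0.25, 80.0) == pytest.approx(115.0, abs=1e-8)

    def test_exponential_recovery_from_noiseless_data(self):
        data = _grid_set(6, (180.0, -2.0), n=10)
        spec = fit_model(6, data)
        np.testing.assert_allclose(spec.coefficients, (180.0, -2.0), rtol=1e-6)

    @pytest.mark.parametrize("model_id", MODEL_IDS)
    def test_noiseless_parameter_recovery(self, model_id):
        data = _grid_set(model_id, TRUE_COEFS[model_id], n=13)
        spec = fit_model(model_id, data)
        np.testing.assert_allclose(spec.coefficients, TRUE_COEFS[model_id], rtol=1e-6)

    @pytest.mark.parametrize("model_id", [mid for mid in MODEL_IDS if mid != 6])
    def test_ols_matches_normal_equations_oracle(self, model_id, rng):
        data = _grid_set(model_id, TRUE_COEFS[model_id], n=20, noise_sd=2.0, seed=3)
        spec = fit_model(model_id, data)
        A = design_terms(model_id, data.ptt_s, data.hr_bpm)
        A = np.column_stack([A, np.ones(data.n)])
        oracle = np.linalg.solve(A.T @ A, A.T @ data.sbp_mmhg)
        np.testing.assert_allclose(spec.coefficients, oracle, atol=1e-8)

    @pytest.mark.parametrize("model_id", MODEL_IDS)
    def test_coefficient_error_shrinks_with_n(self, model_id):
        # averaged over replicates: a single draw need not be monotone
        true = np.asarray(TRUE_COEFS[model_id])
        errs = []
        for n in (13, 130):
            per_seed = []
            for seed in range(10):
                data = _grid_set(model_id, TRUE_COEFS[model_id], n=n, noise_sd=1.0, seed=seed)
                spec = fit_model(model_id, data)
                per_seed.append(
                    np.linalg.norm((np.asarray(spec.coefficients) - true) / true)
                )
            errs.append(np.mean(per_seed))
        assert errs[1] < errs[0]

    def test_fitted_slope_sign_follows_monotone_trend(self):
        data = _grid_set(3, TRUE_COEFS[3], n=13, noise_sd=1.0, seed=4)
        spec = fit_model(3, data)
        assert spec.coefficients[0] < 0  # SBP falls as PTT rises

    def test_too_few_windows_rejected(self):
        data = CalibrationSet(ptt_s=[0.2, 0.25], hr_bpm=[70.0, 80.0], sbp_mmhg=[120.0, 110.0])
        with pytest.raises(ValueError):
            fit_model(4, data)

    def test_rank_deficient_design_rejected(self):
        data = CalibrationSet(
            ptt_s=[0.25] * 4, hr_bpm=[80.0] * 4, sbp_mmhg=[120.0, 118.0, 122.0, 121.0]
        )
        with pytest.raises(ValueError, match="rank"):
            fit_model(3, data)


class TestPredict:
    def test_training_points_of_exact_fit_reproduced(self):
        data = _grid_set(9, TRUE_COEFS[9], n=8)
        spec = fit_model(9, data)
        np.testing.assert_allclose(
            predict(spec, data.ptt_s, data.hr_bpm), data.sbp_mmhg, atol=1e-8
        )

    def test_missing_hr_for_hr_model(self):
        spec = SbpModelSpec(model_id=10, coefficients=(-100.0, 0.5, 100.0))
        with pytest.raises(ValueError):
            predict(spec, 0.25)

    def test_spec_coefficient_count_validated(self):
        with pytest.raises(ValueError):
            SbpModelSpec(model_id=10, coefficients=(1.0, 2.0))


class TestFitAndTestAll:
    def test_noiseless_generative_model_has_zero_rmse(self):
        data = _grid_set(3, TRUE_COEFS[3], n=13)
        table, _ = fit_and_test_all(data, data, model_ids=(3,))
        assert table.loc[3, "RMSE"] == pytest.approx(0.0, abs=1e-9)

    def test_train_equals_test_on_identity_split(self):
        data = _grid_set(10, TRUE_COEFS[10], n=13, noise_sd=2.0, seed=6)
        t1, _ = fit_and_test_all(data, data)
        t2, _ = fit_and_test_all(data, data)
        assert t1.equals(t2)
        assert t1.shape == (10, 4)

    @staticmethod
    def _session_like_set(seed, n=13, noise_sd=1.0):
        # physiology-like windows: HR and SBP rise together across trials
        # with independent per-window jitter, PTT from the generative model
        from armpulse.synthetic_data import invert_sbp_model

        rng = np.random.default_rng(seed)
        u = np.linspace(0.0, 1.0, n)
        hr = 72.0 + 30.0 * u + rng.normal(0.0, 3.0, n)
        sbp_true = 112.0 + 28.0 * u + rng.normal(0.0, 3.0, n)
        spec = SbpModelSpec(model_id=10, coefficients=TRUE_COEFS[10])
        ptt = invert_sbp_model(spec, sbp_true, hr)
        return CalibrationSet(
            ptt_s=ptt, hr_bpm=hr, sbp_mmhg=sbp_true + rng.normal(0.0, noise_sd, n)
        )

    def test_hr_models_beat_ptt_models_on_hr_generated_data(self):
        train = self._session_like_set(seed=7)
        test = self._session_like_set(seed=8)
        table, _ = fit_and_test_all(train, test)
        hr_mae = table.loc[list(HR_MODEL_IDS), "MAE"].max()
        ptt_mae = table.loc[[m for m in MODEL_IDS if m not in HR_MODEL_IDS], "MAE"].min()
        assert hr_mae < ptt_mae
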