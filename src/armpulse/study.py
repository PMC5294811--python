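"""End-to-end train-session / test-session study orchestration.

Reproduces the evaluation design of the monitoring system: every tunable
quantity (detector threshold, SVM classifier, SBP model coefficients) is
fitted on the training session only; the testing session is scored with
those frozen artifacts, so no test-session sample, feature or reference
value influences any fitted parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import beat_detection as bd
from . import pulse_timing as pt
from .evaluation import AgreementStats, aami_check, agreement_stats
from .preprocess import ECG_FILTER, PPG_FILTER, bandpass, resample
from .sbp_models import MODEL_IDS, CalibrationSet, SbpModelSpec, fit_and_test_all
from .signal_io import BeatAnnotation, Session, load_session
from .synthetic_data import ECG_RATE_HZ

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyReport", "run_study", "prepare_session"]


@dataclass
class StudyConfig:
    """Detector and evaluation parameters of one study run."""

    window_s: float = 20.0
    kappa: float = 0.15
    refractory_s: float = 0.2
    base_threshold_frac: float = 0.3
    label_tol_s: float = 0.075
    rr_gate_s: tuple[float, float] = (0.25, 2.0)
    svm_c: float = 1.0
    model_ids: tuple[int, ...] = MODEL_IDS


@dataclass
class PreparedSession:
    """Filtered channels plus the reference beats of one session."""

    session: Session
    arm_ecg_f: object
    ppg_f: object
    ref_beats: BeatAnnotation


@dataclass
class StudyReport:
    """All numbers of one train/test study run."""

    train_table: pd.DataFrame
    test_table: pd.DataFrame
    aami: dict[int, bool]
    specs: dict[int, SbpModelSpec]
    hr_stats: AgreementStats | None
    detector_summary: dict

    def to_dict(self) -> dict:
        return {
            "train": self.train_table.round(6).to_dict(orient="index"),
            "test": self.test_table.round(6).to_dict(orient="index"),
            "aami": {int(k): bool(v) for k, v in self.aami.items()},
            "coefficients": {
                int(k): list(v.coefficients) for k, v in self.specs.items()
            },
            "hr": None
            if self.hr_stats is None
            else {
                "n": self.hr_stats.n,
                "me": self.hr_stats.me,
                "std": self.hr_stats.std,
                "mae": self.hr_stats.mae,
                "rmse": self.hr_stats.rmse,
            },
            "detector": self.detector_summary,
        }


def prepare_session(session: Session) -> PreparedSession:
    """Filter the channels and derive the reference beat annotation.

    The arm ECG is band-passed at 2-30 Hz; the PPG at 0.5-8 Hz, then
    resampled to the ECG rate.  Reference beats come from the session's
    annotation when present, else from a threshold detector on the
    (filtered) strong chest lead.
    """
    arm_f = bandpass(session.arm_ecg, ECG_FILTER)
    ppg_f = resample(bandpass(session.arm_ppg, PPG_FILTER), ECG_RATE_HZ)
    if session.beats is not None:
        ref_beats = session.beats
    else:
        chest_f = bandpass(session.chest_ecg, ECG_FILTER)
        ref_beats = bd.detect_beats_threshold(chest_f)
    return PreparedSession(
        session=session, arm_ecg_f=arm_f, ppg_f=ppg_f, ref_beats=ref_beats
    )


def _calibration_set(
    prep: PreparedSession, beats: BeatAnnotation, cfg: StudyConfig
) -> tuple[CalibrationSet, dict[int, float]]:
    feet = pt.find_ppg_feet(prep.ppg_f, beats)
    pairs = pt.compute_ptt(beats, feet)
    ihr = pt.instantaneous_hr(beats, cfg.rr_gate_s)
    ms = pt.windowed_measurements(
        pairs, ihr, prep.session.layout, prep.session.refs
    )
    hr_by_trial = {m.trial_index: m.mean_hr_bpm for m in ms}
    return CalibrationSet.from_measurements(ms), hr_by_trial


def run_study(
    train: Session | str | Path,
    test: Session | str | Path,
    config: StudyConfig | None = None,
) -> StudyReport:
    """Train on one session, evaluate on another, report the full table.

    Returns per-model train/test agreement statistics (mmHg), AAMI
    verdicts on the test windows, fitted coefficients, windowed-HR
    agreement of the arm-ECG estimate against the chest-derived reference,
    and detector stage counts.
    """
    cfg = config or StudyConfig()
    if not isinstance(train, Session):
        train = load_session(train)
    if not isinstance(test, Session):
        test = load_session(test)
    prep_tr = prepare_session(train)
    prep_te = prepare_session(test)

    # --- detector training on the training session only -------------------
    theta = bd.base_threshold_from_beats(
        prep_tr.arm_ecg_f, prep_tr.ref_beats.times_s, cfg.base_threshold_frac
    )
    gen_cfg = bd.CandidateGenConfig(
        base_threshold=theta,
        window_s=cfg.window_s,
        kappa=cfg.kappa,
        refractory_s=cfg.refractory_s,
    )
    cand_tr = bd.generate_candidates(prep_tr.arm_ecg_f, gen_cfg)
    times_tr, X_tr = bd.extract_feature_matrix(prep_tr.arm_ecg_f, cand_tr)
    y_tr = bd.label_candidates(times_tr, prep_tr.ref_beats, cfg.label_tol_s)
    if np.unique(y_tr).size == 2:
        model = bd.train_svm(X_tr, y_tr, C=cfg.svm_c)
    else:
        # pristine training signal: every candidate is a beat, nothing to learn
        logger.info("single-class training labels; detector keeps all candidates")
        model = None

    beats_tr = bd.detect_beats(prep_tr.arm_ecg_f, model, gen_cfg)
    beats_te = bd.detect_beats(prep_te.arm_ecg_f, model, gen_cfg)
    detector_summary = {
        "train_candidates": int(times_tr.size),
        "train_positive_labels": int((y_tr == 1).sum()),
        "train_beats_kept": len(beats_tr),
        "test_beats_kept": len(beats_te),
        "support_vectors": 0 if model is None else int(model.alphas.size),
        "base_threshold": float(theta),
    }
    logger.info("detector: %s", detector_summary)

    # --- calibration sets --------------------------------------------------
    calib_tr, _ = _calibration_set(prep_tr, beats_tr, cfg)
    calib_te, hr_te = _calibration_set(prep_te, beats_te, cfg)

    test_table, specs = fit_and_test_all(calib_tr, calib_te, cfg.model_ids)
    train_table, _ = fit_and_test_all(calib_tr, calib_tr, cfg.model_ids)
    aami = {}
    for mid in cfg.model_ids:
        st = AgreementStats(
            n=calib_te.n,
            me=float(test_table.loc[mid, "ME"]),
            std=float(test_table.loc[mid, "STD"]),
            mae=float(test_table.loc[mid, "MAE"]),
            rmse=float(test_table.loc[mid, "RMSE"]),
        )
        aami[mid] = aami_check(st)

    # --- windowed HR agreement vs chest-derived truth ----------------------
    hr_stats = None
    try:
        truth_ihr = pt.instantaneous_hr(prep_te.ref_beats, cfg.rr_gate_s)
        truth_by_trial = pt.window_average(truth_ihr, test.layout)
        common = sorted(set(hr_te) & set(truth_by_trial))
        if len(common) >= 2:
            hr_stats = agreement_stats(
                [hr_te[t] for t in common], [truth_by_trial[t] for t in common]
            )
    except ValueError:
        logger.warning("windowed HR agreement unavailable")

    return StudyReport(
        train_table=train_table,
        test_table=test_table,
        aami=aami,
        specs=specs,
        hr_stats=hr_stats,
        detector_summary=detector_summary,
    )
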