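"""The ten PTT-based systolic blood pressure calibration models.

Models 1-7 use pulse transit time alone; models 8-10 add heart rate:

    1   SBP = a ln(PTT) + b
    2   SBP = a PTT^-1 + b
    3   SBP = a PTT + b
    4   SBP = a PTT^2 + b PTT + c
    5   SBP = a PTT^2 + b
    6   SBP = a e^(b PTT)
    7   SBP = a PTT^-2 + b
    8   SBP = a PTT^-2 + b HR^-2 + c
    9   SBP = a ln(PTT) + b ln(HR) + c
    10  SBP = a PTT + b HR + c

All coefficients are trainable and calibrated per subject on that
subject's training windows.  Units are fixed package-wide: PTT in seconds,
HR in BPM, SBP in mmHg.  Models linear in their coefficients are fitted by
ordinary least squares; model 6 by nonlinear least squares on the SBP
scale, initialized from the log-linear fit ln(SBP) = ln(a) + b PTT.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from .pulse_timing import WindowedMeasurement

__all__ = [
    "MODEL_IDS",
    "HR_MODEL_IDS",
    "SbpModelSpec",
    "CalibrationSet",
    "design_terms",
    "fit_model",
    "predict",
    "fit_and_test_all",
]

MODEL_IDS = tuple(range(1, 11))
HR_MODEL_IDS = (8, 9, 10)
_N_COEF = {1: 2, 2: 2, 3: 2, 4: 3, 5: 2, 6: 2, 7: 2, 8: 3, 9: 3, 10: 3}


def uses_hr(model_id: int) -> bool:
    return model_id in HR_MODEL_IDS


@dataclass
class SbpModelSpec:
    """A fitted calibration model: id, coefficients, diagnostics."""

    model_id: int
    coefficients: tuple[float, ...]
    n: int = 0
    rss: float = float("nan")

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"model_id must be in {MODEL_IDS}")
        self.coefficients = tuple(float(c) for c in self.coefficients)
        if len(self.coefficients) != _N_COEF[self.model_id]:
            raise ValueError(
                f"model {self.model_id} takes {_N_COEF[self.model_id]} coefficients"
            )

    @property
    def uses_hr(self) -> bool:
        return uses_hr(self.model_id)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "model_id": self.model_id,
                    "coefficients": list(self.coefficients),
                    "units": {"ptt": "s", "hr": "bpm", "sbp": "mmHg"},
                    "n": self.n,
                    "rss": self.rss,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "SbpModelSpec":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            model_id=int(d["model_id"]),
            coefficients=tuple(d["coefficients"]),
            n=int(d.get("n", 0)),
            rss=float(d.get("rss", float("nan"))),
        )


@dataclass
class CalibrationSet:
    """Windowed (PTT, HR, reference SBP) triples for fitting/testing."""

    ptt_s: np.ndarray
    hr_bpm: np.ndarray
    sbp_mmhg: np.ndarray

    def __post_init__(self) -> None:
        self.ptt_s = np.asarray(self.ptt_s, dtype=float)
        self.hr_bpm = np.asarray(self.hr_bpm, dtype=float)
        self.sbp_mmhg = np.asarray(self.sbp_mmhg, dtype=float)
        if not (self.ptt_s.shape == self.hr_bpm.shape == self.sbp_mmhg.shape):
            raise ValueError("ptt, hr and sbp must align")
        if np.any(self.ptt_s <= 0) or np.any(self.hr_bpm <= 0):
            raise ValueError("PTT and HR must be positive")

    @property
    def n(self) -> int:
        return self.ptt_s.size

    @classmethod
    def from_measurements(cls, ms: list[WindowedMeasurement]) -> "CalibrationSet":
        ms = [m for m in ms if m.sbp_ref_mmhg is not None]
        return cls(
            ptt_s=np.array([m.mean_ptt_s for m in ms]),
            hr_bpm=np.array([m.mean_hr_bpm for m in ms]),
            sbp_mmhg=np.array([m.sbp_ref_mmhg for m in ms]),
        )


def design_terms(
    model_id: int, ptt_s, hr_bpm=None
) -> np.ndarray:
    """Regressor columns of one model (intercept excluded; model 6 has none).

    Returns an ``(n, k)`` matrix for array input or ``(k,)`` for scalars.
    """
    scalar = np.isscalar(ptt_s)
    ptt = np.atleast_1d(np.asarray(ptt_s, dtype=float))
    if np.any(ptt <= 0):
        raise ValueError("PTT must be positive")
    if uses_hr(model_id):
        if hr_bpm is None:
            raise ValueError(f"model {model_id} requires HR")
        hr = np.atleast_1d(np.asarray(hr_bpm, dtype=float))
        if np.any(hr <= 0):
            raise ValueError("HR must be positive")
    if model_id == 1:
        cols = [np.log(ptt)]
    elif model_id == 2:
        cols = [1.0 / ptt]
    elif model_id == 3:
        cols = [ptt]
    elif model_id == 4:
        cols = [ptt**2, ptt]
    elif model_id == 5:
        cols = [ptt**2]
    elif model_id == 6:
        cols = [ptt]  # used only by the nonlinear fit's initializer
    elif model_id == 7:
        cols = [ptt**-2]
    elif model_id == 8:
        cols = [ptt**-2, hr**-2.0]
    elif model_id == 9:
        cols = [np.log(ptt), np.log(hr)]
    elif model_id == 10:
        cols = [ptt, hr]
    else:
        raise ValueError(f"unknown model id {model_id}")
    out = np.column_stack(cols)
    return out[0] if scalar else out


def fit_model(model_id: int, data: CalibrationSet) -> SbpModelSpec:
    """Calibrate one model on windowed training data.

    Linear-in-coefficients models are solved by least squares on the
    design matrix with an appended intercept; model 6 is a nonlinear fit
    of ``a exp(b PTT)`` on the SBP scale.
    """
    k = _N_COEF[model_id]
    if data.n < k:
        raise ValueError(f"model {model_id} needs at least {k} windows, got {data.n}")
    if model_id == 6:
        return _fit_exponential(data)
    A = design_terms(model_id, data.ptt_s, data.hr_bpm)
    A = np.column_stack([A, np.ones(data.n)])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError(f"rank-deficient design for model {model_id}")
    coef, _, _, _ = np.linalg.lstsq(A, data.sbp_mmhg, rcond=None)
    resid = data.sbp_mmhg - A @ coef
    return SbpModelSpec(
        model_id=model_id,
        coefficients=tuple(coef),
        n=data.n,
        rss=float(resid @ resid),
    )


def _fit_exponential(data: CalibrationSet) -> SbpModelSpec:
    if np.any(data.sbp_mmhg <= 0):
        raise ValueError("exponential model requires positive SBP")
    # log-linear initializer: ln SBP = ln a + b PTT
    A = np.column_stack([np.ones(data.n), data.ptt_s])
    c0, _, _, _ = np.linalg.lstsq(A, np.log(data.sbp_mmhg), rcond=None)
    p0 = (float(np.exp(c0[0])), float(c0[1]))
    popt, _ = curve_fit(
        lambda t, a, b: a * np.exp(b * t),
        data.ptt_s,
        data.sbp_mmhg,
        p0=p0,
        maxfev=20000,
    )
    resid = data.sbp_mmhg - popt[0] * np.exp(popt[1] * data.ptt_s)
    return SbpModelSpec(
        model_id=6, coefficients=(float(popt[0]), float(popt[1])), n=data.n,
        rss=float(resid @ resid),
    )


def predict(spec: SbpModelSpec, ptt_s, hr_bpm=None):
    """Evaluate a fitted model at the given PTT (s) and, if used, HR (BPM)."""
    scalar = np.isscalar(ptt_s)
    ptt = np.atleast_1d(np.asarray(ptt_s, dtype=float))
    if np.any(ptt <= 0):
        raise ValueError("PTT must be positive")
    if spec.uses_hr and hr_bpm is None:
        raise ValueError(f"model {spec.model_id} requires HR")
    if spec.model_id == 6:
        a, b = spec.coefficients
        out = a * np.exp(b * ptt)
    else:
        A = design_terms(spec.model_id, ptt, np.atleast_1d(hr_bpm) if hr_bpm is not None else None)
        coef = np.asarray(spec.coefficients)
        out = A @ coef[:-1] + coef[-1]
    return float(out[0]) if scalar else out


def fit_and_test_all(
    train: CalibrationSet,
    test: CalibrationSet,
    model_ids: tuple[int, ...] = MODEL_IDS,
) -> tuple[pd.DataFrame, dict[int, SbpModelSpec]]:
    """Fit every model on the training windows, score on the test windows.

    Returns a per-model table of ME, STD, MAE, RMSE (mmHg) plus the fitted
    specs.
    """
    from .evaluation import agreement_stats

    rows = {}
    specs: dict[int, SbpModelSpec] = {}
    for mid in model_ids:
        spec = fit_model(mid, train)
        specs[mid] = spec
        est = predict(spec, test.ptt_s, test.hr_bpm if spec.uses_hr else None)
        st = agreement_stats(est, test.sbp_mmhg)
        rows[mid] = {"ME": st.me, "STD": st.std, "MAE": st.mae, "RMSE": st.rmse}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "model_id"
    return table, specs
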