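"""Agreement statistics, Bland-Altman summaries and the AAMI criterion.

Conventions: the mean-error STD uses the sample (n-1) denominator and the
RMSE uses n, so the identity ``rmse^2 = me^2 + std^2 (n-1)/n`` holds for
every computed :class:`AgreementStats`.  Bland-Altman limits of agreement
are ``me -/+ 1.96 std``.  The AAMI device criterion (|ME| <= 5 mmHg and
STD <= 8 mmHg) is boundary-inclusive.

The module also carries the published testing-performance benchmark of the
ten calibration models (ME, STD, MAE, RMSE in mmHg, per signal pairing)
and of the windowed heart-rate estimates, used for comparison arithmetic
such as :func:`relative_increase`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AgreementStats",
    "agreement_stats",
    "aami_check",
    "correlation_matrix",
    "relative_increase",
    "ARM_TEST_BENCHMARK",
    "CHEST_TEST_BENCHMARK",
    "HR_TEST_BENCHMARK",
]


@dataclass(frozen=True)
class AgreementStats:
    """Summary of estimate-minus-reference differences."""

    n: int
    me: float
    std: float
    mae: float
    rmse: float

    @property
    def loa_low(self) -> float:
        return self.me - 1.96 * self.std

    @property
    def loa_high(self) -> float:
        return self.me + 1.96 * self.std


def agreement_stats(estimates, references) -> AgreementStats:
    """ME, sample STD, MAE, RMSE and limits of agreement of paired series."""
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("estimates and references must have equal length")
    n = est.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = est - ref
    return AgreementStats(
        n=n,
        me=float(np.mean(d)),
        std=float(np.std(d, ddof=1)),
        mae=float(np.mean(np.abs(d))),
        rmse=float(np.sqrt(np.mean(d**2))),
    )


def aami_check(stats: AgreementStats) -> bool:
    """AAMI device criterion: |ME| <= 5 mmHg and STD <= 8 mmHg (inclusive)."""
    return abs(stats.me) <= 5.0 and stats.std <= 8.0


def correlation_matrix(series_list) -> np.ndarray:
    """Pearson correlation matrix of aligned value series.

    Series must share one length >= 3; a zero-variance series is an error.
    The result is exactly symmetric with a unit diagonal.
    """
    arrs = [np.asarray(s, dtype=float) for s in series_list]
    if len(arrs) < 2:
        raise ValueError("need at least 2 series")
    n = arrs[0].size
    if n < 3 or any(a.size != n for a in arrs):
        raise ValueError("series must be aligned with common length >= 3")
    if any(np.std(a) < 1e-15 for a in arrs):
        raise ValueError("constant series: correlation undefined")
    m = np.corrcoef(np.vstack(arrs))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 1.0)
    return m


def relative_increase(value: float, baseline: float) -> float:
    """Percent increase of ``value`` over ``baseline``, to 1 decimal place."""
    if not baseline > 0:
        raise ValueError("baseline must be positive")
    return round(100.0 * (value - baseline) / baseline, 1)


def _benchmark(rows: dict[int, tuple[float, float, float, float]]) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["ME", "STD", "MAE", "RMSE"])
    df.index.name = "model_id"
    return df


#: Published single-arm study benchmark: testing performance of the ten
#: calibration models with arm-ECG + arm-PPG (mmHg).
ARM_TEST_BENCHMARK = _benchmark(
    {
        1: (1.17, 6.00, 4.73, 6.09),
        2: (1.58, 6.62, 5.08, 6.78),
        3: (0.73, 5.88, 4.58, 5.90),
        4: (0.29, 6.15, 4.82, 6.14),
        5: (0.85, 5.85, 4.59, 5.89),
        6: (0.74, 5.88, 4.59, 5.90),
        7: (0.79, 5.95, 4.65, 5.98),
        8: (1.59, 4.44, 3.69, 4.70),
        9: (1.62, 4.43, 3.67, 4.70),
        10: (1.63, 4.44, 3.68, 4.71),
    }
)

#: Same benchmark with chest-ECG + arm-PPG (mmHg).
CHEST_TEST_BENCHMARK = _benchmark(
    {
        1: (0.96, 5.97, 4.66, 6.02),
        2: (1.46, 6.60, 5.01, 6.74),
        3: (0.59, 5.86, 4.54, 5.87),
        4: (0.02, 6.33, 4.96, 6.30),
        5: (0.68, 5.86, 4.57, 5.88),
        6: (0.61, 5.86, 4.55, 5.86),
        7: (0.68, 5.91, 4.60, 5.93),
        8: (1.58, 4.41, 3.62, 4.67),
        9: (1.61, 4.41, 3.61, 4.67),
        10: (1.61, 4.42, 3.62, 4.69),
    }
)

#: Published windowed heart-rate testing benchmark (BPM).
HR_TEST_BENCHMARK = pd.DataFrame(
    {"MAE": [0.21, 0.37], "RMSE": [1.20, 2.11]},
    index=pd.Index(["arm_ecg", "arm_ppg"], name="source"),
)
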