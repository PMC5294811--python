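"""Machine-learning-enabled heartbeat identification in weak arm-ECG.

The framework has four stages:

1. *Candidate generation* — local maxima of the filtered ECG above an
   adaptive threshold ``thr(t) = theta + kappa * P2P_20s(t)``, where
   ``P2P_20s`` is the peak-to-peak range of the surrounding 20 s window.
   The threshold tracks the signal fluctuation so that real beats are kept
   (high sensitivity) even when motion artifacts inflate the baseline; many
   artifact spikes are also kept (low precision) and handed to the
   classifier.
2. *Feature extraction* — ten motion-artifact-tolerant morphology features
   per candidate (angles, R/S difference, symmetries, skewness, variance,
   RMS, and two local slope angles).
3. *Classification* — a linear soft-margin SVM (C = 1) trained on a labeled
   session, solved in the dual by sequential minimal optimization with
   maximal-violating-pair working-set selection.
4. *Confident-beat output* — candidates classified +1, in time order.

The SVM solver is written here rather than wrapped from a library because
the dual coefficients, dual objective and KKT residuals are part of the
module's contract and are exercised directly by the test suite.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal, stats

from .signal_io import BeatAnnotation, SignalChannel

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateGenConfig",
    "BeatCandidate",
    "SvmModel",
    "FEATURE_NAMES",
    "generate_candidates",
    "extract_features",
    "extract_feature_matrix",
    "label_candidates",
    "train_svm",
    "classify",
    "detect_beats",
    "detect_beats_threshold",
    "base_threshold_from_beats",
    "greedy_match",
]

FEATURE_NAMES = (
    "r_angle",
    "s_angle",
    "rs_diff",
    "r_symmetry",
    "s_symmetry",
    "skns",
    "var",
    "rms",
    "alpha3",
    "alpha2",
)

# Morphology geometry (seconds). The R region spans the normal QRS width;
# the S valley is sought within 100 ms after the apex.
R_REGION_HALF_S = 0.060
S_SEARCH_S = 0.100
ANGLE_ARM_S = 0.020


@dataclass(frozen=True)
class CandidateGenConfig:
    """Adaptive-threshold candidate generator parameters.

    ``base_threshold`` is the fixed threshold theta in filtered-signal
    units (a practical default is 0.3x the median beat amplitude of the
    training data, see :func:`base_threshold_from_beats`); ``kappa`` scales
    the windowed peak-to-peak fluctuation term.
    """

    base_threshold: float
    window_s: float = 20.0
    kappa: float = 0.15
    refractory_s: float = 0.2

    def __post_init__(self) -> None:
        if not self.window_s > 0:
            raise ValueError("window_s must be > 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if not self.refractory_s > 0:
            raise ValueError("refractory_s must be > 0")


@dataclass
class BeatCandidate:
    """Candidate apex time with its feature vector and (optional) label."""

    time_s: float
    features: np.ndarray
    label: int = 0  # +1 beat, -1 artifact, 0 unknown


class EdgeError(ValueError):
    """Candidate too close to the record edge for feature extraction."""


def base_threshold_from_beats(
    ecg: SignalChannel, beat_times_s: np.ndarray, frac: float = 0.3
) -> float:
    """theta = ``frac`` x median beat apex amplitude of a labeled record."""
    amps = []
    half = max(1, int(round(0.02 * ecg.sampling_rate_hz)))
    for t in np.asarray(beat_times_s, dtype=float):
        k = ecg.index_of(t)
        lo, hi = max(0, k - half), min(ecg.n, k + half + 1)
        if hi > lo:
            amps.append(float(np.max(ecg.samples[lo:hi])))
    if not amps:
        raise ValueError("no beats to derive a base threshold from")
    return frac * float(np.median(amps))


def generate_candidates(
    ecg: SignalChannel, cfg: CandidateGenConfig
) -> np.ndarray:
    """Candidate R-apex times: local maxima above the adaptive threshold.

    Within any ``refractory_s`` span only the largest maximum survives.
    """
    fs = ecg.sampling_rate_hz
    x = ecg.samples
    win = int(round(cfg.window_s * fs))
    if win > x.size:
        raise ValueError("window_s longer than the recording")
    p2p = ndimage.maximum_filter1d(x, win, mode="nearest") - ndimage.minimum_filter1d(
        x, win, mode="nearest"
    )
    thr = cfg.base_threshold + cfg.kappa * p2p
    distance = max(1, int(round(cfg.refractory_s * fs)))
    peaks, _ = signal.find_peaks(x, height=thr, distance=distance)
    return ecg.start_time_s + peaks / fs


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = float(np.std(a)), float(np.std(b))
    if sa < 1e-15 or sb < 1e-15:
        # Flat-vs-flat is perfectly mirror-symmetric by convention.
        return 1.0
    return float(np.corrcoef(a, b)[0, 1])


def _apex_angle(seg: np.ndarray, apex: int, arm: int, half: int, p2p: float) -> float:
    """Interior angle at the apex of the triangle (apex, +-arm samples).

    Voltage is normalized by the region peak-to-peak and time by the region
    half-width, so the angle is dimensionless and amplitude-invariant.
    """
    if p2p < 1e-15:
        return float(np.pi)
    t0 = 0.0
    v0 = seg[apex] / p2p
    u = np.array([-arm / half, seg[apex - arm] / p2p - v0])
    v = np.array([arm / half, seg[apex + arm] / p2p - v0])
    denom = float(np.linalg.norm(u) * np.linalg.norm(v))
    if denom < 1e-15:
        return float(np.pi)
    c = float(np.dot(u, v)) / denom
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def _symmetry(region: np.ndarray) -> float:
    half = region.size // 2
    left = region[:half]
    right = region[half + 1 :][::-1]
    return _pearson(left, right)


def _slope_angle(v1: float, v2: float, half: int, p2p: float) -> float:
    if p2p < 1e-15:
        return 0.0
    return float(np.arctan((v2 - v1) / p2p * half))


def extract_features(ecg: SignalChannel, time_s: float) -> np.ndarray:
    """The ten-dimensional morphology feature vector of one candidate.

    Raises :class:`EdgeError` when the apex sits too close to the record
    edges for the R region, S search and S region to fit.
    """
    fs = ecg.sampling_rate_hz
    x = ecg.samples
    half = max(2, int(round(R_REGION_HALF_S * fs)))
    arm = max(1, int(round(ANGLE_ARM_S * fs)))
    s_search = max(1, int(round(S_SEARCH_S * fs)))
    r = ecg.index_of(time_s)
    if r - half < 0 or r + s_search + half >= x.size or r - 3 < 0 or r + 2 >= x.size:
        raise EdgeError(f"candidate at {time_s:.3f}s too close to the record edge")

    region = x[r - half : r + half + 1]
    p2p = float(np.ptp(region))
    s_off = int(np.argmin(x[r + 1 : r + s_search + 1])) + 1
    s = r + s_off
    s_region = x[s - half : s + half + 1] if s - half >= 0 else x[: s + half + 1]
    s_seg_lo = s - half
    s_p2p = float(np.ptp(x[max(0, s_seg_lo) : s + half + 1]))

    r_angle = _apex_angle(region, half, arm, half, p2p)
    # angle at the S valley, arms clipped to the record
    s_region_full = x[max(0, s - half) : min(x.size, s + half + 1)]
    s_apex = s - max(0, s - half)
    s_arm = min(arm, s_apex, s_region_full.size - 1 - s_apex)
    if s_arm >= 1:
        s_angle = _apex_angle(s_region_full, s_apex, s_arm, half, s_p2p)
    else:
        s_angle = float(np.pi)
    rs_diff = float(x[r] - x[s])
    r_symmetry = _symmetry(region)
    s_symmetry = _symmetry(s_region_full) if s_region_full.size >= 3 else 1.0

    var = float(np.var(region, ddof=1))
    rms = float(np.sqrt(np.mean(region**2)))
    if var < 1e-30:
        skns = 0.0
    else:
        skns = float(stats.skew(region, bias=False))

    alpha3 = _slope_angle(x[r - 3], x[r - 2], half, p2p)
    alpha2 = _slope_angle(x[r + 1], x[r + 2], half, p2p)

    feats = np.array(
        [r_angle, s_angle, rs_diff, r_symmetry, s_symmetry, skns, var, rms, alpha3, alpha2]
    )
    if not np.all(np.isfinite(feats)):
        raise EdgeError(f"non-finite features at {time_s:.3f}s")
    return feats


def extract_feature_matrix(
    ecg: SignalChannel, times_s: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Features for many candidates; edge candidates are dropped with a log.

    Returns ``(kept_times, X)``.
    """
    kept, rows = [], []
    n_dropped = 0
    for t in np.asarray(times_s, dtype=float):
        try:
            rows.append(extract_features(ecg, t))
            kept.append(t)
        except EdgeError:
            n_dropped += 1
    if n_dropped:
        logger.warning("dropped %d edge candidates", n_dropped)
    X = np.array(rows) if rows else np.empty((0, len(FEATURE_NAMES)))
    return np.asarray(kept, dtype=float), X


# ---------------------------------------------------------------------------
# Candidate labeling (greedy nearest-first one-to-one matching)
# ---------------------------------------------------------------------------

def greedy_match(
    a_times: np.ndarray, b_times: np.ndarray, tol_s: float
) -> list[tuple[int, int]]:
    """Greedy nearest-first one-to-one matching of two sorted event lists.

    All candidate pairs within ``tol_s`` are sorted by absolute time
    difference and taken greedily, each event consumed at most once.
    """
    a = np.asarray(a_times, dtype=float)
    b = np.asarray(b_times, dtype=float)
    pairs: list[tuple[float, int, int]] = []
    j0 = 0
    for i, t in enumerate(a):
        lo = np.searchsorted(b, t - tol_s, side="left")
        hi = np.searchsorted(b, t + tol_s, side="right")
        for j in range(lo, hi):
            pairs.append((abs(t - b[j]), i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    out: list[tuple[int, int]] = []
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.append((i, j))
    out.sort()
    return out


def label_candidates(
    candidate_times: np.ndarray,
    reference: BeatAnnotation,
    tol_s: float = 0.075,
) -> np.ndarray:
    """+1 where a reference beat lies within ``tol_s`` (one-to-one), else -1."""
    cand = np.asarray(candidate_times, dtype=float)
    labels = -np.ones(cand.size, dtype=int)
    for i, _ in greedy_match(cand, reference.times_s, tol_s):
        labels[i] = 1
    return labels


# ---------------------------------------------------------------------------
# Linear soft-margin SVM, dual SMO solver
# ---------------------------------------------------------------------------

@dataclass
class SvmModel:
    """Fitted linear soft-margin SVM in dual form.

    ``alphas`` are the nonzero Lagrange multipliers of ``support_vectors``
    (stored in standardized feature space); ``alphas_full`` preserves the
    multiplier of every training point in input order for KKT auditing.
    The per-feature standardization (mean, scale) of the training set is
    stored and applied inside :meth:`decision_function`, so callers pass
    raw features.
    """

    alphas: np.ndarray
    support_vectors: np.ndarray
    sv_labels: np.ndarray
    bias: float
    C: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    alphas_full: np.ndarray | None = None
    n_iter: int = 0

    @property
    def weight_vector(self) -> np.ndarray:
        """w = sum_i alpha_i y_i x_i in standardized feature space."""
        return (self.alphas * self.sv_labels) @ self.support_vectors

    def _scale(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.scaler_mean.size:
            raise ValueError(
                f"feature dimension {X.shape[1]} != model dimension {self.scaler_mean.size}"
            )
        return (X - self.scaler_mean) / self.scaler_scale

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Xs = self._scale(X)
        return Xs @ self.weight_vector + self.bias

    def dual_objective(self) -> float:
        """sum alpha - 0.5 ||w||^2 (zero-alpha points contribute nothing)."""
        w = self.weight_vector
        return float(np.sum(self.alphas) - 0.5 * np.dot(w, w))

    def primal_objective(self, X: np.ndarray, y: np.ndarray) -> float:
        """0.5 ||w||^2 + C sum hinge, with slack xi_i = max(0, 1 - y_i f(x_i))."""
        w = self.weight_vector
        f = self.decision_function(X)
        xi = np.maximum(0.0, 1.0 - np.asarray(y, dtype=float) * f)
        return float(0.5 * np.dot(w, w) + self.C * np.sum(xi))

    def to_json(self, path) -> None:
        payload = {
            "alphas": self.alphas.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "sv_labels": self.sv_labels.tolist(),
            "bias": self.bias,
            "C": self.C,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SvmModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            alphas=np.array(d["alphas"], dtype=float),
            support_vectors=np.array(d["support_vectors"], dtype=float),
            sv_labels=np.array(d["sv_labels"], dtype=float),
            bias=float(d["bias"]),
            C=float(d["C"]),
            scaler_mean=np.array(d["scaler_mean"], dtype=float),
            scaler_scale=np.array(d["scaler_scale"], dtype=float),
        )


def _smo(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    tol: float = 1e-6,
    max_iter: int | None = None,
) -> tuple[np.ndarray, float, int]:
    """SMO with second-order working-set selection for the linear-kernel dual.

    Minimizes ``0.5 a' Q a - e' a`` with ``Q_ij = y_i y_j x_i . x_j`` subject
    to ``0 <= a_i <= C`` and ``y' a = 0``.  The first index maximizes the
    KKT violation; the second maximizes the guaranteed decrease of the dual
    objective along the pair direction.  The gradient is maintained
    incrementally; each iteration costs two kernel-row products.  Returns
    ``(alpha, bias, n_iter)``.
    """
    n = X.shape[0]
    if max_iter is None:
        max_iter = max(100_000, 50 * n)
    alpha = np.zeros(n)
    grad = -np.ones(n)  # grad of the dual objective: Q a - e
    eps = 1e-12 * max(C, 1.0)
    xn2 = np.einsum("ij,ij->i", X, X)

    it = 0
    for it in range(1, max_iter + 1):
        yg = -y * grad  # candidate bias per point: y_i - w.x_i
        up = ((y > 0) & (alpha < C - eps)) | ((y < 0) & (alpha > eps))
        low = ((y > 0) & (alpha > eps)) | ((y < 0) & (alpha < C - eps))
        if not up.any() or not low.any():
            break
        i = int(np.flatnonzero(up)[np.argmax(yg[up])])
        m_val = float(yg[i])
        M_val = float(np.min(yg[low]))
        if m_val - M_val < tol:
            break
        ki = X @ X[i]
        # second-order choice of j: maximize b^2 / eta over violating pairs
        b_all = m_val - yg
        eta_all = np.maximum(xn2[i] + xn2 - 2.0 * ki, 1e-12)
        cand = low & (b_all > 0)
        score = np.where(cand, (b_all * b_all) / eta_all, -np.inf)
        j = int(np.argmax(score))
        qi = y * ki * y[i]
        qj = y * (X @ X[j]) * y[j]
        eta = float(eta_all[j])
        d = (m_val - float(yg[j])) / eta
        # step along the equality constraint: a_i += y_i d, a_j -= y_j d
        lo_d, hi_d = -np.inf, np.inf
        if y[i] > 0:
            lo_d = max(lo_d, -alpha[i])
            hi_d = min(hi_d, C - alpha[i])
        else:
            lo_d = max(lo_d, alpha[i] - C)
            hi_d = min(hi_d, alpha[i])
        if y[j] > 0:
            lo_d = max(lo_d, alpha[j] - C)
            hi_d = min(hi_d, alpha[j])
        else:
            lo_d = max(lo_d, -alpha[j])
            hi_d = min(hi_d, C - alpha[j])
        d = float(np.clip(d, lo_d, hi_d))
        if d == 0.0:
            break
        alpha[i] += y[i] * d
        alpha[j] -= y[j] * d
        grad += qi * (y[i] * d) + qj * (-y[j] * d)
    else:
        warnings.warn("SMO hit the iteration limit before convergence")

    # bias from unbounded (0 < alpha < C) support vectors, else midpoint
    yg = -y * grad
    free = (alpha > eps) & (alpha < C - eps)
    if free.any():
        b = float(np.mean(yg[free]))
    else:
        up = ((y > 0) & (alpha < C - eps)) | ((y < 0) & (alpha > eps))
        low = ((y > 0) & (alpha > eps)) | ((y < 0) & (alpha < C - eps))
        hi = float(np.max(yg[up])) if up.any() else 0.0
        lo = float(np.min(yg[low])) if low.any() else 0.0
        b = 0.5 * (hi + lo)
    return alpha, b, it


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    tol: float = 1e-6,
) -> SvmModel:
    """Fit the linear soft-margin SVM on labeled feature vectors.

    Features are z-scored by training-set statistics (stored in the model);
    the dual problem is solved to a maximal-KKT-violation below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n, d) with one label per row")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    classes = np.unique(y)
    if not np.array_equal(classes, [-1, 1]):
        raise ValueError("both classes (+1/-1) must be present")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale < 1e-12] = 1.0
    Xs = (X - mean) / scale

    alpha, b, n_iter = _smo(Xs, y, C, tol=tol)
    sv = alpha > 1e-10 * max(C, 1.0)
    return SvmModel(
        alphas=alpha[sv],
        support_vectors=Xs[sv],
        sv_labels=y[sv],
        bias=b,
        C=C,
        scaler_mean=mean,
        scaler_scale=scale,
        alphas_full=alpha,
        n_iter=n_iter,
    )


def classify(model: SvmModel, X: np.ndarray) -> np.ndarray:
    """sign of the decision function; an exact tie maps to +1 (favor recall)."""
    dec = model.decision_function(X)
    out = np.where(dec >= 0.0, 1, -1)
    return out if np.asarray(X).ndim > 1 else int(out[0])


# ---------------------------------------------------------------------------
# Pipelines
# ---------------------------------------------------------------------------

def detect_beats(
    ecg: SignalChannel, model: SvmModel | None, cfg: CandidateGenConfig
) -> BeatAnnotation:
    """Full detection pipeline: candidates -> features -> SVM -> +1 beats.

    ``model=None`` keeps every candidate: on pristine signals the adaptive
    candidate generator alone already has perfect precision, and a
    single-class training session gives the classifier nothing to learn.
    """
    cand = generate_candidates(ecg, cfg)
    times, X = extract_feature_matrix(ecg, cand)
    if times.size == 0:
        return BeatAnnotation(times_s=np.array([]), modality="ecg_r_peak")
    if model is None:
        labels = np.ones(times.size, dtype=int)
    else:
        labels = np.atleast_1d(classify(model, X))
    beats = times[labels == 1]
    logger.info("detect_beats: %d candidates -> %d beats", times.size, beats.size)
    return BeatAnnotation(times_s=beats, modality="ecg_r_peak")


def detect_beats_threshold(
    ecg: SignalChannel,
    height_frac: float = 0.5,
    refractory_s: float = 0.25,
) -> BeatAnnotation:
    """Simple fixed-threshold R-peak detector for strong (chest) ECG.

    Peaks above ``height_frac`` of the record maximum, separated by the
    refractory period.  Used to derive reference beats from the chest lead.
    """
    fs = ecg.sampling_rate_hz
    height = height_frac * float(np.max(ecg.samples))
    distance = max(1, int(round(refractory_s * fs)))
    peaks, _ = signal.find_peaks(ecg.samples, height=height, distance=distance)
    return BeatAnnotation(
        times_s=ecg.start_time_s + peaks / fs, modality="ecg_r_peak"
    )
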