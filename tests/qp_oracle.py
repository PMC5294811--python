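"""Independent brute-force QP oracle for the soft-margin SVM dual.

Solves max_a sum(a) - 0.5 a'Qa  s.t.  0 <= a <= C, y'a = 0 with a generic
constrained optimizer (SLSQP), entirely independent of the package's SMO
path.  Practical only for small n.
"""

import numpy as np
from scipy.optimize import minimize


def dual_optimum(Xs: np.ndarray, y: np.ndarray, C: float = 1.0) -> float:
    """Optimal dual objective value for standardized features ``Xs``."""
    n = len(y)
    Q = (y[:, None] * y[None, :]) * (Xs @ Xs.T)
    best = None
    # feasible start (zeros) plus restarts; SLSQP's line search can stall at
    # tight tolerances, so fall back to looser ftol values
    for x0 in (np.zeros(n), np.full(n, C / 2)):
        for ftol in (1e-14, 1e-12, 1e-10):
            res = minimize(
                lambda a: 0.5 * a @ Q @ a - a.sum(),
                x0,
                jac=lambda a: Q @ a - 1.0,
                bounds=[(0.0, C)] * n,
                constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
                method="SLSQP",
                options={"maxiter": 1000, "ftol": ftol},
            )
            feasible = abs(res.x @ y) < 1e-8
            if feasible and (best is None or res.fun < best):
                best = float(res.fun)
            if res.success and feasible:
                return -float(res.fun)
    if best is None:  # pragma: no cover
        raise RuntimeError("oracle QP failed from every start")
    return -best


def max_kkt_violation(model, X: np.ndarray, y: np.ndarray) -> float:
    """Largest violation of the complementary-slackness conditions.

    alpha=0 requires y f >= 1; alpha=C requires y f <= 1; interior alpha
    requires y f = 1.
    """
    f = model.decision_function(X)
    a = model.alphas_full
    C = model.C
    worst = 0.0
    for ai, yi, fi in zip(a, y, f):
        margin = yi * fi
        if ai < 1e-8 * C:
            worst = max(worst, max(0.0, 1.0 - margin))
        elif ai > C * (1 - 1e-8):
            worst = max(worst, max(0.0, margin - 1.0))
        else:
            worst = max(worst, abs(margin - 1.0))
    return worst


def random_problem(rng: np.random.Generator, n_max: int = 20, d_max: int = 3):
    """A random small two-class problem with both labels present."""
    n = int(rng.integers(6, n_max + 1))
    d = int(rng.integers(1, d_max + 1))
    X = rng.normal(size=(n, d))
    y = np.where(rng.uniform(size=n) < 0.5, -1.0, 1.0)
    if np.unique(y).size < 2:
        y[0] *= -1
    return X, y
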