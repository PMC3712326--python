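"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's own algorithms: segmentation is
checked by exhaustive enumeration of all cut placements, and region
verdicts by the interval-membership form of the zero-one loss.
"""

import itertools

import numpy as np


def enumerate_best_rss(x: np.ndarray, k: int) -> float:
    """Optimal k-segment residual sum of squares by full enumeration."""
    x = np.asarray(x, dtype=np.float64)
    m = x.size
    best = np.inf
    for cuts in itertools.combinations(range(1, m), k - 1):
        bounds = (0, *cuts, m)
        rss = 0.0
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            seg = x[lo:hi]
            rss += float(np.sum((seg - seg.mean()) ** 2))
        best = min(best, rss)
    return best


def membership_error(count: int, lo: int, hi: float) -> int:
    """Zero-one loss in its interval-membership form."""
    return 0 if lo <= count <= hi else 1


def fused_lasso_objective(x: np.ndarray, mu: np.ndarray, lam2: float) -> float:
    return 0.5 * float(np.sum((x - mu) ** 2)) + lam2 * float(
        np.sum(np.abs(np.diff(mu))))


def fused_lasso_kkt_residual(x: np.ndarray, mu: np.ndarray, lam2: float) -> float:
    """Max violation of the subgradient stationarity conditions.

    With g = mu - x and c = cumsum(g): the total gradient must vanish
    (c[-1] = 0) and for every inner boundary i, c[i] must equal +lam2 at an
    upward jump, -lam2 at a downward jump, and lie in [-lam2, lam2] when
    fused.
    """
    g = np.asarray(mu, float) - np.asarray(x, float)
    c = np.cumsum(g)
    residual = abs(c[-1])
    d = np.diff(mu)
    for i in range(len(d)):
        if d[i] > 1e-12:
            residual = max(residual, abs(c[i] - lam2))
        elif d[i] < -1e-12:
            residual = max(residual, abs(c[i] + lam2))
        else:
            residual = max(residual, max(0.0, abs(c[i]) - lam2))
    return residual
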