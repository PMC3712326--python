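"""Piecewise-constant segmentation and 1-D fused-lasso smoothing.

Two model families share one breakpoint-extraction convention (the midpoint
between adjacent probes with unequal fitted values):

* ``cghseg.k`` / ``pelt.n`` — the maximum-likelihood piecewise-constant
  segmentation for each segment count k, combined with a penalty criterion
  that selects k as a function of the smoothness parameter.  The two
  criteria are mathematically equivalent under ``beta = lam * m``.
* ``flsa`` / ``flsa.norm`` — the exact 1-D fused lasso (total-variation
  denoising), with the penalty either used directly or normalized by probe
  density per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cnsmooth.annotation_error import extract_breakpoints
from cnsmooth.core_data import Profile, SmoothedFit

MODELS = ("cghseg.k", "pelt.n", "flsa", "flsa.norm")

#: |mu_j - mu_{j+1}| <= tol * (1 + max|x|) counts as "no jump" for the
#: fused lasso, whose iterates fuse values only up to float rounding.
DEFAULT_FUSION_TOL = 1e-9

DEFAULT_KMAX = 20


@dataclass(frozen=True)
class PenaltyGrid:
    """A finite, strictly increasing grid of smoothness parameters."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("penalty grid must be a non-empty 1-D array")
        if values.size > 1 and not np.all(np.diff(values) > 0):
            raise ValueError("penalty grid must be strictly increasing")
        if np.any(values < 0):
            raise ValueError("penalty values must be non-negative")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.size)

    @classmethod
    def log_spaced(cls, lo: float, hi: float, count: int) -> "PenaltyGrid":
        return cls(np.logspace(np.log10(lo), np.log10(hi), count))

    @classmethod
    def default_for(cls, model: str, count: int = 100) -> "PenaltyGrid":
        if model in ("cghseg.k", "pelt.n"):
            return cls.log_spaced(1e-8, 1e4, count)
        if model in ("flsa", "flsa.norm"):
            return cls.log_spaced(1e-5, 1e12, count)
        raise ValueError(f"unknown model: {model!r}")


@dataclass(frozen=True)
class SegmentationSet:
    """Optimal piecewise-constant fits for every segment count 1..kmax.

    ``fitted[k-1]`` is the least-squares optimal signal with at most k
    constant runs; ``rss[k-1]`` its residual sum of squares.
    """

    fitted: np.ndarray
    rss: np.ndarray
    kmax: int

    @property
    def m(self) -> int:
        return int(self.fitted.shape[1])


def segment_dp(x: np.ndarray, kmax: int) -> SegmentationSet:
    """Exact least-squares segmentation via O(kmax * m^2) dynamic programming.

    For each k in 1..kmax, minimizes sum (x_i - mu_i)^2 over signals mu with
    at most k constant runs; within-segment values are segment means.
    """
    x = np.asarray(x, dtype=np.float64)
    m = x.size
    if m < 1:
        raise ValueError("empty signal")
    if kmax < 1:
        raise ValueError("kmax must be at least 1")
    if kmax > m:
        raise ValueError(f"kmax={kmax} exceeds number of probes m={m}")

    s1 = np.concatenate(([0.0], np.cumsum(x)))
    s2 = np.concatenate(([0.0], np.cumsum(x * x)))
    idx = np.arange(m + 1)
    seg_len = idx[None, :] - idx[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        cost = (s2[None, :] - s2[:, None]) - (s1[None, :] - s1[:, None]) ** 2 / seg_len
    cost[seg_len <= 0] = np.inf
    np.maximum(cost, 0.0, where=seg_len > 0, out=cost)  # clamp float noise

    best = np.full((kmax + 1, m + 1), np.inf)
    best[0, 0] = 0.0
    last_cut = np.zeros((kmax + 1, m + 1), dtype=np.int64)
    for k in range(1, kmax + 1):
        totals = best[k - 1][:, None] + cost
        last_cut[k] = np.argmin(totals, axis=0)
        best[k] = totals[last_cut[k], idx]

    fitted = np.empty((kmax, m))
    rss = np.empty(kmax)
    for k in range(1, kmax + 1):
        rss[k - 1] = best[k, m]
        j = m
        for kk in range(k, 0, -1):
            i = last_cut[kk, j]
            fitted[k - 1, i:j] = (s1[j] - s1[i]) / (j - i)
            j = i
    # rss is non-increasing in k by construction; clamp rounding noise
    np.minimum.accumulate(rss, out=rss)
    return SegmentationSet(fitted=fitted, rss=rss, kmax=kmax)


def _rss_of(seg) -> np.ndarray:
    if isinstance(seg, SegmentationSet):
        return seg.rss
    return np.asarray(seg, dtype=np.float64)


def choose_k_lavielle(seg, m: int, lam: float) -> int:
    """Select k minimizing ``lam * k + rss[k] / m``; ties go to smallest k."""
    if lam < 0:
        raise ValueError("lam must be non-negative")
    rss = _rss_of(seg)
    k = np.arange(1, rss.size + 1)
    criterion = lam * k + rss / m
    return int(np.argmin(criterion)) + 1


def choose_k_penalty(seg, beta: float) -> int:
    """Select k minimizing ``beta * (k - 1) + rss[k]``; ties go to smallest k."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    rss = _rss_of(seg)
    k = np.arange(1, rss.size + 1)
    criterion = beta * (k - 1) + rss
    return int(np.argmin(criterion)) + 1


def fused_lasso_1d(x: np.ndarray, lam2: float) -> np.ndarray:
    """Exact minimizer of ``1/2 sum (x_i - mu_i)^2 + lam2 * sum |mu_i - mu_{i+1}|``.

    Direct non-iterative taut-string style algorithm; the solution is the
    unique minimizer of the strictly convex objective.
    """
    y = np.asarray(x, dtype=np.float64)
    n = y.size
    if n < 1:
        raise ValueError("empty signal")
    if lam2 < 0:
        raise ValueError("lam2 must be non-negative")
    if n == 1 or lam2 == 0:
        return y.copy()

    out = np.empty(n)
    lam = float(lam2)
    k = k0 = kminus = kplus = 0
    vmin = y[0] - lam
    vmax = y[0] + lam
    umin = lam
    umax = -lam
    while True:
        while k < n - 1:
            if y[k + 1] + umin < vmin - lam:
                # vmin violated: the segment [k0, kminus] is locked at vmin
                out[k0:kminus + 1] = vmin
                k = k0 = kminus = kplus = kminus + 1
                vmin = y[k]
                vmax = y[k] + 2 * lam
                umin = lam
                umax = -lam
            elif y[k + 1] + umax > vmax + lam:
                out[k0:kplus + 1] = vmax
                k = k0 = kminus = kplus = kplus + 1
                vmin = y[k] - 2 * lam
                vmax = y[k]
                umin = lam
                umax = -lam
            else:
                k += 1
                umin += y[k] - vmin
                umax += y[k] - vmax
                if umin >= lam:
                    vmin += (umin - lam) / (k - k0 + 1)
                    umin = lam
                    kminus = k
                if umax <= -lam:
                    vmax += (umax + lam) / (k - k0 + 1)
                    umax = -lam
                    kplus = k
        if umin < 0:
            out[k0:kminus + 1] = vmin
            k = k0 = kminus = kminus + 1
            vmin = y[k]
            umin = lam
            umax = y[k] + lam - vmax
        elif umax > 0:
            out[k0:kplus + 1] = vmax
            k = k0 = kplus = kplus + 1
            vmax = y[k]
            umax = -lam
            umin = y[k] - lam - vmin
        else:
            out[k0:n] = vmin + umin / (k - k0 + 1)
            return out


def flsa_norm_penalty(lam: float, m: int, l: float) -> float:
    """Density-normalized fused-lasso penalty: ``lam * m * 1e6 / l``."""
    if l <= 0:
        raise ValueError("chromosome length must be positive")
    if m < 1:
        raise ValueError("m must be at least 1")
    return lam * m * 1e6 / l


def smooth_profile(
    profile: Profile,
    model: str,
    grid: PenaltyGrid | None = None,
    kmax: int = DEFAULT_KMAX,
    fusion_tolerance: float = DEFAULT_FUSION_TOL,
) -> list[SmoothedFit]:
    """Smooth every chromosome of a profile over a whole penalty grid.

    Chromosomes are smoothed independently.  For the segment-count models
    the SegmentationSet is computed once per chromosome and reused across
    the grid (``kmax`` is clipped to m on short chromosomes).  Returns one
    SmoothedFit per grid value, in grid order.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model: {model!r} (expected one of {MODELS})")
    if grid is None:
        grid = PenaltyGrid.default_for(model)

    chrom_names = sorted(profile.chromosomes)
    smoothed: dict[str, list[np.ndarray]] = {}
    if model in ("cghseg.k", "pelt.n"):
        for chrom in chrom_names:
            series = profile.chromosomes[chrom]
            seg = segment_dp(series.values, min(kmax, series.m))
            per_lambda = []
            for lam in grid.values:
                if model == "cghseg.k":
                    k = choose_k_lavielle(seg, series.m, lam)
                else:
                    k = choose_k_penalty(seg, lam * series.m)
                per_lambda.append(seg.fitted[k - 1])
            smoothed[chrom] = per_lambda
        tol = 0.0  # DP fits jump only between segments with different means
    else:
        for chrom in chrom_names:
            series = profile.chromosomes[chrom]
            per_lambda = []
            for lam in grid.values:
                if model == "flsa":
                    lam2 = lam
                else:
                    lam2 = flsa_norm_penalty(lam, series.m, series.length_bp)
                per_lambda.append(fused_lasso_1d(series.values, lam2))
            smoothed[chrom] = per_lambda
        tol = fusion_tolerance

    fits = []
    for j, lam in enumerate(grid.values):
        per_chrom = {c: smoothed[c][j] for c in chrom_names}
        breakpoints = {}
        for chrom in chrom_names:
            series = profile.chromosomes[chrom]
            scale = tol * (1.0 + np.max(np.abs(series.values)))
            breakpoints[chrom] = extract_breakpoints(
                per_chrom[chrom], series.positions, tolerance=scale)
        fits.append(SmoothedFit(smoothness=float(lam), smoothed=per_chrom,
                                breakpoints=breakpoints))
    return fits
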