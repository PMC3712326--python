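"""Breakpoint extraction and annotation-based error / ROC quantities.

An annotation is a closed genomic region with an interval-valued expected
breakpoint count [a_lo, a_hi].  A model's predicted breakpoints in the
region are counted and compared to the interval with a zero-one loss:
a false positive when the count exceeds a_hi, a false negative when it
falls below a_lo.  Unbounded-above annotations can never produce false
positives, and [0, 0] annotations can never produce false negatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from cnsmooth.core_data import AnnotatedRegion, SmoothedFit


class UndefinedRateError(ValueError):
    """A TPR/FPR was requested but its annotation set is empty."""


@dataclass(frozen=True)
class RegionVerdict:
    """Zero-one outcome of one annotation at one smoothness value."""

    fp: int
    fn: int
    tp: int

    @property
    def error(self) -> int:
        return self.fp + self.fn


@dataclass(frozen=True)
class ErrorCurve:
    """Per-lambda annotation-error totals over a fixed annotation set.

    ``breakpoint_totals`` carries the total number of predicted breakpoints
    at each lambda over the curve's scope; it orders the grid from most to
    fewest breakpoints during tie-breaking in training.
    """

    lambdas: np.ndarray
    errors: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tp: np.ndarray
    n_positive: int
    n_negative: int
    n_annotations: int
    breakpoint_totals: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("lambdas", "errors", "fp", "fn", "tp", "breakpoint_totals"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (np.asarray(self.lambdas).size,):
                raise ValueError(f"{name} length does not match the grid")
            arrays[name] = arr
        for name, arr in arrays.items():
            object.__setattr__(self, name, arr)
        if np.any(self.errors > self.n_annotations):
            raise ValueError("errors exceed the number of annotations")
        if np.any(self.tp > self.n_positive) or np.any(self.fp > self.n_negative):
            raise ValueError("tp/fp totals exceed their annotation-set sizes")

    def to_frame(self, model: str = "") -> pd.DataFrame:
        return pd.DataFrame({
            "model": model,
            "lambda": self.lambdas,
            "errors": self.errors,
            "fp": self.fp,
            "fn": self.fn,
            "tp": self.tp,
            "n_breakpoints": self.breakpoint_totals,
            "n_annotations": self.n_annotations,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
        })


def extract_breakpoints(values: np.ndarray, positions: np.ndarray,
                        tolerance: float = 0.0) -> np.ndarray:
    """Midpoints between adjacent probes whose fitted values differ.

    With ``tolerance > 0``, adjacent values within tolerance are treated as
    fused (needed for fused-lasso output, where equality holds only up to
    float rounding).
    """
    values = np.asarray(values, dtype=np.float64)
    positions = np.asarray(positions, dtype=np.float64)
    if values.shape != positions.shape:
        raise ValueError("values and positions must have the same length")
    if positions.size > 1 and not np.all(np.diff(positions) > 0):
        raise ValueError("positions must be strictly increasing")
    jumps = np.abs(np.diff(values)) > tolerance
    return (positions[:-1][jumps] + positions[1:][jumps]) / 2.0


def count_in_region(breakpoints: np.ndarray, start: float, end: float) -> int:
    """Number of breakpoint positions inside the closed interval [start, end]."""
    if start > end:
        raise ValueError(f"malformed region: start {start} > end {end}")
    b = np.asarray(breakpoints, dtype=np.float64)
    return int(np.count_nonzero((b >= start) & (b <= end)))


def region_verdict(count: int, min_breakpoints: int,
                   max_breakpoints: float) -> RegionVerdict:
    """Compare a predicted breakpoint count to an annotation interval."""
    if count < 0:
        raise ValueError("count must be non-negative")
    fp = 1 if count > max_breakpoints else 0
    fn = 1 if count < min_breakpoints else 0
    tp = 1 if count >= min_breakpoints else 0
    return RegionVerdict(fp=fp, fn=fn, tp=tp)


def _positive(a: AnnotatedRegion) -> bool:
    return a.min_breakpoints >= 1


def _negative(a: AnnotatedRegion) -> bool:
    return not math.isinf(a.max_breakpoints)


def local_error(fits: Sequence[SmoothedFit],
                annotations: Sequence[AnnotatedRegion]) -> ErrorCurve:
    """Total annotation error of one profile's fits at every grid value.

    ``fits`` is the lambda-indexed output of a smoother for a single
    profile; ``annotations`` are the regions of that profile.  Regions on
    chromosomes absent from the fit are rejected.
    """
    lambdas = np.array([fit.smoothness for fit in fits], dtype=np.float64)
    n = lambdas.size
    errors = np.zeros(n, dtype=np.int64)
    fp = np.zeros(n, dtype=np.int64)
    fn = np.zeros(n, dtype=np.int64)
    tp = np.zeros(n, dtype=np.int64)
    for region in annotations:
        if region.chromosome not in fits[0].breakpoints:
            raise ValueError(
                f"annotation on absent chromosome: "
                f"{region.profile_id}/{region.chromosome}"
            )
        for j, fit in enumerate(fits):
            count = count_in_region(fit.breakpoints[region.chromosome],
                                    region.start, region.end)
            verdict = region_verdict(count, region.min_breakpoints,
                                     region.max_breakpoints)
            errors[j] += verdict.error
            fp[j] += verdict.fp
            fn[j] += verdict.fn
            if _positive(region):  # TPR sums TP over positive annotations only
                tp[j] += verdict.tp
    totals = np.array([fit.total_breakpoints() for fit in fits], dtype=np.int64)
    return ErrorCurve(
        lambdas=lambdas, errors=errors, fp=fp, fn=fn, tp=tp,
        n_positive=sum(_positive(a) for a in annotations),
        n_negative=sum(_negative(a) for a in annotations),
        n_annotations=len(annotations),
        breakpoint_totals=totals,
    )


def global_error(curves: Sequence[ErrorCurve]) -> ErrorCurve:
    """Pointwise sum of per-profile error curves sharing one grid."""
    if not curves:
        raise ValueError("no curves to aggregate")
    lambdas = curves[0].lambdas
    for curve in curves[1:]:
        if curve.lambdas.shape != lambdas.shape or not np.allclose(
                curve.lambdas, lambdas, rtol=0, atol=0):
            raise ValueError("error curves computed on different grids")
    return ErrorCurve(
        lambdas=lambdas,
        errors=np.sum([c.errors for c in curves], axis=0),
        fp=np.sum([c.fp for c in curves], axis=0),
        fn=np.sum([c.fn for c in curves], axis=0),
        tp=np.sum([c.tp for c in curves], axis=0),
        n_positive=sum(c.n_positive for c in curves),
        n_negative=sum(c.n_negative for c in curves),
        n_annotations=sum(c.n_annotations for c in curves),
        breakpoint_totals=np.sum([c.breakpoint_totals for c in curves], axis=0),
    )


def roc_curve(curve: ErrorCurve) -> np.ndarray:
    """(FPR, TPR) pairs in grid order; requires non-empty positive and
    negative annotation sets."""
    if curve.n_positive == 0:
        raise UndefinedRateError("TPR undefined: no positive annotations")
    if curve.n_negative == 0:
        raise UndefinedRateError("FPR undefined: no negative annotations")
    fpr = curve.fp / curve.n_negative
    tpr = curve.tp / curve.n_positive
    return np.column_stack([fpr, tpr])
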