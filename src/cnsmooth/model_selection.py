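"""Global and local smoothness training by annotation-error minimization.

Both trainers pick the grid value minimizing the error curve.  When several
grid values attain the minimum, ties are resolved on the argmin list
ordered from most to fewest predicted breakpoints:

1. an interior plateau takes its middle element;
2. a plateau reaching the most-breakpoints end takes the fewest-breakpoints
   minimizer (guards against false positives);
3. a plateau reaching the fewest-breakpoints end takes the most-breakpoints
   minimizer (guards against false negatives).

A plateau spanning the whole ordering counts as interior (rule 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cnsmooth.annotation_error import ErrorCurve


@dataclass(frozen=True)
class TrainedSmoothness:
    """A trained smoothness value and the evidence behind it."""

    chosen: float
    chosen_index: int
    scope: str
    achieved_error: int
    argmin_set: np.ndarray

    def __post_init__(self) -> None:
        if self.chosen not in np.asarray(self.argmin_set):
            raise ValueError("chosen value must belong to the argmin set")


def _breakpoint_order(curve: ErrorCurve) -> np.ndarray:
    """Grid indices ordered from most to fewest predicted breakpoints.

    Exact ties in breakpoint count fall back to increasing lambda, which is
    the natural orientation when lambda is monotonic in breakpoints.
    """
    return np.lexsort((curve.lambdas, -curve.breakpoint_totals))


def _select(curve: ErrorCurve, scope: str) -> TrainedSmoothness:
    if curve.lambdas.size == 0:
        raise ValueError("cannot train on an empty grid")
    order = _breakpoint_order(curve)
    errors_ordered = curve.errors[order]
    min_error = errors_ordered.min()
    argmin_ordered = np.flatnonzero(errors_ordered == min_error)

    touches_most = argmin_ordered[0] == 0
    touches_fewest = argmin_ordered[-1] == errors_ordered.size - 1
    if len(argmin_ordered) == 1:
        pick = argmin_ordered[0]
    elif touches_most and touches_fewest:
        pick = argmin_ordered[(len(argmin_ordered) - 1) // 2]
    elif touches_most:
        pick = argmin_ordered[-1]  # fewest breakpoints among minimizers
    elif touches_fewest:
        pick = argmin_ordered[0]  # most breakpoints among minimizers
    else:
        pick = argmin_ordered[(len(argmin_ordered) - 1) // 2]

    chosen_index = int(order[pick])
    return TrainedSmoothness(
        chosen=float(curve.lambdas[chosen_index]),
        chosen_index=chosen_index,
        scope=scope,
        achieved_error=int(min_error),
        argmin_set=np.sort(curve.lambdas[order[argmin_ordered]]),
    )


def train_global(curve: ErrorCurve) -> TrainedSmoothness:
    """Smoothness minimizing the global (all-profiles) error curve."""
    return _select(curve, scope="global")


def train_local(curve: ErrorCurve) -> TrainedSmoothness:
    """Smoothness minimizing one profile's local error curve."""
    return _select(curve, scope="local")
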