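"""Cross-validation protocols for annotation-trained smoothing models.

Two protocols:

* ``loocv_annotation`` — per repetition, one annotation per profile is held
  out; the smoothness is trained on the remainder (globally, or locally per
  profile) and errors are counted on the held-out regions only.
* ``nt_fold_cv`` — profiles are partitioned into ``floor(n/t)`` folds of
  about ``t`` profiles; each fold in turn trains a global smoothness that
  is tested on all annotations of every other fold.

Smoothing is computed once per profile and reused across folds and
repetitions, since the penalty grid does not depend on the split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from cnsmooth.annotation_error import ErrorCurve, count_in_region, region_verdict
from cnsmooth.core_data import AnnotatedRegion, Profile
from cnsmooth.model_selection import _select
from cnsmooth.segmentation import DEFAULT_KMAX, PenaltyGrid, smooth_profile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVResult:
    """Aggregate test error of one protocol/scope combination."""

    protocol: str
    scope: str
    per_fold_errors: np.ndarray
    mean: float
    sd: float
    fp_rate: float
    fn_rate: float
    seed: int
    t: int | None = None
    V: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_fold_errors",
                           np.asarray(self.per_fold_errors, dtype=np.float64))


@dataclass
class ProfileErrorData:
    """Per-profile, per-annotation, per-lambda verdicts, precomputed once.

    ``err``/``fp``/``fn``/``tp`` map profile_id to (n_annotations, n_lambda)
    0/1 matrices; ``bkpt`` maps profile_id to per-lambda total predicted
    breakpoint counts (used for tie-break ordering).
    """

    lambdas: np.ndarray
    profile_ids: list[str]
    annotations: dict[str, list[AnnotatedRegion]]
    err: dict[str, np.ndarray] = field(default_factory=dict)
    fp: dict[str, np.ndarray] = field(default_factory=dict)
    fn: dict[str, np.ndarray] = field(default_factory=dict)
    tp: dict[str, np.ndarray] = field(default_factory=dict)
    bkpt: dict[str, np.ndarray] = field(default_factory=dict)

    def curve(self, pid: str, keep: np.ndarray | None = None) -> ErrorCurve:
        """Local error curve of one profile, optionally restricted to a
        boolean annotation mask."""
        mask = np.ones(len(self.annotations[pid]), dtype=bool) if keep is None else keep
        ann = [a for a, k in zip(self.annotations[pid], mask) if k]
        return ErrorCurve(
            lambdas=self.lambdas,
            errors=self.err[pid][mask].sum(axis=0),
            fp=self.fp[pid][mask].sum(axis=0),
            fn=self.fn[pid][mask].sum(axis=0),
            tp=self.tp[pid][mask].sum(axis=0),
            n_positive=sum(a.min_breakpoints >= 1 for a in ann),
            n_negative=sum(not a.unbounded for a in ann),
            n_annotations=len(ann),
            breakpoint_totals=self.bkpt[pid],
        )


def compute_error_data(
    profiles: Sequence[Profile],
    annotations: Sequence[AnnotatedRegion],
    model: str,
    grid: PenaltyGrid | None = None,
    kmax: int = DEFAULT_KMAX,
) -> ProfileErrorData:
    """Smooth every profile over the grid and score every annotation."""
    if grid is None:
        grid = PenaltyGrid.default_for(model)
    by_profile: dict[str, list[AnnotatedRegion]] = {}
    for region in annotations:
        by_profile.setdefault(region.profile_id, []).append(region)
    profile_map = {p.profile_id: p for p in profiles}
    unknown = set(by_profile) - set(profile_map)
    if unknown:
        raise ValueError(f"annotations reference unknown profiles: {sorted(unknown)}")

    ids = sorted(pid for pid in by_profile)
    data = ProfileErrorData(lambdas=grid.values.copy(), profile_ids=ids,
                            annotations={pid: by_profile[pid] for pid in ids})
    n_lambda = len(grid)
    for pid in ids:
        fits = smooth_profile(profile_map[pid], model, grid=grid, kmax=kmax)
        ann = by_profile[pid]
        err = np.zeros((len(ann), n_lambda), dtype=np.int64)
        fp = np.zeros_like(err)
        fn = np.zeros_like(err)
        tp = np.zeros_like(err)
        for i, region in enumerate(ann):
            if region.chromosome not in fits[0].breakpoints:
                raise ValueError(
                    f"annotation on absent chromosome: {pid}/{region.chromosome}")
            for j, fit in enumerate(fits):
                count = count_in_region(fit.breakpoints[region.chromosome],
                                        region.start, region.end)
                v = region_verdict(count, region.min_breakpoints,
                                   region.max_breakpoints)
                err[i, j] = v.error
                fp[i, j] = v.fp
                fn[i, j] = v.fn
                tp[i, j] = v.tp if region.min_breakpoints >= 1 else 0
        data.err[pid] = err
        data.fp[pid] = fp
        data.fn[pid] = fn
        data.tp[pid] = tp
        data.bkpt[pid] = np.array([fit.total_breakpoints() for fit in fits],
                                  dtype=np.int64)
    return data


def _sum_curve(data: ProfileErrorData, pids: Sequence[str],
               keep: Mapping[str, np.ndarray] | None = None) -> ErrorCurve:
    parts = [data.curve(pid, None if keep is None else keep[pid]) for pid in pids]
    from cnsmooth.annotation_error import global_error
    return global_error(parts)


def loocv_annotation(
    profiles: Sequence[Profile],
    annotations: Sequence[AnnotatedRegion],
    model: str,
    grid: PenaltyGrid | None = None,
    V: int = 10,
    seed: int = 1,
    kmax: int = DEFAULT_KMAX,
    error_data: ProfileErrorData | None = None,
) -> dict[str, CVResult]:
    """Leave-one-annotation-out CV comparing global and local training.

    Returns ``{"global": CVResult, "local": CVResult}``.  Profiles with a
    single annotation still contribute to the global scope but are excluded
    from the local scope (no training annotation would remain).
    """
    if V < 1:
        raise ValueError("V must be at least 1")
    data = error_data if error_data is not None else compute_error_data(
        profiles, annotations, model, grid, kmax)
    ids = data.profile_ids
    local_ids = [pid for pid in ids if len(data.annotations[pid]) >= 2]
    skipped = sorted(set(ids) - set(local_ids))
    if skipped:
        logger.info("local-scope LOOCV excludes profiles with <2 annotations: %s",
                    skipped)

    rng = np.random.default_rng(seed)
    rep_stats = {scope: {"err": [], "fp": [], "fn": []}
                 for scope in ("global", "local")}
    for _ in range(V):
        held = {pid: int(rng.integers(len(data.annotations[pid]))) for pid in ids}
        keep = {}
        for pid in ids:
            mask = np.ones(len(data.annotations[pid]), dtype=bool)
            mask[held[pid]] = False
            keep[pid] = mask

        train_curve = _sum_curve(data, ids, keep)
        j_global = _select(train_curve, "global").chosen_index
        g_err = g_fp = g_fn = 0
        for pid in ids:
            h = held[pid]
            g_err += data.err[pid][h, j_global]
            g_fp += data.fp[pid][h, j_global]
            g_fn += data.fn[pid][h, j_global]
        n_held = len(ids)
        rep_stats["global"]["err"].append(g_err / n_held)
        rep_stats["global"]["fp"].append(g_fp / n_held)
        rep_stats["global"]["fn"].append(g_fn / n_held)

        l_err = l_fp = l_fn = 0
        for pid in local_ids:
            j_local = _select(data.curve(pid, keep[pid]), "local").chosen_index
            h = held[pid]
            l_err += data.err[pid][h, j_local]
            l_fp += data.fp[pid][h, j_local]
            l_fn += data.fn[pid][h, j_local]
        n_local = len(local_ids)
        rep_stats["local"]["err"].append(l_err / n_local)
        rep_stats["local"]["fp"].append(l_fp / n_local)
        rep_stats["local"]["fn"].append(l_fn / n_local)

    results = {}
    for scope in ("global", "local"):
        errs = np.asarray(rep_stats[scope]["err"])
        results[scope] = CVResult(
            protocol="loo_annotation", scope=scope, per_fold_errors=errs,
            mean=float(errs.mean()), sd=float(errs.std(ddof=1)) if V > 1 else 0.0,
            fp_rate=float(np.mean(rep_stats[scope]["fp"])),
            fn_rate=float(np.mean(rep_stats[scope]["fn"])),
            seed=seed, V=V)
    return results


def nt_fold_cv(
    profiles: Sequence[Profile],
    annotations: Sequence[AnnotatedRegion],
    model: str,
    t: int,
    grid: PenaltyGrid | None = None,
    seed: int = 1,
    kmax: int = DEFAULT_KMAX,
    error_data: ProfileErrorData | None = None,
) -> CVResult:
    """floor(n/t)-fold CV: train a global smoothness on each fold of about
    t profiles, test on all annotations of all other folds."""
    data = error_data if error_data is not None else compute_error_data(
        profiles, annotations, model, grid, kmax)
    ids = list(data.profile_ids)
    n = len(ids)
    if not 1 <= t < n:
        raise ValueError(f"t must satisfy 1 <= t < n (t={t}, n={n})")
    n_folds = n // t
    if n_folds < 2:
        raise ValueError(f"floor(n/t) = {n_folds} < 2: no test set possible")

    rng = np.random.default_rng(seed)
    order = list(rng.permutation(n))
    sizes = [t] * n_folds
    for i in range(n - t * n_folds):  # remainder, one per fold from the front
        sizes[i % n_folds] += 1
    folds = []
    at = 0
    for size in sizes:
        folds.append([ids[k] for k in order[at:at + size]])
        at += size

    fold_err, fold_fp, fold_fn = [], [], []
    for f, train_ids in enumerate(folds):
        test_ids = [pid for g, fold in enumerate(folds) if g != f for pid in fold]
        train_curve = _sum_curve(data, train_ids)
        j = _select(train_curve, "global").chosen_index
        n_test = sum(len(data.annotations[pid]) for pid in test_ids)
        fold_err.append(sum(data.err[pid][:, j].sum() for pid in test_ids) / n_test)
        fold_fp.append(sum(data.fp[pid][:, j].sum() for pid in test_ids) / n_test)
        fold_fn.append(sum(data.fn[pid][:, j].sum() for pid in test_ids) / n_test)

    errs = np.asarray(fold_err)
    return CVResult(
        protocol="nt_fold", scope="global", per_fold_errors=errs,
        mean=float(errs.mean()),
        sd=float(errs.std(ddof=1)) if len(errs) > 1 else 0.0,
        fp_rate=float(np.mean(fold_fp)), fn_rate=float(np.mean(fold_fn)),
        seed=seed, t=t)
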