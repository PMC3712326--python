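"""Domain types and tabular I/O for probe profiles, annotations and segments.

Coordinate conventions: probe positions and annotated-region bounds are
1-based; regions are closed intervals, so a breakpoint landing exactly on a
bound counts as inside.  bedGraph input follows the standard 0-based
half-open convention and each interval is converted to its midpoint probe
position on read.  Segment output is written BED-like, 0-based half-open.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for an unbounded maximum expected breakpoint count.
UNBOUNDED = math.inf

#: Canonical label -> expected-breakpoint-count interval.
LABEL_INTERVALS = {
    "0breakpoints": (0, 0),
    "1breakpoint": (1, 1),
    ">0breakpoints": (1, UNBOUNDED),
}


class DataError(ValueError):
    """Raised when an input table violates the format contract."""


@dataclass(frozen=True)
class ProbeSeries:
    """Sorted probes of a single chromosome: positions and logratios.

    ``length_bp`` is the chromosome extent in base pairs; it is only needed
    by the length-normalized fused-lasso penalty and defaults to the last
    probe position when not supplied.
    """

    chromosome: str
    positions: np.ndarray
    values: np.ndarray
    length_bp: int | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        val = np.asarray(self.values, dtype=np.float64)
        if pos.ndim != 1 or val.ndim != 1 or pos.shape != val.shape:
            raise DataError("positions and values must be 1-D arrays of equal length")
        if pos.size < 1:
            raise DataError("a probe series needs at least one probe")
        if pos.size > 1 and not np.all(np.diff(pos) > 0):
            raise DataError(f"positions not strictly increasing on {self.chromosome}")
        if not np.all(np.isfinite(val)):
            raise DataError(f"non-finite logratio on {self.chromosome}")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)
        length = self.length_bp if self.length_bp is not None else int(pos[-1])
        if length < pos[-1]:
            raise DataError("length_bp smaller than the last probe position")
        object.__setattr__(self, "length_bp", int(length))

    @property
    def m(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class Profile:
    """A collection of per-chromosome probe series for one sample."""

    profile_id: str
    chromosomes: Mapping[str, ProbeSeries]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise DataError(f"profile {self.profile_id} has no chromosomes")
        object.__setattr__(self, "chromosomes", dict(self.chromosomes))

    @property
    def total_probes(self) -> int:
        return sum(series.m for series in self.chromosomes.values())


@dataclass(frozen=True)
class AnnotatedRegion:
    """A genomic interval plus an expected-breakpoint-count interval.

    ``min_breakpoints``/``max_breakpoints`` form the closed count interval;
    ``max_breakpoints`` may be ``math.inf`` for the unbounded ">0" label.
    """

    profile_id: str
    chromosome: str
    start: int
    end: int
    min_breakpoints: int
    max_breakpoints: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataError(
                f"region start {self.start} > end {self.end} "
                f"({self.profile_id}/{self.chromosome})"
            )
        if self.min_breakpoints < 0:
            raise DataError("min_breakpoints must be non-negative")
        if self.min_breakpoints > self.max_breakpoints:
            raise DataError(
                f"min_breakpoints {self.min_breakpoints} > "
                f"max_breakpoints {self.max_breakpoints}"
            )

    @property
    def unbounded(self) -> bool:
        return math.isinf(self.max_breakpoints)


@dataclass(frozen=True)
class SmoothedFit:
    """A smoothed signal at one smoothness value, with extracted breakpoints.

    ``smoothed`` maps chromosome -> fitted values (same length as the probe
    series); ``breakpoints`` maps chromosome -> sorted array of breakpoint
    positions (midpoints between adjacent probes, so often half-integers).
    """

    smoothness: float
    smoothed: Mapping[str, np.ndarray]
    breakpoints: Mapping[str, np.ndarray]

    def total_breakpoints(self) -> int:
        return sum(len(b) for b in self.breakpoints.values())


PathLike = Union[str, Path]


def _build_profile(profile_id: str, rows: pd.DataFrame,
                   length_bp: Mapping[str, int] | None = None) -> Profile:
    chromosomes: dict[str, ProbeSeries] = {}
    for chrom, sub in rows.groupby("chromosome", sort=True):
        sub = sub.sort_values("position")
        pos = sub["position"].to_numpy(dtype=np.int64)
        dup = pos[1:][np.diff(pos) == 0]
        if dup.size:
            raise DataError(
                f"duplicate probe position {int(dup[0])} on "
                f"{profile_id}/{chrom}"
            )
        chromosomes[str(chrom)] = ProbeSeries(
            chromosome=str(chrom),
            positions=pos,
            values=sub["logratio"].to_numpy(dtype=np.float64),
            length_bp=None if length_bp is None else length_bp.get(str(chrom)),
        )
    return Profile(profile_id=profile_id, chromosomes=chromosomes)


def read_profiles(source: PathLike | Iterable[PathLike], format: str = "csv") -> list[Profile]:
    """Read logratio profiles from CSV or bedGraph text.

    CSV needs columns profile_id, chromosome, position, logratio (one file,
    many profiles).  bedGraph is 4-column chrom/start/end/value with one
    profile per file; probe position is the midpoint of the 0-based
    half-open interval.  Rows with non-finite logratio are dropped with a
    logged count; duplicate (profile, chromosome, position) rows are
    rejected.
    """
    if format == "csv":
        frame = pd.read_csv(source)
        required = {"profile_id", "chromosome", "position", "logratio"}
        missing = required - set(frame.columns)
        if missing:
            raise DataError(f"profile CSV missing columns: {sorted(missing)}")
        if frame.empty:
            raise DataError(f"empty profile file: {source}")
        frames = [(str(pid), sub) for pid, sub in frame.groupby("profile_id", sort=True)]
    elif format == "bedgraph":
        paths = [source] if isinstance(source, (str, Path)) else list(source)
        frames = []
        for path in paths:
            bed = pd.read_csv(
                path, sep=r"\s+", comment="#", header=None,
                names=["chromosome", "start", "end", "logratio"],
            )
            if bed.empty:
                raise DataError(f"empty bedGraph file: {path}")
            # midpoint of the 0-based half-open interval, as a 1-based position
            bed["position"] = (bed["start"] + bed["end"]) // 2
            frames.append((Path(path).stem, bed))
    else:
        raise DataError(f"unknown profile format: {format!r}")

    profiles = []
    for pid, sub in frames:
        finite = np.isfinite(sub["logratio"].to_numpy(dtype=np.float64))
        dropped = int((~finite).sum())
        if dropped:
            logger.info("profile %s: dropped %d non-finite logratio rows", pid, dropped)
            sub = sub.loc[finite]
        if sub.empty:
            raise DataError(f"profile {pid} has no finite logratio rows")
        profiles.append(_build_profile(pid, sub))
    return profiles


def _parse_max(value) -> float:
    if value is None:
        return UNBOUNDED
    if isinstance(value, float) and math.isnan(value):
        return UNBOUNDED
    text = str(value).strip()
    if text == "" or text.lower() in {"inf", "infinity"}:
        return UNBOUNDED
    return float(text)


def read_annotations(source: PathLike) -> list[AnnotatedRegion]:
    """Read breakpoint-region annotations from CSV.

    Either explicit columns min_breakpoints/max_breakpoints (blank or "Inf"
    meaning unbounded) or a ``label`` column with values 0breakpoints /
    1breakpoint / >0breakpoints.
    """
    frame = pd.read_csv(source)
    base = {"profile_id", "chromosome", "start", "end"}
    missing = base - set(frame.columns)
    if missing:
        raise DataError(f"annotation CSV missing columns: {sorted(missing)}")
    regions = []
    for row in frame.itertuples(index=False):
        if "label" in frame.columns and not (
            isinstance(getattr(row, "label"), float) and math.isnan(getattr(row, "label"))
        ):
            label = str(getattr(row, "label"))
            if label not in LABEL_INTERVALS:
                raise DataError(f"unknown annotation label: {label!r}")
            lo, hi = LABEL_INTERVALS[label]
        elif "min_breakpoints" in frame.columns:
            lo = int(getattr(row, "min_breakpoints"))
            hi = _parse_max(getattr(row, "max_breakpoints", None))
        else:
            raise DataError(
                "annotation CSV needs either a label column or "
                "min_breakpoints/max_breakpoints columns"
            )
        regions.append(
            AnnotatedRegion(
                profile_id=str(row.profile_id),
                chromosome=str(row.chromosome),
                start=int(row.start),
                end=int(row.end),
                min_breakpoints=int(lo),
                max_breakpoints=hi,
            )
        )
    return regions


def write_annotations(regions: Sequence[AnnotatedRegion], path: PathLike) -> None:
    """Write annotations to CSV; unbounded maxima serialize as "Inf"."""
    rows = [
        {
            "profile_id": r.profile_id,
            "chromosome": r.chromosome,
            "start": r.start,
            "end": r.end,
            "min_breakpoints": r.min_breakpoints,
            "max_breakpoints": "Inf" if r.unbounded else int(r.max_breakpoints),
        }
        for r in regions
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_profiles(profiles: Sequence[Profile], path: PathLike) -> None:
    """Write profiles to the canonical CSV format (12 significant digits)."""
    rows = []
    for profile in profiles:
        for chrom, series in sorted(profile.chromosomes.items()):
            for pos, value in zip(series.positions, series.values):
                rows.append((profile.profile_id, chrom, int(pos), value))
    frame = pd.DataFrame(rows, columns=["profile_id", "chromosome", "position", "logratio"])
    frame.to_csv(path, index=False, float_format="%.12g")


def write_segments(fit: SmoothedFit, profile: Profile, segments_path: PathLike,
                   breakpoints_path: PathLike) -> None:
    """Write a fit as BED-like segment rows plus a breakpoints table.

    Segments are delimited by the fit's breakpoints and written 0-based
    half-open (chromosome, start, end, mean); breakpoints are written as
    (chromosome, position) with positions as produced by extraction.
    """
    seg_rows = []
    bkp_rows = []
    for chrom in sorted(profile.chromosomes):
        series = profile.chromosomes[chrom]
        fitted = np.asarray(fit.smoothed[chrom], dtype=np.float64)
        if fitted.size != series.m:
            raise DataError(f"fit length mismatch on chromosome {chrom}")
        breaks = np.asarray(fit.breakpoints[chrom], dtype=np.float64)
        # segment j spans probes between consecutive breakpoints
        cuts = np.searchsorted(series.positions, breaks)
        bounds = [0, *cuts.tolist(), series.m]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            seg_rows.append((
                chrom,
                int(series.positions[lo]) - 1,
                int(series.positions[hi - 1]),
                float(np.mean(fitted[lo:hi])),
            ))
        for position in breaks:
            bkp_rows.append((chrom, float(position)))
    pd.DataFrame(seg_rows, columns=["chromosome", "start", "end", "mean"]).to_csv(
        segments_path, index=False, float_format="%.12g")
    pd.DataFrame(bkp_rows, columns=["chromosome", "position"]).to_csv(
        breakpoints_path, index=False, float_format="%.12g")
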