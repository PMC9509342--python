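"""Data model and I/O for time-resolved mutation-frequency trajectories.

The central object is a :class:`TrajectorySet`: all mutation trajectories
observed by pool-sequencing of one host's bacterial population, together with
the sampling time grid (in days post-colonization) and the detection floor of
the variant calls (frequencies below it are reported as 0).

File dialect
------------
The canonical on-disk format is a long-format TSV with header columns
``host  mutation_id  target  func_class  day  frequency`` (UTF-8, '.' decimal
separator).  A day that appears in a host's grid but not for a particular
mutation is interpreted as *sampled, below detection* and stored as 0; days
that never appear for a host were simply not sampled.

OD600 kinetics series are two-column TSVs with header ``time_h  od600``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FUNC_CLASSES",
    "TimeGrid",
    "MutationRecord",
    "TrajectorySet",
    "ODSeries",
    "read_trajectories",
    "write_trajectories",
    "read_od_series",
    "to_generations",
    "TrajectoryFormatError",
]

#: Functional annotation classes for mutation records.
FUNC_CLASSES = frozenset(
    {"nonsynonymous", "synonymous", "intergenic", "indel", "IS", "HGT", "other"}
)

TRAJECTORY_COLUMNS = ["host", "mutation_id", "target", "func_class", "day", "frequency"]


class TrajectoryFormatError(ValueError):
    """Malformed or inconsistent trajectory table."""


@dataclass(frozen=True)
class TimeGrid:
    """Sampling days of one host and the day-to-generation conversion.

    Parameters
    ----------
    days
        Strictly increasing non-negative sampling days post-colonization.
    generations_per_day
        Bacterial generations elapsed per day; the in-vivo estimate for gut
        *E. coli* is 15.
    """

    days: tuple[float, ...]
    generations_per_day: float = 15.0

    def __post_init__(self) -> None:
        days = tuple(float(d) for d in self.days)
        object.__setattr__(self, "days", days)
        if len(days) == 0:
            raise ValueError("TimeGrid needs at least one sampling day")
        if days[0] < 0:
            raise ValueError("days must be non-negative")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("days must be strictly increasing")
        if not self.generations_per_day > 0:
            raise ValueError("generations_per_day must be positive")

    @property
    def end_day(self) -> float:
        return self.days[-1]

    @property
    def end_generation(self) -> float:
        return self.end_day * self.generations_per_day

    def generations(self, day: float) -> float:
        """Convert a day to generations (``day * generations_per_day``)."""
        if day < 0:
            raise ValueError(f"negative day: {day}")
        return day * self.generations_per_day


def to_generations(grid: TimeGrid, day: float) -> float:
    """Convert ``day`` to generations using the grid's per-day rate."""
    return grid.generations(day)


@dataclass(frozen=True)
class MutationRecord:
    """One mutation's sampled frequency time series in one host.

    ``frequencies`` maps sampling day -> allele frequency in [0, 1].  A day
    absent from the mapping was not sampled for this mutation; a day present
    with value 0 was sampled but the mutation was below the detection floor.
    """

    mutation_id: str
    host_id: str
    target: str
    func_class: str
    frequencies: Mapping[float, float]

    def __post_init__(self) -> None:
        if self.func_class not in FUNC_CLASSES:
            raise ValueError(
                f"unknown func_class {self.func_class!r}; expected one of {sorted(FUNC_CLASSES)}"
            )
        freqs = {float(d): float(f) for d, f in self.frequencies.items()}
        for d, f in freqs.items():
            if not (0.0 <= f <= 1.0) or math.isnan(f):
                raise ValueError(
                    f"frequency {f} at day {d} of {self.mutation_id} outside [0, 1]"
                )
        object.__setattr__(self, "frequencies", freqs)

    def series(self, grid: TimeGrid) -> tuple[np.ndarray, np.ndarray]:
        """Return (days, frequencies) on the host grid, absent days as 0."""
        days = np.asarray(grid.days, dtype=float)
        freqs = np.array([self.frequencies.get(d, 0.0) for d in days])
        return days, freqs

    @property
    def max_frequency(self) -> float:
        """Maximum sampled frequency (the piecewise-linear max is at a node)."""
        return max(self.frequencies.values(), default=0.0)


@dataclass
class TrajectorySet:
    """All mutation trajectories of one host plus the time grid and metadata."""

    host_id: str
    grid: TimeGrid
    records: list[MutationRecord] = field(default_factory=list)
    detection_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.detection_threshold < 1.0):
            raise ValueError("detection_threshold must be in [0, 1)")
        seen: set[str] = set()
        grid_days = set(self.grid.days)
        for rec in self.records:
            if rec.host_id != self.host_id:
                raise ValueError(
                    f"record {rec.mutation_id} has host {rec.host_id!r}, set is {self.host_id!r}"
                )
            if rec.mutation_id in seen:
                raise ValueError(f"duplicate mutation_id {rec.mutation_id!r}")
            seen.add(rec.mutation_id)
            extra = set(rec.frequencies) - grid_days
            if extra:
                raise ValueError(
                    f"record {rec.mutation_id} has days {sorted(extra)} outside the grid"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def record(self, mutation_id: str) -> MutationRecord:
        for rec in self.records:
            if rec.mutation_id == mutation_id:
                return rec
        raise KeyError(mutation_id)

    def to_frame(self, sparse: bool = False) -> pd.DataFrame:
        """Long-format DataFrame of the set.

        With ``sparse=True`` zero-frequency rows are omitted (they are implied
        by the grid); otherwise every (mutation, grid day) pair is written.
        """
        rows = []
        for rec in self.records:
            for day in self.grid.days:
                f = rec.frequencies.get(day)
                if f is None:
                    if sparse:
                        continue
                    f = 0.0
                elif sparse and f == 0.0:
                    continue
                rows.append(
                    (self.host_id, rec.mutation_id, rec.target, rec.func_class, day, f)
                )
        return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)


@dataclass(frozen=True)
class ODSeries:
    """An optical-density (OD600) time series in hours."""

    times: tuple[float, ...]
    od: tuple[float, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        od = tuple(float(v) for v in self.od)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "od", od)
        if len(times) != len(od):
            raise ValueError("times and od must have equal length")
        if len(times) < 3:
            raise ValueError("ODSeries needs at least 3 points")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        if any(v <= 0 for v in od):
            raise ValueError("od values must be positive (logarithms are taken)")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _validate_frame(df: pd.DataFrame, path) -> None:
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"{path}: missing columns {missing}")
    for col, line in zip(df["frequency"], df.index):
        try:
            v = float(col)
        except (TypeError, ValueError):
            raise TrajectoryFormatError(
                f"{path}: line {line + 2}: unparseable frequency {col!r}"
            ) from None
        if not (0.0 <= v <= 1.0):
            raise TrajectoryFormatError(
                f"{path}: line {line + 2}: frequency {v} outside [0, 1]"
            )
    dup = df.duplicated(subset=["host", "mutation_id", "day"])
    if dup.any():
        first = df[dup].iloc[0]
        raise TrajectoryFormatError(
            f"{path}: duplicate (host, mutation_id, day) = "
            f"({first['host']}, {first['mutation_id']}, {first['day']})"
        )


def read_trajectories(
    path,
    detection_threshold: float = 0.05,
    generations_per_day: float = 15.0,
) -> dict[str, TrajectorySet]:
    """Read a long-format trajectory TSV into one :class:`TrajectorySet` per host.

    Each host's grid is the sorted set of days appearing for any of its
    mutations; grid days absent for a mutation are filled with 0 (sampled,
    below detection).
    """
    try:
        df = pd.read_csv(
            path, sep="\t", dtype={"host": str, "mutation_id": str},
            float_precision="round_trip",
        )
    except pd.errors.ParserError as exc:
        raise TrajectoryFormatError(f"{path}: {exc}") from exc
    _validate_frame(df, path)
    df["day"] = df["day"].astype(float)
    df["frequency"] = df["frequency"].astype(float)

    out: dict[str, TrajectorySet] = {}
    for host, sub in df.groupby("host", sort=True):
        grid = TimeGrid(tuple(sorted(sub["day"].unique())), generations_per_day)
        records = []
        for mid, traj in sub.groupby("mutation_id", sort=True):
            freqs = dict.fromkeys(grid.days, 0.0)
            freqs.update(zip(traj["day"], traj["frequency"]))
            records.append(
                MutationRecord(
                    mutation_id=str(mid),
                    host_id=str(host),
                    target=str(traj["target"].iloc[0]),
                    func_class=str(traj["func_class"].iloc[0]),
                    frequencies=freqs,
                )
            )
        out[str(host)] = TrajectorySet(
            host_id=str(host),
            grid=grid,
            records=records,
            detection_threshold=detection_threshold,
        )
    return out


def write_trajectories(
    sets: TrajectorySet | Iterable[TrajectorySet], path, sparse: bool = False
) -> None:
    """Write one or more TrajectorySets as the canonical long-format TSV.

    ``read_trajectories(write_trajectories(S))`` reproduces ``S`` up to row
    order under both dialects (explicit zeros, or the sparse dialect omitting
    them) as long as each mutation has at least one detected point.
    """
    if isinstance(sets, TrajectorySet):
        sets = [sets]
    frames = [s.to_frame(sparse=sparse) for s in sets]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    )
    # repr round-trips doubles exactly and keeps short decimals short
    for col in ("day", "frequency"):
        df[col] = df[col].map(repr)
    df.to_csv(path, sep="\t", index=False)


def pool_sets(sets: Sequence[TrajectorySet], host_id: str = "pooled") -> TrajectorySet:
    """Pool replicate hosts sharing one time grid into a single set.

    Mutation ids are prefixed with their host of origin so that trajectories
    from different hosts stay distinct.  All sets must share the same grid
    and detection threshold.
    """
    if not sets:
        raise ValueError("nothing to pool")
    grid = sets[0].grid
    thr = sets[0].detection_threshold
    records = []
    for s in sets:
        if s.grid != grid:
            raise ValueError(f"host {s.host_id}: grid differs from {sets[0].host_id}")
        if s.detection_threshold != thr:
            raise ValueError(f"host {s.host_id}: detection threshold differs")
        for rec in s.records:
            records.append(
                MutationRecord(
                    mutation_id=f"{s.host_id}:{rec.mutation_id}",
                    host_id=host_id,
                    target=rec.target,
                    func_class=rec.func_class,
                    frequencies=rec.frequencies,
                )
            )
    return TrajectorySet(
        host_id=host_id, grid=grid, records=records, detection_threshold=thr
    )


def read_od_series(path) -> ODSeries:
    """Read a two-column ``time_h  od600`` TSV."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if len(cols) < 2:
        raise TrajectoryFormatError(f"{path}: expected two columns time_h, od600")
    return ODSeries(tuple(df[cols[0]].astype(float)), tuple(df[cols[1]].astype(float)))


def write_od_series(series: ODSeries, path) -> None:
    pd.DataFrame({"time_h": series.times, "od600": series.od}).to_csv(
        path, sep="\t", index=False
    )
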