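"""Sweep calling and aggregate molecular-evolution statistics.

A *selective sweep* is a mutation (or HGT event) whose trajectory reached
>95% population frequency and kept high frequency until the end of the
observation.  Alongside sweep calling this module computes the mutation
accumulation statistic M(t) (sum of allele frequencies at each sampling
point) and its per-generation rate, the dN/dS count ratio, cross-host
parallelism of mutational targets, the intergenic fraction, and the
hypothesis tests used to compare sweep rates between host groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .ptau import _crossing
from .trajectory_io import TrajectorySet

__all__ = [
    "SweepCall",
    "AccumulationSeries",
    "DnDsSummary",
    "ParallelismTable",
    "SweepRateTests",
    "detect_sweeps",
    "mutation_accumulation",
    "dn_ds",
    "parallelism",
    "intergenic_fraction",
    "sweep_rate_tests",
]


@dataclass(frozen=True)
class SweepCall:
    mutation_id: str
    first_day_above: float  # interpolated day of the threshold crossing
    maintained: bool = True


@dataclass(frozen=True)
class AccumulationSeries:
    days: tuple[float, ...]
    M: tuple[float, ...]
    rate: float  # per genome per generation; NaN with < 2 sampled days
    rate_se: float


@dataclass(frozen=True)
class DnDsSummary:
    dN: int
    dS: int

    @property
    def ratio(self) -> float | None:
        return self.dN / self.dS if self.dS > 0 else None


@dataclass(frozen=True)
class ParallelismTable:
    """Targets ordered by the number of hosts in which they mutated."""

    hosts_by_target: tuple[tuple[str, frozenset[str]], ...]

    def count(self, target: str) -> int:
        for t, hosts in self.hosts_by_target:
            if t == target:
                return len(hosts)
        return 0


@dataclass(frozen=True)
class SweepRateTests:
    t_stat: float
    df: float
    p_one_sided: float  # H1: first group has the higher mean sweep rate
    spearman_rho: float | None
    spearman_p: float | None


def detect_sweeps(
    set_: TrajectorySet,
    threshold: float = 0.95,
    maintain_floor: float | None = None,
    strict: bool = False,
) -> list[SweepCall]:
    """Call selective sweeps: trajectories exceeding ``threshold`` and
    maintained at high frequency until the end of observation.

    ``maintain_floor`` (default: the threshold itself) is the level every
    sampled point after the first crossing must stay at or above; with
    ``strict=True`` points must stay strictly above ``threshold``.
    """
    floor = threshold if maintain_floor is None else maintain_floor
    calls: list[SweepCall] = []
    for rec in set_.records:
        days = np.array(sorted(rec.frequencies))
        freqs = np.array([rec.frequencies[d] for d in days])
        above = np.nonzero(freqs > threshold)[0]
        if above.size == 0:
            continue
        i = int(above[0])
        cross = (
            days[0]
            if i == 0
            else _crossing(days[i - 1], freqs[i - 1], days[i], freqs[i], threshold)
        )
        later = freqs[days >= cross]
        maintained = bool(
            np.all(later > threshold) if strict else np.all(later >= floor)
        )
        if maintained:
            calls.append(SweepCall(rec.mutation_id, float(cross), True))
    return calls


def mutation_accumulation(set_: TrajectorySet) -> AccumulationSeries:
    """M(t) = sum of allele frequencies over all mutations at each sampled day,
    and its least-squares rate per generation (free intercept, since the
    first sample may postdate colonization)."""
    days = np.asarray(set_.grid.days)
    M = np.zeros_like(days, dtype=float)
    for rec in set_.records:
        M += np.array([rec.frequencies.get(d, 0.0) for d in days])
    if len(days) >= 2:
        gens = days * set_.grid.generations_per_day
        fit = stats.linregress(gens, M)
        rate, rate_se = float(fit.slope), float(fit.stderr)
    else:
        rate, rate_se = math.nan, math.nan
    return AccumulationSeries(tuple(days), tuple(M), rate, rate_se)


def dn_ds(set_: TrajectorySet) -> DnDsSummary:
    """Raw counts of nonsynonymous and synonymous mutations.

    The ratio is a count ratio (not per-site normalized, which would need the
    reference annotation); undefined when dS = 0.
    """
    dN = sum(1 for r in set_.records if r.func_class == "nonsynonymous")
    dS = sum(1 for r in set_.records if r.func_class == "synonymous")
    return DnDsSummary(dN, dS)


def parallelism(sets: Iterable[TrajectorySet]) -> ParallelismTable:
    """Per mutational target, the set of hosts in which it mutated,
    ordered by host count descending (ties broken alphabetically)."""
    table: dict[str, set[str]] = {}
    for s in sets:
        for rec in s.records:
            table.setdefault(rec.target, set()).add(s.host_id)
    ordered = sorted(table.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return ParallelismTable(tuple((t, frozenset(h)) for t, h in ordered))


def intergenic_fraction(
    sets: Iterable[TrajectorySet],
) -> tuple[int, int, float]:
    """(intergenic count, total count, fraction) across all hosts."""
    n_inter = total = 0
    for s in sets:
        for rec in s.records:
            total += 1
            n_inter += rec.func_class == "intergenic"
    return n_inter, total, (n_inter / total if total else 0.0)


def sweep_rate_tests(
    group_with: Sequence[float],
    group_without: Sequence[float],
    sweep_rates: Sequence[float] | None = None,
    pop_sizes: Sequence[float] | None = None,
) -> SweepRateTests:
    """Welch one-sided comparison of per-host sweep rates between two groups
    (H1: the first group sweeps faster) and, optionally, the Spearman rank
    correlation between sweep rate and mean population size across hosts."""
    if len(group_with) < 2 or len(group_without) < 2:
        raise ValueError("each group needs at least 2 hosts")
    res = stats.ttest_ind(
        group_with, group_without, equal_var=False, alternative="greater"
    )
    a, b = np.asarray(group_with, float), np.asarray(group_without, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    if va + vb > 0:
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    else:
        df = float(len(a) + len(b) - 2)
    rho = p_rho = None
    if sweep_rates is not None and pop_sizes is not None:
        sp = stats.spearmanr(sweep_rates, pop_sizes)
        rho, p_rho = float(sp.statistic), float(sp.pvalue)
    t = float(res.statistic)
    p = 0.5 if math.isnan(t) else float(res.pvalue)
    return SweepRateTests(0.0 if math.isnan(t) else t, float(df), p, rho, p_rho)
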