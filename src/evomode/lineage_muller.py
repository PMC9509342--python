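"""Nesting of mutations into clonal lineages and Muller-plot tables.

In an asexual population a mutation arising on the background of a
pre-existing mutation can never exceed the frequency of that pre-existing
mutation, and the two fluctuate together.  :func:`assign_lineages` turns
this observation into a deterministic greedy rule that nests mutation
trajectories into a forest of clonal lineages; :func:`muller_table` converts
the forest into the exclusive per-day abundances that stacked-area (Muller)
plots consume.

Low-frequency mutations cannot be placed with confidence; they are attached
to the root and flagged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ptau import origination_time
from .trajectory_io import MutationRecord, TrajectorySet

__all__ = ["LineageForest", "LineageInconsistencyError", "assign_lineages", "muller_table"]

ROOT = "__root__"


class LineageInconsistencyError(ValueError):
    """A forest's frequencies violate the nesting invariant beyond tolerance."""


@dataclass
class LineageForest:
    """Parent links of mutations (root = ancestral background) plus per-day
    lineage frequencies.  ``low_confidence`` flags mutations that could not
    be nested and were attached to the root by default."""

    parent: dict[str, str]  # mutation_id -> parent mutation_id or ROOT
    frequencies: dict[str, dict[float, float]]  # lineage freq per sampled day
    days: tuple[float, ...]
    low_confidence: frozenset[str] = frozenset()
    eps: float = 0.05

    def children(self, node: str) -> list[str]:
        return [m for m, p in self.parent.items() if p == node]

    def depth(self, node: str) -> int:
        d = 0
        while node != ROOT:
            node = self.parent[node]
            d += 1
        return d


def _pearson_positive(f1: np.ndarray, f2: np.ndarray) -> bool:
    """Do two trajectories 'fluctuate together'? Pearson r > 0 over shared
    detected days; degenerate (constant / < 2 shared points) counts as
    compatible, since co-fluctuation cannot be rejected."""
    mask = (f1 > 0) & (f2 > 0)
    if mask.sum() < 2:
        return True
    a, b = f1[mask], f2[mask]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return True
    return float(np.corrcoef(a, b)[0, 1]) > 0.0


def assign_lineages(set_: TrajectorySet, eps: float = 0.05) -> LineageForest:
    """Greedy nesting of mutations into clonal lineages.

    Mutations are processed in descending order of maximum frequency
    (tie-break: earlier origination, then mutation id).  Each is attached to
    the deepest already-placed mutation that dominates it (candidate child
    frequency <= parent frequency + eps at every sampled day) and with which
    it is positively correlated; otherwise it becomes a direct child of the
    root.  Mutations that never exceed eps are flagged low-confidence: below
    that scale the dominance test cannot discriminate between parents.
    """
    days = np.asarray(set_.grid.days)

    def freqs(rec: MutationRecord) -> np.ndarray:
        return np.array([rec.frequencies.get(d, 0.0) for d in days])

    def order_key(rec: MutationRecord):
        orig = origination_time(rec, set_.grid, x0=min(0.01, eps))
        return (-rec.max_frequency, math.inf if orig is None else orig, rec.mutation_id)

    ordered = sorted(set_.records, key=order_key)
    parent: dict[str, str] = {}
    series: dict[str, np.ndarray] = {}
    low_conf: set[str] = set()

    for rec in ordered:
        f = freqs(rec)
        candidates = []
        for placed_id, pf in series.items():
            if np.all(f <= pf + eps) and _pearson_positive(f, pf):
                candidates.append(placed_id)
        if candidates:
            depth = {
                m: _chain_depth(parent, m) for m in candidates
            }
            best = max(
                candidates,
                key=lambda m: (depth[m], series[m].max(), m),
            )
            parent[rec.mutation_id] = best
        else:
            parent[rec.mutation_id] = ROOT
        # below eps the dominance test cannot discriminate parents at all
        if rec.max_frequency < eps:
            low_conf.add(rec.mutation_id)
        series[rec.mutation_id] = f

    frequencies = {
        m: dict(zip(map(float, days), map(float, series[m]))) for m in series
    }
    frequencies[ROOT] = {float(d): 1.0 for d in days}
    return LineageForest(
        parent=parent,
        frequencies=frequencies,
        days=tuple(map(float, days)),
        low_confidence=frozenset(low_conf),
        eps=eps,
    )


def _chain_depth(parent: dict[str, str], node: str) -> int:
    d = 0
    while node != ROOT:
        node = parent[node]
        d += 1
    return d


def muller_table(forest: LineageForest, set_: TrajectorySet | None = None) -> pd.DataFrame:
    """Long-format (day, lineage, abundance) table of exclusive abundances.

    A node's exclusive abundance is its lineage frequency minus the sum of
    its children's; the root row carries the unmutated background.  A child
    exceeding its parent's frequency by more than eps violates the nesting
    invariant and raises :class:`LineageInconsistencyError`.  Negative
    exclusive abundances (sibling frequencies over-counting because of
    pool-seq noise or greedy mis-placement of co-segregating clades) are
    clipped to 0 with a warning and each day is renormalized to sum to 1.
    """
    nodes = [ROOT] + [m for m in forest.parent]
    rows = []
    for day in forest.days:
        excl = {}
        for node in nodes:
            f = forest.frequencies[node][day]
            children = forest.children(node)
            for c in children:
                fc = forest.frequencies[c][day]
                if fc > f + forest.eps + 1e-12:
                    raise LineageInconsistencyError(
                        f"day {day}: child {c!r} at {fc:.4f} exceeds its "
                        f"parent {node!r} at {f:.4f} beyond eps={forest.eps}"
                    )
            e = f - sum(forest.frequencies[c][day] for c in children)
            if e < -1e-12:
                warnings.warn(
                    f"day {day}: clipping negative exclusive abundance "
                    f"{e:.4f} of {node!r} to 0",
                    stacklevel=2,
                )
            excl[node] = max(e, 0.0)
        total = sum(excl.values())
        for node in nodes:
            rows.append((day, node, excl[node] / total if total > 0 else 0.0))
    return pd.DataFrame(rows, columns=["day", "lineage", "abundance"])
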