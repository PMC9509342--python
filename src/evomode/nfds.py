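"""Detection of negative frequency-dependent selection (NFDS) from trajectories.

A mutation under NFDS (rare-type advantage) rises when rare and falls when
common, so its frequency and its subsequent change in frequency are
negatively correlated.  :func:`freq_change_correlation` computes the Pearson
correlation between x_t and Delta x_t = x_{t+1} - x_t over consecutive
detected samples, for trajectories detected at four or more time points.
:func:`rare_advantage` estimates the selective advantage while rare from the
logit-linear slope of the trajectory in the low-frequency range (under a
constant advantage s, logit(x) grows linearly at rate s per generation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trajectory_io import MutationRecord, TimeGrid

__all__ = ["NfdsResult", "freq_change_correlation", "rare_advantage"]


@dataclass(frozen=True)
class NfdsResult:
    mutation_id: str
    n_pairs: int
    r: float  # NaN when the trajectory does not qualify
    p_value: float
    qualifies: bool


def _detected(record: MutationRecord) -> tuple[np.ndarray, np.ndarray]:
    """(days, frequencies) restricted to detected (> 0) samples.

    A reported 0 is a censored below-detection value, not a measurement, so
    zeros break consecutive-pair formation rather than entering it.
    """
    days = np.array(sorted(record.frequencies))
    freqs = np.array([record.frequencies[d] for d in days])
    mask = freqs > 0
    return days[mask], freqs[mask]


def freq_change_correlation(
    record: MutationRecord,
    grid: TimeGrid | None = None,
    min_points: int = 4,
    per_generation: bool = False,
) -> NfdsResult:
    """Pearson correlation between frequency and subsequent frequency change.

    Pairs (x_t, Delta x_t) are formed over consecutive detected samples; a
    significantly negative r indicates rare-type advantage.  With
    ``per_generation=True`` the change is divided by the elapsed generations
    (requires ``grid``), compensating uneven sampling.  Trajectories with
    fewer than ``min_points`` detected time points do not qualify.
    """
    days, freqs = _detected(record)
    n = len(freqs)
    if n < min_points:
        return NfdsResult(record.mutation_id, max(n - 1, 0), math.nan, math.nan, False)
    dx = np.diff(freqs)
    if per_generation:
        if grid is None:
            raise ValueError("per_generation=True requires the TimeGrid")
        dx = dx / (np.diff(days) * grid.generations_per_day)
    x = freqs[:-1]
    if np.ptp(x) == 0 or np.ptp(dx) == 0:
        # degenerate pairs: correlation undefined
        return NfdsResult(record.mutation_id, n - 1, math.nan, math.nan, True)
    res = stats.pearsonr(x, dx)
    return NfdsResult(
        record.mutation_id, n - 1, float(res.statistic), float(res.pvalue), True
    )


def rare_advantage(
    record: MutationRecord, grid: TimeGrid, rare_max: float = 0.1
) -> float:
    """Per-generation selective advantage while rare.

    Least-squares slope of logit(x) against generations over the detected
    samples with frequency in (0, rare_max].  Positive values mean the
    mutation gains when rare; for a logistic trajectory the slope equals the
    selection coefficient.
    """
    days, freqs = _detected(record)
    mask = freqs <= rare_max
    days, freqs = days[mask], freqs[mask]
    if len(freqs) < 2:
        raise ValueError(
            f"{record.mutation_id}: fewer than 2 detected samples at or below {rare_max}"
        )
    gens = days * grid.generations_per_day
    logit = np.log(freqs / (1.0 - freqs))
    return float(stats.linregress(gens, logit).slope)
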