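"""Shared fixtures: hand-built trajectory sets and synthetic logistic paths."""

from __future__ import annotations

import math

import numpy as np
import pytest

from evomode import MutationRecord, TimeGrid, TrajectorySet


def make_record(
    days,
    freqs,
    mutation_id="m1",
    host_id="h1",
    target="geneA",
    func_class="nonsynonymous",
):
    return MutationRecord(
        mutation_id=mutation_id,
        host_id=host_id,
        target=target,
        func_class=func_class,
        frequencies=dict(zip(days, freqs)),
    )


def make_set(trajs, days, host_id="h1", generations_per_day=1.0, **kw):
    """Build a TrajectorySet from {mutation_id: [frequencies]} on shared days."""
    records = [
        make_record(days, freqs, mutation_id=mid, host_id=host_id)
        for mid, freqs in trajs.items()
    ]
    return TrajectorySet(
        host_id=host_id,
        grid=TimeGrid(tuple(days), generations_per_day),
        records=records,
        **kw,
    )


def logistic(t, s, x0=0.01):
    """Deterministic logistic frequency path crossing x0 at t=0."""
    l0 = math.log(x0 / (1.0 - x0))
    return 1.0 / (1.0 + np.exp(-(l0 + s * np.asarray(t, dtype=float))))


@pytest.fixture
def five_trajectories():
    """Five established trajectories with maxima 0.05/0.25/0.40/0.97/0.99.

    G(0.3) = 3/5 and G(0.95) = 2/5 by enumeration.
    """
    days = [0.0, 100.0, 200.0, 300.0]
    return make_set(
        {
            "a": [0.0, 0.05, 0.02, 0.0],
            "b": [0.0, 0.10, 0.25, 0.20],
            "c": [0.0, 0.20, 0.40, 0.35],
            "d": [0.0, 0.30, 0.80, 0.97],
            "e": [0.02, 0.50, 0.95, 0.99],
        },
        days,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20231107)
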