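"""Wright-Fisher simulators generating synthetic trajectory data.

Two generators produce :class:`~evomode.trajectory_io.TrajectorySet` data with
the statistical structure of the three selection modes:

* :func:`simulate_directional` -- an asexual Wright-Fisher population with
  beneficial mutations arising at rate ``U`` per genome per generation.  With
  a small mutational input (N*U*s << 1) sweeps proceed one at a time
  (periodic sweeps); with a large input many beneficial clades compete
  (clonal interference).

* :func:`simulate_resource_competition` -- a consumer-resource Wright-Fisher
  model: each genotype allocates its uptake over R substitutable resources
  and the marginal value of a resource is inversely proportional to its total
  consumption.  Rare types feeding on underused resources gain an advantage,
  generating negative frequency-dependent selection and stable ecotypes that
  suppress fixation (diversifying selection).

Both report per-mutation population frequencies (summed over the genotypes
carrying the mutation, so hitchhiking arises naturally) and push them through
a pool-seq observation layer: sampling at scheduled days, binomial read-depth
noise, and a detection floor below which frequencies are reported as 0.

Populations are simulated at desk scale (N ~ 1e3-1e5, up to ~1e4
generations); larger natural populations are emulated by scaling s and U,
since the regime is set by the products N*U and N*s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .trajectory_io import MutationRecord, TimeGrid, TrajectorySet

__all__ = [
    "WFParams",
    "ResourceParams",
    "SamplingScheme",
    "SimulationTruth",
    "simulate_directional",
    "simulate_resource_competition",
    "subsample",
]


@dataclass(frozen=True)
class WFParams:
    """Parameters of the directional-selection Wright-Fisher model.

    ``s_dist`` selects the distribution of selection coefficients of new
    beneficial mutations: ``"fixed"`` (all equal to ``s``) or
    ``"exponential"`` (mean ``s``).  ``init_mutants`` seeds mutant lineages
    at generation 0 as (copy number, selection coefficient) pairs, mainly for
    calibration against diffusion theory.
    """

    N: int = 100_000
    U: float = 0.0
    s: float = 0.05
    s_dist: Literal["fixed", "exponential"] = "fixed"
    T_gen: int = 8000
    seed: int = 0
    init_mutants: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        if self.N < 10:
            raise ValueError("N must be >= 10")
        if self.U < 0:
            raise ValueError("U must be non-negative")
        if self.s <= -1:
            raise ValueError("s must exceed -1")
        if self.T_gen < 1:
            raise ValueError("T_gen must be positive")
        if self.s_dist not in ("fixed", "exponential"):
            raise ValueError("s_dist must be 'fixed' or 'exponential'")


@dataclass(frozen=True)
class ResourceParams:
    """Parameters of the consumer-resource (ecotype) model.

    Genotype fitness is w_g = sum_r supply_r * alpha_gr / c_r with
    c_r = sum_h x_h * alpha_hr the total consumption of resource r; mean
    fitness is always sum_r supply_r.  Mutations perturb the allocation
    vector by a truncated Gaussian of scale ``alloc_mut_sd`` and renormalize.

    ``ancestor_alloc`` is the founding genotype's allocation.  The default is
    skewed away from the supply profile, modelling an invader arriving
    maladapted to the resource spectrum of a new environment: mutants
    feeding on the underused resource then rise quickly to an intermediate
    frequency where resource competition balances, and ecotypes form
    reliably.  A supply-matched ancestor makes specialist invasion
    selectively neutral, leaving ecotype formation drift-limited.
    """

    R: int = 2
    supply: tuple[float, ...] = (0.5, 0.5)
    ancestor_alloc: tuple[float, ...] = (0.7, 0.3)
    alloc_mut_sd: float = 0.5
    mu_eco: float = 5e-5
    N: int = 10_000
    T_gen: int = 8000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if len(self.supply) != self.R:
            raise ValueError("supply must have R entries")
        if any(s <= 0 for s in self.supply):
            raise ValueError("supply must be positive")
        if len(self.ancestor_alloc) != self.R:
            raise ValueError("ancestor_alloc must have R entries")
        if any(a < 0 for a in self.ancestor_alloc) or sum(self.ancestor_alloc) <= 0:
            raise ValueError("ancestor_alloc must be non-negative with positive sum")
        if self.alloc_mut_sd <= 0:
            raise ValueError("alloc_mut_sd must be positive")
        if self.mu_eco < 0:
            raise ValueError("mu_eco must be non-negative")
        if self.N < 10:
            raise ValueError("N must be >= 10")


@dataclass(frozen=True)
class SamplingScheme:
    """Pool-seq observation scheme: when, how deep, and the detection floor.

    The defaults emulate ~300x alignment depth and the 5% retention floor of
    pooled population sequencing.
    """

    sample_days: tuple[float, ...]
    depth: int = 300
    detection_threshold: float = 0.05
    generations_per_day: float = 15.0

    def __post_init__(self) -> None:
        if len(self.sample_days) == 0:
            raise ValueError("sample_days must be non-empty")
        if any(b <= a for a, b in zip(self.sample_days, self.sample_days[1:])):
            raise ValueError("sample_days must be strictly increasing")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not (0.0 <= self.detection_threshold < 1.0):
            raise ValueError("detection_threshold must be in [0, 1)")

    def sample_generations(self) -> np.ndarray:
        return np.asarray(self.sample_days) * self.generations_per_day


@dataclass
class SimulationTruth:
    """Ground truth accompanying a simulated observation.

    ``dense`` holds noise-free frequencies at the sampled days; ``final_freq``
    the exact frequency of each mutation at the last simulated generation
    (1.0 = fixed); ``parent`` maps each mutation to the most recent mutation
    on its founding background (None = founded on the ancestor); ``s_coef``
    and ``origin_gen`` record each mutation's effect and birth generation.
    """

    dense: TrajectorySet
    final_freq: dict[str, float]
    parent: dict[str, str | None]
    s_coef: dict[str, float]
    origin_gen: dict[str, int]

    @property
    def fixed_mutations(self) -> set[str]:
        return {m for m, f in self.final_freq.items() if f >= 1.0}


# ---------------------------------------------------------------------------
# observation layer
# ---------------------------------------------------------------------------

def subsample(
    truth: TrajectorySet, scheme: SamplingScheme, seed: int
) -> TrajectorySet:
    """Apply pool-seq observation noise to a dense (noise-free) TrajectorySet.

    Each requested day must exist in the truth grid.  Reported frequency is
    Binomial(depth, x)/depth, zeroed below the detection threshold.
    Deterministic given ``seed``.
    """
    truth_days = set(truth.grid.days)
    missing = [d for d in scheme.sample_days if d not in truth_days]
    if missing:
        raise ValueError(f"sample days {missing} absent from the truth grid")
    rng = np.random.default_rng(seed)
    grid = TimeGrid(tuple(scheme.sample_days), scheme.generations_per_day)
    records = []
    for rec in truth.records:
        freqs = {}
        for day in scheme.sample_days:
            x = rec.frequencies.get(day, 0.0)
            obs = rng.binomial(scheme.depth, x) / scheme.depth
            freqs[day] = obs if obs >= scheme.detection_threshold else 0.0
        records.append(
            MutationRecord(
                mutation_id=rec.mutation_id,
                host_id=rec.host_id,
                target=rec.target,
                func_class=rec.func_class,
                frequencies=freqs,
            )
        )
    return TrajectorySet(
        host_id=truth.host_id,
        grid=grid,
        records=records,
        detection_threshold=scheme.detection_threshold,
    )


def _drop_undetected(set_: TrajectorySet) -> TrajectorySet:
    """Mimic variant-call retention: keep mutations detected at >=1 time point."""
    kept = [r for r in set_.records if r.max_frequency > 0.0]
    return TrajectorySet(
        host_id=set_.host_id,
        grid=set_.grid,
        records=kept,
        detection_threshold=set_.detection_threshold,
    )


def _build_truth(
    host_id: str,
    scheme: SamplingScheme,
    snapshots: dict[str, dict[float, float]],
    final_freq: dict[str, float],
    parent: dict[str, str | None],
    s_coef: dict[str, float],
    origin_gen: dict[str, int],
    func_class: str,
) -> SimulationTruth:
    grid = TimeGrid(tuple(scheme.sample_days), scheme.generations_per_day)
    records = [
        MutationRecord(
            mutation_id=mid,
            host_id=host_id,
            target=mid,
            func_class=func_class,
            frequencies={d: snapshots[mid].get(d, 0.0) for d in grid.days},
        )
        for mid in sorted(snapshots)
    ]
    dense = TrajectorySet(host_id=host_id, grid=grid, records=records,
                          detection_threshold=0.0)
    return SimulationTruth(dense, final_freq, parent, s_coef, origin_gen)


# ---------------------------------------------------------------------------
# directional selection (periodic sweeps / clonal interference)
# ---------------------------------------------------------------------------

def simulate_directional(
    params: WFParams,
    scheme: SamplingScheme,
    host_id: str = "sim",
    return_truth: bool = False,
) -> TrajectorySet | tuple[TrajectorySet, SimulationTruth]:
    """Simulate beneficial-mutation dynamics in an asexual WF population.

    Each generation, genotype counts are multinomially resampled with weights
    proportional to count * (1 + s_genotype); Poisson(N*U) new beneficial
    mutations each found a child genotype carrying one extra sampled
    selection coefficient.  Mutation frequencies are summed over carrying
    genotypes and observed through :func:`subsample`.
    """
    sample_gens = scheme.sample_generations()
    if np.any(sample_gens > params.T_gen + 1e-9):
        raise ValueError(
            f"sampling horizon {sample_gens.max():.0f} generations exceeds T_gen={params.T_gen}"
        )
    gen_to_day = {int(round(g)): d for g, d in zip(sample_gens, scheme.sample_days)}

    rng = np.random.default_rng(params.seed)
    N = params.N

    # genotype state: parallel lists
    counts = [N]
    fitness = [1.0]
    muts: list[tuple[int, ...]] = [()]

    mut_s: list[float] = []
    mut_origin: list[int] = []
    mut_parent: list[int | None] = []  # index of background's newest mutation

    def seed_mutant(copies: int, s_val: float, gen: int, parent_geno: int) -> None:
        take = min(copies, counts[parent_geno])
        if take <= 0:
            return
        mid = len(mut_s)
        mut_s.append(s_val)
        mut_origin.append(gen)
        bg = muts[parent_geno]
        mut_parent.append(bg[-1] if bg else None)
        counts[parent_geno] -= take
        counts.append(take)
        fitness.append(fitness[parent_geno] * (1.0 + s_val))
        muts.append(bg + (mid,))

    for copies, s_val in params.init_mutants:
        seed_mutant(copies, s_val, 0, 0)

    snapshots: dict[int, dict[float, float]] = {}

    def record_snapshot(day: float) -> None:
        freq: dict[int, float] = {}
        for c, ms in zip(counts, muts):
            if c == 0:
                continue
            for m in ms:
                freq[m] = freq.get(m, 0.0) + c
        for m, tot in freq.items():
            snapshots.setdefault(m, {})[day] = tot / N

    if 0 in gen_to_day:
        record_snapshot(gen_to_day[0])

    for gen in range(1, params.T_gen + 1):
        arr = np.asarray(counts, dtype=float)
        w = np.asarray(fitness)
        probs = arr * w
        probs /= probs.sum()
        new_counts = rng.multinomial(N, probs)
        # prune extinct genotypes
        keep = np.nonzero(new_counts)[0]
        counts = [int(new_counts[i]) for i in keep]
        fitness = [fitness[i] for i in keep]
        muts = [muts[i] for i in keep]

        n_new = rng.poisson(N * params.U) if params.U > 0 else 0
        if n_new:
            arr = np.asarray(counts, dtype=float)
            parents = rng.choice(len(counts), size=n_new, p=arr / arr.sum())
            for pg in parents:
                s_val = (
                    params.s
                    if params.s_dist == "fixed"
                    else float(rng.exponential(params.s))
                )
                seed_mutant(1, s_val, gen, int(pg))

        if gen in gen_to_day:
            record_snapshot(gen_to_day[gen])

    # final-generation exact frequencies
    final: dict[int, float] = {}
    for c, ms in zip(counts, muts):
        for m in ms:
            final[m] = final.get(m, 0.0) + c / N

    def name(m: int) -> str:
        return f"m{mut_origin[m]:05d}.{m}"

    truth = _build_truth(
        host_id,
        scheme,
        {name(m): days for m, days in snapshots.items()},
        {name(m): final.get(m, 0.0) for m in range(len(mut_s))},
        {name(m): (name(p) if (p := mut_parent[m]) is not None else None)
         for m in range(len(mut_s))},
        {name(m): mut_s[m] for m in range(len(mut_s))},
        {name(m): mut_origin[m] for m in range(len(mut_s))},
        func_class="nonsynonymous",
    )
    observed = _drop_undetected(
        subsample(truth.dense, scheme, seed=int(rng.integers(2**31)))
    )
    return (observed, truth) if return_truth else observed


# ---------------------------------------------------------------------------
# resource competition (diversifying / NFDS)
# ---------------------------------------------------------------------------

def resource_fitness(
    alloc: np.ndarray, x: np.ndarray, supply: np.ndarray
) -> np.ndarray:
    """Consumer-resource fitness of each genotype.

    ``alloc`` is (k, R) with rows summing to 1, ``x`` the genotype frequency
    vector, ``supply`` the resource supply rates.  w_g = sum_r supply_r *
    alpha_gr / c_r with c_r the population consumption of resource r; unused
    resources contribute their full supply to any genotype feeding on them.
    """
    c = alloc.T @ x  # total consumption per resource
    c = np.where(c <= 0, np.inf, c)  # untouched resource: no competition term
    value = supply / c
    return alloc @ value


def simulate_resource_competition(
    params: ResourceParams,
    scheme: SamplingScheme,
    host_id: str = "sim",
    return_truth: bool = False,
    init_alloc: np.ndarray | None = None,
    init_counts: np.ndarray | None = None,
) -> TrajectorySet | tuple[TrajectorySet, SimulationTruth]:
    """Simulate the consumer-resource WF model with allocation mutations.

    Starting from a generalist ancestor whose allocation matches the supply
    profile, mutations perturb resource allocation; negative
    frequency-dependent selection on resource use maintains coexisting
    ecotypes, so mutation trajectories plateau at intermediate frequency
    instead of sweeping.  ``init_alloc``/``init_counts`` override the initial
    genotype composition (rows of ``init_alloc`` must sum to 1).
    """
    sample_gens = scheme.sample_generations()
    if np.any(sample_gens > params.T_gen + 1e-9):
        raise ValueError(
            f"sampling horizon {sample_gens.max():.0f} generations exceeds T_gen={params.T_gen}"
        )
    gen_to_day = {int(round(g)): d for g, d in zip(sample_gens, scheme.sample_days)}

    rng = np.random.default_rng(params.seed)
    N = params.N
    supply = np.asarray(params.supply, dtype=float)

    if init_alloc is None:
        anc = np.asarray(params.ancestor_alloc, dtype=float)
        alloc_rows = [anc / anc.sum()]
        counts = [N]
    else:
        alloc_rows = [np.asarray(a, dtype=float) for a in init_alloc]
        if init_counts is None:
            raise ValueError("init_counts required with init_alloc")
        counts = [int(c) for c in init_counts]
        if sum(counts) != N:
            raise ValueError("init_counts must sum to N")
    muts: list[tuple[int, ...]] = [() for _ in alloc_rows]

    mut_origin: list[int] = []
    mut_parent: list[int | None] = []

    def mutate_alloc(base: np.ndarray) -> np.ndarray:
        while True:
            a = base + rng.normal(0.0, params.alloc_mut_sd, size=params.R)
            a = np.clip(a, 0.0, None)
            tot = a.sum()
            if tot > 0:
                return a / tot

    snapshots: dict[int, dict[float, float]] = {}

    def record_snapshot(day: float) -> None:
        tot = sum(counts)
        freq: dict[int, float] = {}
        for c, ms in zip(counts, muts):
            for m in ms:
                freq[m] = freq.get(m, 0.0) + c
        for m, v in freq.items():
            snapshots.setdefault(m, {})[day] = v / tot

    if 0 in gen_to_day:
        record_snapshot(gen_to_day[0])

    for gen in range(1, params.T_gen + 1):
        arr = np.asarray(counts, dtype=float)
        x = arr / N
        A = np.vstack(alloc_rows)
        w = resource_fitness(A, x, supply)
        probs = x * w
        probs /= probs.sum()
        new_counts = rng.multinomial(N, probs)
        keep = np.nonzero(new_counts)[0]
        counts = [int(new_counts[i]) for i in keep]
        alloc_rows = [alloc_rows[i] for i in keep]
        muts = [muts[i] for i in keep]

        n_new = rng.poisson(N * params.mu_eco) if params.mu_eco > 0 else 0
        if n_new:
            arr = np.asarray(counts, dtype=float)
            parents = rng.choice(len(counts), size=n_new, p=arr / arr.sum())
            for pg in parents:
                pg = int(pg)
                if counts[pg] == 0:
                    continue
                mid = len(mut_origin)
                bg = muts[pg]
                mut_origin.append(gen)
                mut_parent.append(bg[-1] if bg else None)
                counts[pg] -= 1
                counts.append(1)
                alloc_rows.append(mutate_alloc(alloc_rows[pg]))
                muts.append(bg + (mid,))

        if gen in gen_to_day:
            record_snapshot(gen_to_day[gen])

    final: dict[int, float] = {}
    for c, ms in zip(counts, muts):
        for m in ms:
            final[m] = final.get(m, 0.0) + c / N

    def name(m: int) -> str:
        return f"e{mut_origin[m]:05d}.{m}"

    truth = _build_truth(
        host_id,
        scheme,
        {name(m): days for m, days in snapshots.items()},
        {name(m): final.get(m, 0.0) for m in range(len(mut_origin))},
        {name(m): (name(p) if (p := mut_parent[m]) is not None else None)
         for m in range(len(mut_origin))},
        {name(m): math.nan for m in range(len(mut_origin))},
        {name(m): mut_origin[m] for m in range(len(mut_origin))},
        func_class="nonsynonymous",
    )
    observed = _drop_undetected(
        subsample(truth.dense, scheme, seed=int(rng.integers(2**31)))
    )
    return (observed, truth) if return_truth else observed
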