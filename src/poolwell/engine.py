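"""The pool → wells → pool cycle engine.

One cycle consists of (i) an unstructured pool phase of duration
``t_pool`` in which the strains grow exponentially at their
minimal-medium rates, (ii) sampling: each of the ``n_wells`` wells
receives an ecology drawn from the cycle's ecology distribution and a
community of ``inoculum_slots`` slot draws from the pool frequencies
(each slot contributing an equal share of the K/2 inoculum), and (iii)
a structured well phase of duration ``t_wells`` in which every well
grows logistically under its community- and ecology-dependent rates —
or decays at the death rate if the pairing is non-viable.  Final well
densities are pooled, normalized, and seed the next cycle.

A lineage is extinct when the pooled density reaches zero (all wells
dead) or every strain frequency falls below ``extinction_eps``; after
extinction the recorded proportions stay identically zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .core import (
    ALL_STRAINS,
    N_ECOLOGIES,
    STRAINS,
    GrowthModelParams,
    Strain,
    ecology_from_index,
    growth_rate_vector,
    members_mask,
    viable,
)
from .distributions import EcologyDistribution, feedback_distribution
from .dynamics import (
    DEFAULT_DT,
    PoolState,
    clamp_floor,
    integrate_pool,
    integrate_wells_batch,
)

__all__ = [
    "CycleConfig",
    "CycleRecord",
    "RunResult",
    "ConstantSchedule",
    "FeedbackSchedule",
    "sample_ecologies",
    "sample_community",
    "run_well_phase",
    "normalize_to_pool",
    "run_lineage",
]

DistributionSchedule = Callable[[int, np.ndarray], EcologyDistribution]


@dataclass(frozen=True)
class CycleConfig:
    """All run parameters for the cycling process.

    ``inoculum_density`` is the total inoculated density per well; the
    default ``None`` means K/2 (half the carrying capacity), split
    equally over the ``inoculum_slots`` slot draws.
    """

    K: float = 10.0
    n_wells: int = 96
    inoculum_slots: int = 4
    inoculum_density: Optional[float] = None
    inoculum_mode: str = "slots"  # or "multinomial"
    t_wells: float = 20.0
    t_pool: float = 2.0
    d: float = -2.0
    n_cycles: int = 10
    pool_init_total: float = 1.0
    extinction_eps: float = 1e-6
    dt: float = DEFAULT_DT
    nonviable_mode: str = "logistic"  # or "exponential"
    initial_proportions: object = "equal"  # "equal", "random", or 4-vector
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be > 0")
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")
        if self.inoculum_slots < 1:
            raise ValueError("inoculum_slots must be >= 1")
        if self.inoculum_density is not None and self.inoculum_density <= 0:
            raise ValueError("inoculum_density must be > 0")
        if self.inoculum_mode not in ("slots", "multinomial"):
            raise ValueError("inoculum_mode must be 'slots' or 'multinomial'")
        if self.t_wells < 0 or self.t_pool < 0:
            raise ValueError("t_wells and t_pool must be >= 0")
        if self.d >= 0:
            raise ValueError("death rate d must be < 0")
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.nonviable_mode not in ("logistic", "exponential"):
            raise ValueError("nonviable_mode must be 'logistic' or 'exponential'")

    @property
    def total_inoculum(self) -> float:
        return self.K / 2 if self.inoculum_density is None else self.inoculum_density

    def initial_freqs(self, rng: np.random.Generator) -> np.ndarray:
        if isinstance(self.initial_proportions, str):
            if self.initial_proportions == "equal":
                return np.full(4, 0.25)
            if self.initial_proportions == "random":
                return rng.dirichlet(np.ones(4))
            raise ValueError(
                f"unknown initial_proportions {self.initial_proportions!r}"
            )
        p = np.asarray(self.initial_proportions, dtype=float)
        if p.shape != (4,) or (p < 0).any() or abs(p.sum() - 1) > 1e-9:
            raise ValueError("initial_proportions must be a simplex 4-vector")
        return p


@dataclass
class CycleRecord:
    """Per-cycle bookkeeping of one lineage."""

    cycle: int
    strain_proportions: np.ndarray  # after the pool phase
    death_rate: float  # fraction of non-viable wells in the well phase
    ecology_histogram: np.ndarray  # counts over the 16 indices


@dataclass
class RunResult:
    """One lineage: a sequence of cycle records plus extinction status."""

    records: list[CycleRecord]
    extinct: bool
    extinction_cycle: Optional[int]
    config: CycleConfig

    def proportions_matrix(self) -> np.ndarray:
        return np.vstack([r.strain_proportions for r in self.records])

    def death_rates(self) -> np.ndarray:
        return np.array([r.death_rate for r in self.records])

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for r in self.records:
            row = {"cycle": r.cycle, "death_rate": r.death_rate}
            for s in STRAINS:
                row[f"prop_{s.name}"] = r.strain_proportions[int(s)]
            rows.append(row)
        df = pd.DataFrame(rows)
        df["extinct"] = self.extinct
        return df


class ConstantSchedule:
    """The same ecology distribution every cycle."""

    def __init__(self, dist: EcologyDistribution):
        self.dist = dist

    def __call__(self, cycle: int, pool_freqs: np.ndarray) -> EcologyDistribution:
        return self.dist


class FeedbackSchedule:
    """Metabolic feedback switching on at ``start_cycle``.

    Before ``start_cycle`` the base distribution is used; from it on,
    the ecology distribution is derived from the current post-pool
    strain frequencies (the strains shape their own niche).
    """

    def __init__(
        self,
        base: EcologyDistribution,
        start_cycle: int = 1,
        scaling: str = "identity",
    ):
        self.base = base
        self.start_cycle = int(start_cycle)
        self.scaling = scaling

    def __call__(self, cycle: int, pool_freqs: np.ndarray) -> EcologyDistribution:
        if cycle >= self.start_cycle and pool_freqs.sum() > 0:
            return feedback_distribution(pool_freqs, scaling=self.scaling)
        return self.base


# ---------------------------------------------------------------------------
# rate/viability lookup tables: 16 ecologies x 16 memberships


def _membership_from_bits(bits: int) -> frozenset[Strain]:
    # bit 3 (MSB) = ADE, matching the 4-char mask string convention
    return frozenset(s for s in STRAINS if bits & (1 << (3 - int(s))))


def build_rate_tables(
    params: GrowthModelParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Precompute rate vectors and viability for every (ecology, membership).

    Returns ``(rates, viab)`` with shapes (16, 16, 4) and (16, 16); the
    membership axis is indexed by the integer value of the 4-bit
    membership mask (ADE as MSB).
    """
    rates = np.zeros((N_ECOLOGIES, 16, 4))
    viab = np.zeros((N_ECOLOGIES, 16), dtype=bool)
    for ei in range(1, N_ECOLOGIES + 1):
        eco = ecology_from_index(ei)
        for bits in range(16):
            members = _membership_from_bits(bits)
            if not members:
                continue
            viab[ei - 1, bits] = viable(eco, members)
            rates[ei - 1, bits] = growth_rate_vector(eco, members, params)
    return rates, viab


_tables_cache: dict[int, tuple[GrowthModelParams, tuple[np.ndarray, np.ndarray]]] = {}


def _cached_tables(params: GrowthModelParams) -> tuple[np.ndarray, np.ndarray]:
    key = id(params)
    hit = _tables_cache.get(key)
    if hit is not None and hit[0] is params:
        return hit[1]
    tables = build_rate_tables(params)
    if len(_tables_cache) > 64:
        _tables_cache.clear()
    _tables_cache[key] = (params, tables)
    return tables


# ---------------------------------------------------------------------------
# sampling


def sample_ecologies(
    dist: EcologyDistribution, n_wells: int, rng: np.random.Generator
) -> np.ndarray:
    """``n_wells`` i.i.d. ecology indices (1..16) from ``dist``."""
    return dist.sample_indices(n_wells, rng)


def sample_community(
    pool_freqs: np.ndarray,
    K: float,
    slots: int,
    rng: np.random.Generator,
    total_density: Optional[float] = None,
) -> tuple[np.ndarray, frozenset[Strain]]:
    """Inoculate one well: ``slots`` strain draws from the pool frequencies.

    Each slot contributes an equal share of the total inoculum (K/2 by
    default, i.e. K/8 per slot at the default four slots).  Returns the
    length-4 density vector and the membership set.
    """
    f = np.asarray(pool_freqs, dtype=float)
    if f.sum() <= 0:
        raise ValueError("cannot sample a community from an extinct pool")
    total = K / 2 if total_density is None else total_density
    draws = rng.choice(4, size=slots, p=f / f.sum())
    counts = np.bincount(draws, minlength=4)
    densities = counts * (total / slots)
    members = frozenset(s for s in STRAINS if counts[int(s)] > 0)
    return densities, members


def _sample_communities_batch(
    pool_freqs: np.ndarray,
    config: CycleConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Densities (n_wells, 4) and membership-mask ints for all wells."""
    f = pool_freqs / pool_freqs.sum()
    n, slots = config.n_wells, config.inoculum_slots
    total = config.total_inoculum
    if config.inoculum_mode == "slots":
        draws = rng.choice(4, size=(n, slots), p=f)
        counts = np.stack([np.bincount(row, minlength=4) for row in draws])
        densities = counts * (total / slots)
    else:  # multinomial individuals: round(total) unit draws
        n_units = max(1, int(round(total)))
        counts = rng.multinomial(n_units, f, size=n)
        densities = counts * (total / n_units)
    bits = (counts > 0) @ np.array([8, 4, 2, 1])
    return densities, bits


# ---------------------------------------------------------------------------
# phases


def run_well_phase(
    pool_freqs: np.ndarray,
    dist: EcologyDistribution,
    config: CycleConfig,
    params: GrowthModelParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, np.ndarray]:
    """One structured phase over all wells.

    Samples an ecology and a community per well, classifies viability,
    integrates the logistic system for ``t_wells``, and returns the
    per-strain densities summed over wells, the death rate (fraction of
    non-viable wells) and the histogram of sampled ecology indices.
    """
    rates_tab, viab_tab = _cached_tables(params)
    eco_idx = sample_ecologies(dist, config.n_wells, rng)
    densities, bits = _sample_communities_batch(pool_freqs, config, rng)
    well_rates = rates_tab[eco_idx - 1, bits]
    is_viable = viab_tab[eco_idx - 1, bits]
    death_rate = 1.0 - is_viable.mean()

    if config.t_wells > 0:
        if config.nonviable_mode == "exponential":
            out = np.empty_like(densities)
            dead = ~is_viable
            out[dead] = densities[dead] * np.exp(config.d * config.t_wells)
            if is_viable.any():
                out[is_viable] = integrate_wells_batch(
                    densities[is_viable],
                    well_rates[is_viable],
                    config.K,
                    config.t_wells,
                    config.dt,
                )
            final = out
        else:
            final = integrate_wells_batch(
                densities, well_rates, config.K, config.t_wells, config.dt
            )
    else:
        final = densities
    final = clamp_floor(final)
    aggregated = final.sum(axis=0)
    histogram = np.bincount(eco_idx - 1, minlength=N_ECOLOGIES)
    return aggregated, death_rate, histogram


def normalize_to_pool(
    aggregated: np.ndarray, pool_init_total: float = 1.0
) -> PoolState:
    """Rescale pooled well output to the pool seeding density.

    An all-zero aggregate yields an extinct (all-zero) pool.
    """
    agg = np.asarray(aggregated, dtype=float)
    total = agg.sum()
    if total <= 0:
        return PoolState(densities=np.zeros(4))
    return PoolState(densities=agg / total * pool_init_total)


# ---------------------------------------------------------------------------
# the full lineage


def run_lineage(
    config: CycleConfig,
    params: GrowthModelParams,
    schedule: DistributionSchedule,
    seed_seq: Optional[np.random.SeedSequence] = None,
) -> RunResult:
    """Simulate one lineage for ``config.n_cycles`` pool-well cycles.

    Record 0 holds the initial proportions; record ``c`` (1-based)
    holds the proportions after cycle ``c``'s pool phase and the death
    rate of its well phase.  Per-cycle RNG substreams are derived from
    ``seed_seq`` (default: seeded by ``config.seed``) so results are
    reproducible bit-for-bit.
    """
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(config.seed)
    streams = seed_seq.spawn(config.n_cycles + 1)
    init_rng = np.random.default_rng(streams[0])
    freqs = config.initial_freqs(init_rng)
    pool = PoolState(densities=freqs * config.pool_init_total)

    records = [
        CycleRecord(
            cycle=0,
            strain_proportions=freqs.copy(),
            death_rate=0.0,
            ecology_histogram=np.zeros(N_ECOLOGIES, dtype=int),
        )
    ]
    extinct = False
    extinction_cycle: Optional[int] = None

    for cycle in range(1, config.n_cycles + 1):
        if extinct:
            records.append(
                CycleRecord(
                    cycle=cycle,
                    strain_proportions=np.zeros(4),
                    death_rate=1.0,
                    ecology_histogram=np.zeros(N_ECOLOGIES, dtype=int),
                )
            )
            continue

        pool = integrate_pool(pool, np.asarray(params.pool_rates), config.t_pool)
        post_pool = pool.frequencies
        rng = np.random.default_rng(streams[cycle])
        dist = schedule(cycle, post_pool)
        aggregated, death_rate, histogram = run_well_phase(
            post_pool, dist, config, params, rng
        )
        records.append(
            CycleRecord(
                cycle=cycle,
                strain_proportions=post_pool.copy(),
                death_rate=death_rate,
                ecology_histogram=histogram,
            )
        )
        pool = normalize_to_pool(aggregated, config.pool_init_total)
        # strains below the extinction threshold are gone for good
        f = pool.frequencies
        f[f < config.extinction_eps] = 0.0
        if f.sum() <= 0:
            extinct = True
            extinction_cycle = cycle
            pool = PoolState(densities=np.zeros(4))
        else:
            pool = PoolState(
                densities=f / f.sum() * config.pool_init_total
            )

    return RunResult(
        records=records,
        extinct=extinct,
        extinction_cycle=extinction_cycle,
        config=config,
    )
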