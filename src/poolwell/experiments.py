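"""Scenario presets, replicate orchestration and rescue interventions.

The presets pin the published study conditions: K = 10, d = -2,
t_wells = 20, 96 wells, 10 cycles, 100 replicate runs, equal initial
proportions.  The interventions are (i) metabolic feedback switched on
early (cycle 1), intermediate (cycle 5) or late (cycle 9); (ii) a
rescue that halves the pool duration; and (iii) a rescue that pulls
every growth rate halfway towards the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .core import GrowthModelParams, Metabolite, Strain, default_params
from .distributions import (
    EcologyDistribution,
    restrict_distribution,
    uniform_distribution,
)
from .engine import (
    ConstantSchedule,
    CycleConfig,
    DistributionSchedule,
    FeedbackSchedule,
    RunResult,
    run_lineage,
)

__all__ = [
    "InterventionSpec",
    "ExperimentSummary",
    "Scenario",
    "apply_equalization",
    "equalize_params",
    "run_replicates",
    "baseline",
    "timescale_scan",
    "capacity_contrast",
    "poisson_scan",
    "feedback_intervention",
    "rescue_tpool",
    "rescue_equalization",
    "null_single_well",
    "keystone_trp",
    "PRESETS",
    "get_preset",
]

DEFAULT_N_RUNS = 100
#: the headline feedback experiments run at an order-of-magnitude
#: pool/well timescale separation
FEEDBACK_T_POOL = 1.28


@dataclass(frozen=True)
class InterventionSpec:
    """A named bundle of interventions applied on top of a scenario."""

    feedback_start_cycle: Optional[int] = None  # 1=early, 5=intermediate, 9=late
    tpool_scale: float = 1.0
    equalization_alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.tpool_scale <= 0:
            raise ValueError("tpool_scale must be > 0")
        if not 0 <= self.equalization_alpha <= 1:
            raise ValueError("equalization_alpha must be in [0, 1]")


@dataclass
class ExperimentSummary:
    """Replicate-averaged outcome of a scenario.

    Means are arithmetic over all runs; extinct runs contribute zero
    proportions (and death rate 1) from their extinction cycle on, so
    mean proportions decay towards zero as lineages collapse.
    """

    name: str
    n_runs: int
    mean_proportions: np.ndarray  # (n_cycles + 1, 4)
    mean_death_rate: np.ndarray  # (n_cycles + 1,)
    extinction_fraction: float
    extinction_time_histogram: np.ndarray  # counts per cycle 1..n_cycles
    runs: list[RunResult] = field(default_factory=list, repr=False)

    def final_mean_proportions(self) -> np.ndarray:
        return self.mean_proportions[-1]

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for c in range(self.mean_proportions.shape[0]):
            row = {"cycle": c, "mean_death_rate": self.mean_death_rate[c]}
            for s in Strain:
                row[f"mean_prop_{s.name}"] = self.mean_proportions[c, int(s)]
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class Scenario:
    """A fully specified, runnable experiment."""

    name: str
    config: CycleConfig
    params: GrowthModelParams
    schedule_factory: Callable[[], DistributionSchedule]
    n_runs: int = DEFAULT_N_RUNS
    description: str = ""


def apply_equalization(rates: np.ndarray, alpha: float) -> np.ndarray:
    """Pull each rate a fraction ``alpha`` towards the vector mean.

    r'_i = r_i + alpha (mean(r) - r_i); the mean is preserved exactly,
    alpha = 0 is the identity and alpha = 1 collapses all rates to the
    mean.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    r = np.asarray(rates, dtype=float)
    return r + alpha * (r.mean() - r)


def equalize_params(params: GrowthModelParams, alpha: float) -> GrowthModelParams:
    """Equalize base, pool and override rates uniformly.

    Override entries are grouped by (ecology, membership) and pulled
    towards their group mean, mirroring the per-community calibration.
    """
    base = tuple(apply_equalization(np.array(params.base_rates), alpha))
    pool = tuple(apply_equalization(np.array(params.pool_rates), alpha))
    groups: dict[tuple[int, str], list[tuple[Strain, float]]] = {}
    for (idx, mask, strain), rate in params.overrides.items():
        groups.setdefault((idx, mask), []).append((strain, rate))
    overrides: dict[tuple[int, str, Strain], float] = {}
    for (idx, mask), entries in groups.items():
        mean = float(np.mean([r for _, r in entries]))
        for strain, rate in entries:
            overrides[(idx, mask, strain)] = rate + alpha * (mean - rate)
    return replace(
        params, base_rates=base, pool_rates=pool, overrides=overrides
    )


def run_replicates(
    scenario: Scenario,
    n_runs: Optional[int] = None,
    seed: int = 0,
    keep_runs: bool = False,
) -> ExperimentSummary:
    """Run independent replicate lineages and aggregate them.

    Replicate ``i`` draws its RNG substream from
    ``SeedSequence(seed, spawn_key=(i,))`` so adding replicates never
    perturbs earlier ones.
    """
    n = scenario.n_runs if n_runs is None else n_runs
    if n < 1:
        raise ValueError("n_runs must be >= 1")
    n_cycles = scenario.config.n_cycles
    props = np.zeros((n_cycles + 1, 4))
    deaths = np.zeros(n_cycles + 1)
    ext_hist = np.zeros(n_cycles, dtype=int)
    n_ext = 0
    runs: list[RunResult] = []
    for i in range(n):
        seq = np.random.SeedSequence(entropy=seed, spawn_key=(i,))
        result = run_lineage(
            scenario.config, scenario.params, scenario.schedule_factory(), seq
        )
        props += result.proportions_matrix()
        deaths += result.death_rates()
        if result.extinct:
            n_ext += 1
            ext_hist[result.extinction_cycle - 1] += 1
        if keep_runs:
            runs.append(result)
    return ExperimentSummary(
        name=scenario.name,
        n_runs=n,
        mean_proportions=props / n,
        mean_death_rate=deaths / n,
        extinction_fraction=n_ext / n,
        extinction_time_histogram=ext_hist,
        runs=runs,
    )


# ---------------------------------------------------------------------------
# presets


def _uniform_factory() -> Callable[[], DistributionSchedule]:
    return lambda: ConstantSchedule(uniform_distribution())


def baseline(**config_kwargs) -> Scenario:
    """The headline cycling experiment: t_pool = 2, uniform ecologies."""
    cfg = CycleConfig(t_pool=2.0, **config_kwargs)
    return Scenario(
        name="baseline",
        config=cfg,
        params=default_params(),
        schedule_factory=_uniform_factory(),
        description="pool-well cycling, uniform ecologies, t_pool=2",
    )


def timescale_scan(
    tpool_values: Sequence[float] = tuple(0.02 * 2**k for k in range(9)),
) -> list[Scenario]:
    """Scenarios along the doubling grid of pool durations (0.02 .. 5.12)."""
    if not tpool_values:
        raise ValueError("tpool_values must be non-empty")
    return [
        replace_scenario(baseline(), t_pool=tp, name=f"timescale_tpool={tp:g}")
        for tp in tpool_values
    ]


def capacity_contrast(K_values: Sequence[float] = (10.0, 100.0)) -> list[Scenario]:
    """Carrying-capacity contrast at a fixed inoculum density.

    The inoculum density is pinned to the baseline K/2 = 5 for every K:
    with the inoculum scaled to K/2 the logistic system is exactly
    invariant in K (substitute u = x/K), so only a fixed inoculum lets
    a larger well prolong exponential growth and speed the takeover by
    the fastest strain.
    """
    if not K_values:
        raise ValueError("K_values must be non-empty")
    out = []
    for K in K_values:
        cfg = CycleConfig(K=K, inoculum_density=5.0, t_pool=2.0)
        out.append(
            Scenario(
                name=f"capacity_K={K:g}",
                config=cfg,
                params=default_params(),
                schedule_factory=_uniform_factory(),
                description=f"uniform ecologies, K={K}, fixed inoculum density 5",
            )
        )
    return out


def poisson_scan(
    mus: Sequence[float] = (1.0, 3.5, 9.0), weighting: str = "index"
) -> list[Scenario]:
    """Poisson-skewed niche availability at means 1, 3.5 and 9."""
    from .distributions import poisson_distribution

    if not mus:
        raise ValueError("mus must be non-empty")
    out = []
    for mu in mus:
        dist = poisson_distribution(mu, weighting=weighting)
        cfg = CycleConfig(t_pool=FEEDBACK_T_POOL)
        out.append(
            Scenario(
                name=f"poisson_mu={mu:g}",
                config=cfg,
                params=default_params(),
                schedule_factory=(lambda d=dist: ConstantSchedule(d)),
                description=f"Poisson({mu}) ecologies, t_pool={FEEDBACK_T_POOL}",
            )
        )
    return out


def feedback_intervention(
    start_cycle: int, t_pool: float = FEEDBACK_T_POOL
) -> Scenario:
    """Metabolic feedback from ``start_cycle`` (1 early, 5 intermediate, 9 late)."""
    cfg = CycleConfig(t_pool=t_pool)
    return Scenario(
        name=f"feedback_start={start_cycle}",
        config=cfg,
        params=default_params(),
        schedule_factory=lambda: FeedbackSchedule(
            uniform_distribution(), start_cycle=start_cycle
        ),
        description=f"metabolic feedback from cycle {start_cycle}, t_pool={t_pool}",
    )


def rescue_tpool(start_cycle: int, scale: float = 0.5) -> Scenario:
    """Rescue by shortening the pool phase (default: halved t_pool)."""
    sc = feedback_intervention(start_cycle, t_pool=FEEDBACK_T_POOL * scale)
    sc.name = f"rescue_tpool_start={start_cycle}"
    sc.description = (
        f"feedback from cycle {start_cycle}, t_pool scaled by {scale}"
    )
    return sc


def rescue_equalization(start_cycle: int, alpha: float = 0.5) -> Scenario:
    """Rescue by pulling all growth rates towards the mean by ``alpha``."""
    sc = feedback_intervention(start_cycle)
    sc.params = equalize_params(sc.params, alpha)
    sc.name = f"rescue_equalization_start={start_cycle}"
    sc.description = (
        f"feedback from cycle {start_cycle}, rates equalized by alpha={alpha}"
    )
    return sc


def null_single_well() -> Scenario:
    """Null model: a single well instead of 96, random initial proportions."""
    cfg = CycleConfig(
        n_wells=1, t_pool=FEEDBACK_T_POOL, initial_proportions="random"
    )
    return Scenario(
        name="null_single_well",
        config=cfg,
        params=default_params(),
        schedule_factory=_uniform_factory(),
        description="single-well null model, uniform ecologies",
    )


def keystone_trp() -> Scenario:
    """Keystone experiment: every tryptophan-containing ecology removed."""
    dist = restrict_distribution(uniform_distribution(), Metabolite.TRP)
    cfg = CycleConfig(t_pool=2.0)
    return Scenario(
        name="keystone_trp",
        config=cfg,
        params=default_params(),
        schedule_factory=lambda: ConstantSchedule(dist),
        description="uniform ecologies restricted to TRP-free wells",
    )


def replace_scenario(sc: Scenario, name: Optional[str] = None, **config_kwargs) -> Scenario:
    """Copy a scenario with modified config fields (and optional rename)."""
    return Scenario(
        name=name or sc.name,
        config=replace(sc.config, **config_kwargs),
        params=sc.params,
        schedule_factory=sc.schedule_factory,
        n_runs=sc.n_runs,
        description=sc.description,
    )


PRESETS: dict[str, Callable[[], object]] = {
    "baseline": baseline,
    "timescale-scan": timescale_scan,
    "capacity-contrast": capacity_contrast,
    "poisson-scan": poisson_scan,
    "feedback-early": lambda: feedback_intervention(1),
    "feedback-intermediate": lambda: feedback_intervention(5),
    "feedback-late": lambda: feedback_intervention(9),
    "rescue-tpool-intermediate": lambda: rescue_tpool(5),
    "rescue-tpool-late": lambda: rescue_tpool(9),
    "rescue-equalization-intermediate": lambda: rescue_equalization(5),
    "rescue-equalization-late": lambda: rescue_equalization(9),
    "null-single-well": null_single_well,
    "keystone-trp": keystone_trp,
}


def get_preset(name: str):
    """Look up a preset factory by CLI name."""
    if name not in PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        )
    return PRESETS[name]()
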