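"""Within-well logistic dynamics and pool-phase exponential growth.

Wells: each strain density obeys a logistic equation with a shared
carrying capacity,

    dx_i/dt = x_i R_i(E, S) (1 - sum_k x_k / K),

integrated with a fixed-step classical Runge-Kutta (RK4) scheme.  In a
non-viable well every member carries the same negative rate d; by
default the same logistic equation is integrated (the crowding bracket
merely damps the decay), with a pure exponential-decay alternative
available for sensitivity checks.

Pool: unstructured exponential growth dy_i/dt = r_i y_i, solved in
closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._integrate import rk4_wells

__all__ = [
    "WellState",
    "PoolState",
    "IntegrationInstabilityError",
    "integrate_well",
    "integrate_wells_batch",
    "integrate_pool",
    "DEFAULT_DT",
    "DENSITY_FLOOR",
]

DEFAULT_DT = 0.01
#: densities below this are clamped to zero at phase boundaries
DENSITY_FLOOR = 1e-12


class IntegrationInstabilityError(RuntimeError):
    """A density went negative beyond tolerance; use a smaller dt."""


@dataclass
class WellState:
    """Per-strain densities in one compartment with carrying capacity K."""

    densities: np.ndarray
    K: float

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        if self.densities.shape != (4,):
            raise ValueError("well state needs a length-4 density vector")
        if (self.densities < 0).any():
            raise ValueError("densities must be non-negative")
        if self.K <= 0:
            raise ValueError("carrying capacity K must be positive")

    @property
    def total(self) -> float:
        return float(self.densities.sum())


@dataclass
class PoolState:
    """Global per-strain densities in the unstructured pool."""

    densities: np.ndarray

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        if self.densities.shape != (4,):
            raise ValueError("pool state needs a length-4 density vector")
        if (self.densities < 0).any():
            raise ValueError("densities must be non-negative")

    @property
    def total(self) -> float:
        return float(self.densities.sum())

    @property
    def frequencies(self) -> np.ndarray:
        """Strain frequencies; all-zero for an extinct pool."""
        tot = self.densities.sum()
        if tot <= 0:
            return np.zeros(4)
        return self.densities / tot

    @property
    def extinct(self) -> bool:
        return self.total <= 0


def integrate_well(
    state: WellState,
    rates: np.ndarray,
    t: float,
    dt: float = DEFAULT_DT,
) -> WellState:
    """Advance one well for duration ``t`` under the logistic system.

    ``rates`` is the length-4 vector R_i(E, S) in canonical strain
    order (entries for absent strains are inert since their densities
    are zero).  Zero densities are absorbing.
    """
    if t <= 0:
        raise ValueError("duration t must be positive")
    if dt <= 0:
        raise ValueError("step dt must be positive")
    rates = np.asarray(rates, dtype=float)
    x, ok = rk4_wells(state.densities[None, :], rates[None, :], state.K, t, dt)
    if not ok:
        raise IntegrationInstabilityError(
            f"negative density during RK4 at dt={dt}; reduce dt"
        )
    return WellState(densities=x[0], K=state.K)


def integrate_wells_batch(
    densities: np.ndarray,
    rates: np.ndarray,
    K: float,
    t: float,
    dt: float = DEFAULT_DT,
) -> np.ndarray:
    """Advance many wells at once; (n_wells, 4) densities and rates."""
    x, ok = rk4_wells(densities, rates, K, t, dt)
    if not ok:
        raise IntegrationInstabilityError(
            f"negative density during RK4 at dt={dt}; reduce dt"
        )
    return x


def integrate_pool(
    state: PoolState, pool_rates: np.ndarray, t: float
) -> PoolState:
    """Exponential pool growth y_i(t) = y_i(0) exp(r_i t), in closed form."""
    if t < 0:
        raise ValueError("duration t must be non-negative")
    r = np.asarray(pool_rates, dtype=float)
    return PoolState(densities=state.densities * np.exp(r * t))


def clamp_floor(densities: np.ndarray, floor: float = DENSITY_FLOOR) -> np.ndarray:
    """Zero out denormal-scale densities at a phase boundary."""
    out = np.asarray(densities, dtype=float).copy()
    out[out < floor] = 0.0
    return out
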