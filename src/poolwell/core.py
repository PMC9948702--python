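"""Strains, metabolites, ecologies and the growth-rate model.

The community is the engineered four-strain *Saccharomyces cerevisiae*
cross-feeding system: each strain overproduces exactly one of the four
essential metabolites adenine (ADE), tryptophan (TRP), histidine (HIS)
and lysine (LYS) and is auxotrophic for the other three.  An *ecology*
is the presence/absence state of the four metabolites in a well; there
are 16 of them, indexed 1..16 in ascending richness (ties broken by the
binary value of the presence vector with ADE as the most significant
bit).  That ordering puts the two ecologies permissive for a pure-HIS
community, {1,1,0,1} and {1,1,1,1}, at indices 14 and 16.

A well pairs an ecology ``E`` with a community membership ``S``.  Every
metabolite a member strain requires must be sourced from the ecology or
from a co-inoculated producer; otherwise the whole community is
non-viable and every member decays at the death rate ``d``.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field, replace
from typing import FrozenSet, Iterable, Mapping

import numpy as np

__all__ = [
    "Metabolite",
    "Strain",
    "Ecology",
    "Source",
    "GrowthModelParams",
    "METABOLITES",
    "STRAINS",
    "N_ECOLOGIES",
    "ALL_STRAINS",
    "enumerate_ecologies",
    "ecology_from_index",
    "ecology_from_presence",
    "metabolite_source",
    "viable",
    "growth_rates",
    "growth_rate_vector",
    "members_mask",
    "mask_members",
    "default_params",
    "FIG_RATE_VECTOR",
]


class Metabolite(enum.IntEnum):
    """The four shareable essential metabolites, in canonical order."""

    ADE = 0
    TRP = 1
    HIS = 2
    LYS = 3


class Strain(enum.IntEnum):
    """The four overproducer strains (ADE↑, TRP↑, HIS↑, LYS↑).

    ``Strain.ADE`` is the adenine overproducer: it supplies ADE and
    requires the other three metabolites.
    """

    ADE = 0
    TRP = 1
    HIS = 2
    LYS = 3

    @property
    def produces(self) -> Metabolite:
        return Metabolite(int(self))

    @property
    def requires(self) -> FrozenSet[Metabolite]:
        return frozenset(m for m in Metabolite if int(m) != int(self))


METABOLITES: tuple[Metabolite, ...] = tuple(Metabolite)
STRAINS: tuple[Strain, ...] = tuple(Strain)
ALL_STRAINS: FrozenSet[Strain] = frozenset(Strain)
N_ECOLOGIES = 16

#: Within-well growth rates of the all-strain community in the metabolite-free
#: ecology, for (ADE↑, TRP↑, HIS↑, LYS↑) — the calibration point of the model.
FIG_RATE_VECTOR: tuple[float, float, float, float] = (0.804, 0.869, 1.157, 0.732)


@dataclass(frozen=True, order=True)
class Ecology:
    """Presence/absence of the four metabolites in a well.

    Attributes
    ----------
    presence
        4-tuple of 0/1 in canonical metabolite order (ADE, TRP, HIS, LYS).
    index
        Canonical index 1..16 (ascending richness, ADE-as-MSB tiebreak).
    """

    index: int
    presence: tuple[int, int, int, int]

    @property
    def richness(self) -> int:
        return sum(self.presence)

    def has(self, m: Metabolite) -> bool:
        return bool(self.presence[int(m)])

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"E{self.index}{self.presence}"


def _binary_value(presence: tuple[int, ...]) -> int:
    # ADE is the most significant bit
    v = 0
    for bit in presence:
        v = (v << 1) | bit
    return v


def enumerate_ecologies() -> tuple[Ecology, ...]:
    """All 16 ecologies in canonical order (index 1 = barren, 16 = rich)."""
    vectors = sorted(
        itertools.product((0, 1), repeat=4),
        key=lambda p: (sum(p), _binary_value(p)),
    )
    return tuple(
        Ecology(index=i + 1, presence=p) for i, p in enumerate(vectors)
    )


_ECOLOGIES = enumerate_ecologies()
_PRESENCE_TO_INDEX = {e.presence: e.index for e in _ECOLOGIES}


def ecology_from_index(index: int) -> Ecology:
    if not 1 <= index <= N_ECOLOGIES:
        raise ValueError(f"ecology index must be in 1..16, got {index}")
    return _ECOLOGIES[index - 1]


def ecology_from_presence(presence: Iterable[int]) -> Ecology:
    key = tuple(int(b) for b in presence)
    if key not in _PRESENCE_TO_INDEX:
        raise ValueError(f"not a 0/1 4-vector: {presence!r}")
    return _ECOLOGIES[_PRESENCE_TO_INDEX[key] - 1]


class Source(enum.Enum):
    """Where a community member can obtain a metabolite from."""

    ECOLOGY = "ecology"
    CROSSFED = "crossfed"
    ABSENT = "absent"


def metabolite_source(
    ecology: Ecology, members: FrozenSet[Strain] | Iterable[Strain], m: Metabolite
) -> Source:
    """Classify the supply of metabolite ``m`` in well ``(E, S)``.

    Ecology supply shadows cross-feeding: when both are available the
    metabolite counts as supplemented, and the member growing on it is
    charged no cross-feeding cost.
    """
    if ecology.has(m):
        return Source.ECOLOGY
    if any(Strain(s).produces == m for s in members):
        return Source.CROSSFED
    return Source.ABSENT


def viable(ecology: Ecology, members: FrozenSet[Strain] | Iterable[Strain]) -> bool:
    """True iff every member can source all three of its foreign requirements.

    Viability is all-or-nothing at the community level: one starving member
    dooms the well and every member then decays at the death rate.  The
    empty community is non-viable by definition.
    """
    members = frozenset(members)
    if not members:
        return False
    for s in members:
        for m in s.requires:
            if metabolite_source(ecology, members, m) is Source.ABSENT:
                return False
    return True


def members_mask(members: Iterable[Strain]) -> str:
    """4-character 0/1 membership string in canonical strain order."""
    ms = frozenset(members)
    return "".join("1" if s in ms else "0" for s in STRAINS)


def mask_members(mask: str) -> FrozenSet[Strain]:
    if len(mask) != 4 or any(c not in "01" for c in mask):
        raise ValueError(f"membership mask must be 4 chars of 0/1, got {mask!r}")
    return frozenset(s for s, c in zip(STRAINS, mask) if c == "1")


@dataclass(frozen=True)
class GrowthModelParams:
    """Parameters of the within-well and pool growth-rate model.

    The parametric rule for a viable well is::

        R_i(E, S) = base_rate[i] * crossfeed_factor ** n_crossfed(i)

    where ``n_crossfed(i)`` counts the member's required metabolites that
    are available only through cross-feeding.  Explicit overrides,
    keyed by (ecology index, membership mask, strain), take precedence
    and carry empirically calibrated community rates.  Non-viable wells
    use the (negative) death rate for every member.
    """

    base_rates: tuple[float, float, float, float]
    crossfeed_factor: float = 0.95
    death_rate: float = -2.0
    pool_rates: tuple[float, float, float, float] = FIG_RATE_VECTOR
    overrides: Mapping[tuple[int, str, Strain], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.base_rates):
            raise ValueError("base_rates must all be positive")
        if not 0 < self.crossfeed_factor <= 1:
            raise ValueError("crossfeed_factor must be in (0, 1]")
        if self.death_rate >= 0:
            raise ValueError("death_rate must be negative")
        for (idx, mask, strain), rate in self.overrides.items():
            if not 1 <= idx <= N_ECOLOGIES:
                raise ValueError(f"override ecology index out of range: {idx}")
            mask_members(mask)  # raises on malformed masks
            if not isinstance(strain, Strain):
                raise ValueError(f"override strain not a Strain: {strain!r}")
            float(rate)

    def with_overrides(
        self, overrides: Mapping[tuple[int, str, Strain], float]
    ) -> "GrowthModelParams":
        return replace(self, overrides=dict(overrides))


def default_params() -> GrowthModelParams:
    """Default growth model, calibrated to the published rate vector.

    The all-strain community in the metabolite-free ecology grows at
    (0.804, 0.869, 1.157, 0.732) for (ADE↑, TRP↑, HIS↑, LYS↑); that entry
    ships as an override.  Base (fully supplemented) rates are chosen as
    ``printed / crossfeed_factor**3`` so the parametric rule and the
    override agree at the calibration point.  Pool (minimal-medium) rates
    default to the same printed vector.
    """
    c = 0.95
    base = tuple(r / c**3 for r in FIG_RATE_VECTOR)
    overrides = {
        (1, "1111", s): FIG_RATE_VECTOR[int(s)] for s in STRAINS
    }
    return GrowthModelParams(
        base_rates=base, crossfeed_factor=c, overrides=overrides
    )


def growth_rates(
    ecology: Ecology,
    members: FrozenSet[Strain] | Iterable[Strain],
    params: GrowthModelParams,
) -> dict[Strain, float]:
    """Per-member growth rates R_i(E, S) for the strains in the community.

    Non-viable communities map every member to the death rate; viable
    ones use the override table first, then the parametric
    base-times-crossfeed-penalty rule.  A strain's own product is free
    to itself, so only its three foreign requirements can incur the
    cross-feeding penalty.
    """
    members = frozenset(Strain(s) for s in members)
    if not viable(ecology, members):
        return {s: params.death_rate for s in members}
    mask = members_mask(members)
    out: dict[Strain, float] = {}
    for s in members:
        key = (ecology.index, mask, s)
        if key in params.overrides:
            out[s] = float(params.overrides[key])
            continue
        n_crossfed = sum(
            1
            for m in s.requires
            if metabolite_source(ecology, members, m) is Source.CROSSFED
        )
        out[s] = params.base_rates[int(s)] * params.crossfeed_factor**n_crossfed
    return out


def growth_rate_vector(
    ecology: Ecology,
    members: FrozenSet[Strain] | Iterable[Strain],
    params: GrowthModelParams,
) -> np.ndarray:
    """Length-4 rate vector in canonical strain order; non-members get 0.

    Convenience for the integrator, where non-member densities are zero
    and their rates are inert.
    """
    rates = np.zeros(4)
    for s, r in growth_rates(ecology, members, params).items():
        rates[int(s)] = r
    return rates
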