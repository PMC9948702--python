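"""Probability distributions over the 16 well ecologies.

Four families are provided: uniform (the baseline), Poisson-weighted
(niche availability skewed towards poor or rich ecologies), metabolic
feedback (the strains' own pool frequencies set the chance that their
product is present in the next round of wells), and keystone
restrictions (all ecologies containing a given metabolite removed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import (
    METABOLITES,
    N_ECOLOGIES,
    STRAINS,
    Metabolite,
    enumerate_ecologies,
)

__all__ = [
    "EcologyDistribution",
    "uniform_distribution",
    "poisson_distribution",
    "feedback_distribution",
    "restrict_distribution",
    "point_mass",
]

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class EcologyDistribution:
    """A probability vector over the 16 canonical ecology indices."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (N_ECOLOGIES,):
            raise ValueError("ecology distribution needs 16 probabilities")
        if (p < 0).any():
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {p.sum()}, not 1")
        p = p / p.sum()  # kill rounding residue
        object.__setattr__(self, "probs", p)

    def prob(self, index: int) -> float:
        """Probability of the ecology with canonical index 1..16."""
        return float(self.probs[index - 1])

    def sample_indices(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` ecology indices (1..16) i.i.d. from the distribution."""
        return rng.choice(N_ECOLOGIES, size=n, p=self.probs) + 1


def uniform_distribution() -> EcologyDistribution:
    """All 16 ecologies equally likely (probability 0.0625 each)."""
    return EcologyDistribution(np.full(N_ECOLOGIES, 1.0 / N_ECOLOGIES))


def point_mass(index: int) -> EcologyDistribution:
    """Degenerate distribution on a single ecology index (testing aid)."""
    p = np.zeros(N_ECOLOGIES)
    p[index - 1] = 1.0
    return EcologyDistribution(p)


def poisson_distribution(mu: float, weighting: str = "index") -> EcologyDistribution:
    """Poisson-skewed niche availability.

    ``weighting="index"`` (default) weights ecology index ``j`` by the
    Poisson pmf at ``j - 1`` and renormalizes over the 16 indices, so
    larger means shift mass towards richer ecologies.
    ``weighting="richness"`` instead places the (truncated) Poisson over
    the five richness classes 0..4 and splits each class's mass
    uniformly among its ecologies; at large means this concentrates on
    the richest ecologies (indices 14 and 16 dominate the HIS-permissive
    pair).
    """
    if mu <= 0:
        raise ValueError("Poisson mean mu must be positive")
    if weighting == "index":
        w = stats.poisson.pmf(np.arange(N_ECOLOGIES), mu)
    elif weighting == "richness":
        class_mass = stats.poisson.pmf(np.arange(5), mu)
        richness = np.array([e.richness for e in enumerate_ecologies()])
        class_size = np.bincount(richness, minlength=5)
        w = class_mass[richness] / class_size[richness]
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    total = w.sum()
    if total <= 0:
        raise ValueError(f"Poisson weights vanished for mu={mu}")
    return EcologyDistribution(w / total)


def feedback_distribution(
    strain_freqs: np.ndarray, scaling: str = "identity"
) -> EcologyDistribution:
    """Metabolic feedback: strain frequencies shape the next ecologies.

    Each metabolite is present independently with probability equal to
    the current pool frequency of the strain producing it (``scaling=
    "identity"``) or ``min(1, 4 * frequency)`` (``scaling="4x"``); the
    ecology probabilities are the resulting product-Bernoulli masses.
    A pool dominated by one strain therefore floods the wells with that
    strain's own product — the metabolite it does *not* need — which is
    the self-limiting feedback at the heart of the niche-stabilization
    experiments.
    """
    f = np.asarray(strain_freqs, dtype=float)
    if f.shape != (4,):
        raise ValueError("strain_freqs must be a length-4 vector")
    if (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("strain_freqs must be non-negative and sum to 1")
    if scaling == "identity":
        p_present = f
    elif scaling == "4x":
        p_present = np.minimum(1.0, 4.0 * f)
    else:
        raise ValueError(f"unknown feedback scaling {scaling!r}")
    probs = np.empty(N_ECOLOGIES)
    for e in enumerate_ecologies():
        mass = 1.0
        for m in METABOLITES:
            pm = p_present[int(m)]
            mass *= pm if e.presence[int(m)] else (1.0 - pm)
        probs[e.index - 1] = mass
    return EcologyDistribution(probs)


def restrict_distribution(
    dist: EcologyDistribution, banned: Metabolite
) -> EcologyDistribution:
    """Remove every ecology containing ``banned`` and renormalize.

    Eight ecologies survive; the renormalization keeps the number of
    wells unchanged.  Used for the keystone experiment in which all
    tryptophan-containing ecologies are removed and TRP↑ becomes an
    obligatory community member.
    """
    keep = np.array(
        [0 if e.presence[int(banned)] else 1 for e in enumerate_ecologies()],
        dtype=float,
    )
    masked = dist.probs * keep
    total = masked.sum()
    if total <= _SUM_TOL:
        raise ValueError(
            f"no probability mass left after banning {Metabolite(banned).name}"
        )
    return EcologyDistribution(masked / total)
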