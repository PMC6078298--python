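"""Equal-probability (binomial) single-state deuteration model.

A single conformational state in which every exchangeable site exchanges
with the same probability ``f`` produces a deuterium-count distribution
``Binomial(n_sites, f)``.  This equal-probability assumption yields the
*widest* distribution one state can produce: for heterogeneous per-site
probabilities with the same mean, the Poisson-binomial variance
``sum p_i (1 - p_i)`` is at most ``n p(1-p)``.  A mixture decomposition
against the equal-probability family therefore yields a lower bound on the
number of co-populated states.

The theoretical family used for deconvolution is a grid of such single-state
envelopes at uptake fractions uniformly spanning [0, 1] (200 members by
default, endpoints included, step 1/199).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .peptide_chemistry import IsotopeDistribution

__all__ = [
    "DELTA_M_D",
    "SingleStateEnvelope",
    "DeuterationFamily",
    "single_state",
    "build_family",
    "expected_uptake",
    "poisson_binomial_pmf",
    "family_to_tsv",
]

#: Mass increment per exchanged site: m(D) - m(H), Da.
DELTA_M_D = 1.006277


@dataclass(frozen=True)
class SingleStateEnvelope:
    """Isotope envelope of one uniformly exchanging state.

    ``site_mass_shift`` is the mass added per exchanged site on the envelope's
    mass axis: ``DELTA_M_D`` in the neutral/oligomer mass domain, or
    ``DELTA_M_D / n_monomers`` when the axis is mass-per-monomer.
    """

    fraction: float
    n_sites: int
    distribution: IsotopeDistribution
    site_mass_shift: float = DELTA_M_D

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.n_sites < 0:
            raise ValueError("n_sites must be non-negative")


@dataclass(frozen=True)
class DeuterationFamily:
    """Ordered grid of single-state envelopes from 0% to 100% uptake."""

    members: tuple[SingleStateEnvelope, ...]
    n_sites: int
    site_mass_shift: float = DELTA_M_D

    def __post_init__(self) -> None:
        fr = self.fractions
        if len(fr) < 2 or np.any(np.diff(fr) <= 0):
            raise ValueError("member fractions must be strictly increasing")

    @property
    def fractions(self) -> np.ndarray:
        return np.array([m.fraction for m in self.members])

    @property
    def uptakes(self) -> np.ndarray:
        """Expected deuterons of each member (whole-ion count)."""
        return self.fractions * self.n_sites

    def __len__(self) -> int:
        return len(self.members)


def _merge_sorted(masses: np.ndarray, probs: np.ndarray, tol: float = 1e-9):
    """Sort entries and sum probabilities of near-coincident masses."""
    order = np.argsort(masses, kind="stable")
    m, p = masses[order], probs[order]
    groups = np.concatenate([[0], np.cumsum(np.diff(m) > tol)])
    out_m = np.bincount(groups, weights=m * p) / np.bincount(groups, weights=p)
    out_p = np.bincount(groups, weights=p)
    return out_m, out_p


def single_state(
    natural: IsotopeDistribution,
    n_sites: int,
    fraction: float,
    site_mass_shift: float = DELTA_M_D,
    prune: float = 1e-6,
) -> SingleStateEnvelope:
    """Convolve a natural envelope with Binomial(n_sites, fraction) uptake.

    Each of the ``k`` exchanged sites (k binomially distributed) shifts the
    mass by ``site_mass_shift``.  The binomial pmf is evaluated exactly; the
    result is renormalized after pruning entries below ``prune``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    if n_sites < 0:
        raise ValueError("n_sites must be non-negative")
    if n_sites == 0 or fraction == 0.0:
        dist = natural
    elif fraction == 1.0:
        dist = IsotopeDistribution(
            natural.masses + n_sites * site_mass_shift, natural.probs, natural.domain
        )
    else:
        k = np.arange(n_sites + 1)
        bpmf = stats.binom.pmf(k, n_sites, fraction)
        keep = bpmf > prune * bpmf.max()
        k, bpmf = k[keep], bpmf[keep]
        masses = (natural.masses[:, None] + k[None, :] * site_mass_shift).ravel()
        probs = (natural.probs[:, None] * bpmf[None, :]).ravel()
        m, p = _merge_sorted(masses, probs)
        keep2 = p >= prune * p.max()
        dist = IsotopeDistribution(m[keep2], p[keep2], natural.domain)
    return SingleStateEnvelope(fraction, n_sites, dist, site_mass_shift)


def build_family(
    natural: IsotopeDistribution,
    n_sites: int,
    grid: int = 200,
    site_mass_shift: float = DELTA_M_D,
) -> DeuterationFamily:
    """Single-state envelopes at fractions k/(grid-1), k = 0..grid-1."""
    if grid < 2:
        raise ValueError("grid must be >= 2")
    fractions = np.arange(grid) / (grid - 1)
    members = tuple(
        single_state(natural, n_sites, float(f), site_mass_shift) for f in fractions
    )
    return DeuterationFamily(members, n_sites, site_mass_shift)


def expected_uptake(e: SingleStateEnvelope) -> float:
    """Expected deuterons of a single-state envelope: fraction * n_sites."""
    return e.fraction * e.n_sites


def poisson_binomial_pmf(ps: Sequence[float]) -> np.ndarray:
    """Exact pmf of the number of exchanged sites with per-site probabilities.

    Iterative convolution; the reference model for heterogeneous-rate single
    states (the equal-probability binomial is the special case of equal
    ``ps`` and has the largest variance at matched mean).
    """
    pmf = np.array([1.0])
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def family_to_tsv(family: DeuterationFamily) -> str:
    """Long-format columnar dump: fraction, mass, probability per row."""
    lines = ["fraction\tmass\tprobability"]
    for m in family.members:
        for mass_val, prob in zip(m.distribution.masses, m.distribution.probs):
            lines.append(f"{m.fraction:.10g}\t{mass_val:.6f}\t{prob:.8e}")
    return "\n".join(lines) + "\n"
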