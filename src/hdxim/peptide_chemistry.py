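"""Peptide sequences, elemental composition, isotope envelopes and the
gas-phase exchangeable-proton inventory.

Gas-phase HDX with ND3 on millisecond timescales labels heteroatom-bound
side-chain and terminus hydrogens; backbone amide NH exchange is too slow in
vacuum to be observed, so amides are excluded from every count here.  The
per-residue inventory (``DEFAULT_EXCHANGE_TABLE``) lists the exchangeable
hydrogens of the *neutral* side-chain forms; protons acquired on ionization
are added separately per charge (see :func:`total_exchangeable`).

Elemental compositions and atomic/isotope masses come from the pyteomics
tables (``std_aa_comp``, ``nist_mass``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml
from pyteomics import mass as _pmass

__all__ = [
    "PROTON_MASS",
    "ISOTOPE_SPACING",
    "CANONICAL_RESIDUES",
    "WT_ABETA_1_40",
    "NSCR_ABETA_1_40",
    "SCR_ABETA_1_40",
    "PeptideSpec",
    "ElementalComposition",
    "IsotopeDistribution",
    "ExchangeTable",
    "DEFAULT_EXCHANGE_TABLE",
    "OligomerIon",
    "parse_sequence",
    "read_fasta_sequence",
    "composition",
    "average_mass",
    "monoisotopic_mass",
    "natural_isotope_distribution",
    "mz",
    "exchangeable_protons",
    "total_exchangeable",
]

#: Mass of the proton charge carrier (positive mode), Da.
PROTON_MASS = 1.007276

#: Average spacing between adjacent peptide isotope peaks, Da.  This is the
#: averagine-style mean gap, slightly below the pure 13C-12C difference
#: (1.00336); configurable wherever it is consumed.
ISOTOPE_SPACING = 1.00235

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Wild-type amyloid-beta 1-40.
WT_ABETA_1_40 = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVV"

# Synthetic stand-ins for the scrambled-sequence variants: fixed,
# composition-preserving permutations of the WT sequence (N-terminal 16
# residues only for NSCR, the whole chain for SCR).  Every quantity computed
# here (composition, masses, exchangeable counts) is permutation-invariant.
_rng = np.random.default_rng(20180806)
_n16 = list(WT_ABETA_1_40[:16])
_rng.shuffle(_n16)
#: Synthetic N-terminally scrambled variant (residues 1-16 permuted).
NSCR_ABETA_1_40 = "".join(_n16) + WT_ABETA_1_40[16:]
_full = list(WT_ABETA_1_40)
_rng.shuffle(_full)
#: Synthetic fully scrambled variant (all residues permuted).
SCR_ABETA_1_40 = "".join(_full)
del _rng, _n16, _full


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide chain with explicit terminus chemistry.

    Only free termini (alpha-amine, alpha-carboxylic acid) are supported;
    they contribute the terminal H/OH to the composition and their own
    exchangeable hydrogens (2 and 1 respectively).
    """

    sequence: str
    n_term: str = "free-amine"
    c_term: str = "free-acid"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        for i, aa in enumerate(self.sequence):
            if aa not in CANONICAL_RESIDUES:
                raise ValueError(
                    f"non-canonical residue {aa!r} at position {i + 1}"
                )
        if self.n_term != "free-amine" or self.c_term != "free-acid":
            raise ValueError("only free termini are supported")

    def __len__(self) -> int:
        return len(self.sequence)


class ElementalComposition(dict):
    """Counts per element symbol (C, H, N, O, S, ...).

    A thin dict subclass; values are non-negative integers, zero counts are
    dropped.  Supports ``+`` and integer ``*`` for combining compositions.
    """

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        super().__init__()
        merged: dict[str, int] = dict(counts or {})
        merged.update(kw)
        for el, n in merged.items():
            if n < 0 or int(n) != n:
                raise ValueError(f"count for {el} must be a non-negative integer")
            if el not in _pmass.nist_mass:
                raise ValueError(f"unknown element {el!r}")
            if n:
                self[el] = int(n)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        out = dict(self)
        for el, n in other.items():
            out[el] = out.get(el, 0) + n
        return ElementalComposition(out)

    def __mul__(self, k: int) -> "ElementalComposition":
        if int(k) != k or k < 0:
            raise ValueError("multiplier must be a non-negative integer")
        return ElementalComposition({el: n * int(k) for el, n in self.items()})

    __rmul__ = __mul__


@dataclass(frozen=True)
class IsotopeDistribution:
    """Discrete (mass, probability) pairs, sorted by mass.

    ``domain`` tags the mass axis: ``"mass"`` (neutral Da), ``"m/z"`` or
    ``"mass-per-monomer"`` (Da per monomeric unit of an oligomer).
    """

    masses: np.ndarray
    probs: np.ndarray
    domain: str = "mass"

    def __post_init__(self) -> None:
        m = np.asarray(self.masses, dtype=float)
        p = np.asarray(self.probs, dtype=float)
        if m.ndim != 1 or m.shape != p.shape:
            raise ValueError("masses and probs must be 1-D arrays of equal length")
        if m.size == 0:
            raise ValueError("distribution must be non-empty")
        if np.any(np.diff(m) <= 0):
            raise ValueError("masses must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        total = p.sum()
        if total <= 0:
            raise ValueError("probabilities must not be all zero")
        object.__setattr__(self, "masses", m)
        object.__setattr__(self, "probs", p / total)
        if self.domain not in ("mass", "m/z", "mass-per-monomer"):
            raise ValueError(f"unknown domain tag {self.domain!r}")

    def __len__(self) -> int:
        return int(self.masses.size)

    def centroid(self) -> float:
        """Probability-weighted mean mass."""
        return float(np.dot(self.masses, self.probs))

    def variance(self) -> float:
        mu = self.centroid()
        return float(np.dot((self.masses - mu) ** 2, self.probs))

    def pruned(self, threshold: float) -> "IsotopeDistribution":
        """Drop entries below ``threshold`` probability and renormalize."""
        keep = self.probs >= threshold
        if not keep.any():
            keep = self.probs == self.probs.max()
        return IsotopeDistribution(self.masses[keep], self.probs[keep], self.domain)


@dataclass(frozen=True)
class ExchangeTable:
    """Exchangeable heteroatom-bound hydrogens of neutral residue forms.

    The default values are the unique simple neutral-form assignment that
    reproduces the full/N-terminal/C-terminal inventory of wild-type
    amyloid-beta 1-40 (27 / 19 / 8).  Serializable as a flat name-to-integer
    YAML mapping with ``n_term`` / ``c_term`` keys.
    """

    residues: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUE_EXCHANGE)
    )
    n_term: int = 2  # free alpha-amine NH2
    c_term: int = 1  # free alpha-carboxylic acid OH

    def __post_init__(self) -> None:
        if self.n_term < 0 or self.c_term < 0:
            raise ValueError("terminus counts must be non-negative")
        for aa, n in self.residues.items():
            if aa not in CANONICAL_RESIDUES or n < 0:
                raise ValueError(f"invalid table entry {aa!r}: {n}")

    def count(self, aa: str) -> int:
        return int(self.residues.get(aa, 0))

    def to_yaml(self) -> str:
        data = {**{k: int(v) for k, v in sorted(self.residues.items())},
                "n_term": self.n_term, "c_term": self.c_term}
        return yaml.safe_dump(data, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ExchangeTable":
        data = dict(yaml.safe_load(text))
        n_term = int(data.pop("n_term", 2))
        c_term = int(data.pop("c_term", 1))
        return cls(residues={k: int(v) for k, v in data.items()},
                   n_term=n_term, c_term=c_term)


DEFAULT_RESIDUE_EXCHANGE: dict[str, int] = {
    "D": 1, "E": 1, "S": 1, "T": 1, "Y": 1, "H": 1,
    "Q": 2, "N": 2, "K": 2, "R": 4, "W": 1, "C": 1,
}

DEFAULT_EXCHANGE_TABLE = ExchangeTable()


@dataclass(frozen=True)
class OligomerIon:
    """An (n-mer, charge) identity of one native-MS signal, positive mode."""

    n_monomers: int
    charge: int

    _NAMES = ("MON", "DIM", "TRI", "TET", "PEN", "HEX", "HEP", "OCT")

    def __post_init__(self) -> None:
        if self.n_monomers < 1:
            raise ValueError("n_monomers must be >= 1")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")

    @property
    def label(self) -> str:
        """Conventional name, e.g. ``TRI6+`` for the 6+ trimer."""
        if self.n_monomers <= len(self._NAMES):
            stem = self._NAMES[self.n_monomers - 1]
        else:
            stem = f"{self.n_monomers}MER"
        return f"{stem}{self.charge}+"


# ---------------------------------------------------------------------------
# sequence and composition

_FASTA_HEADER = re.compile(r"^>")


def parse_sequence(text: str) -> PeptideSpec:
    """Parse a one-letter sequence string into a :class:`PeptideSpec`.

    Whitespace is stripped; a non-canonical character raises ``ValueError``
    naming its (1-based) position.
    """
    seq = "".join(text.split()).upper()
    return PeptideSpec(seq)


def read_fasta_sequence(path: str) -> PeptideSpec:
    """Read the first record of a FASTA file."""
    lines = []
    with open(path) as fh:
        seen_header = False
        for line in fh:
            if _FASTA_HEADER.match(line):
                if seen_header:
                    break
                seen_header = True
                continue
            lines.append(line.strip())
    if not lines:
        raise ValueError(f"no sequence found in {path}")
    return parse_sequence("".join(lines))


def composition(p: PeptideSpec) -> ElementalComposition:
    """Elemental composition: residue sum plus one water for the free termini."""
    counts: dict[str, int] = {"H": 2, "O": 1}  # terminal H + OH
    for aa in p.sequence:
        for el, n in _pmass.std_aa_comp[aa].items():
            counts[el] = counts.get(el, 0) + n
    return ElementalComposition(counts)


def _isotopes(el: str) -> list[tuple[float, float]]:
    """(mass, abundance) pairs of an element's stable isotopes."""
    table = _pmass.nist_mass.get(el)
    if table is None:
        raise ValueError(f"unknown element {el!r}")
    iso = [(m, a) for num, (m, a) in table.items() if num != 0 and a > 0]
    if not iso:
        raise ValueError(f"no natural abundance data for {el!r}")
    return sorted(iso)


def average_mass(c: ElementalComposition) -> float:
    """Abundance-weighted molecular mass, Da."""
    total = 0.0
    for el, n in c.items():
        total += n * sum(m * a for m, a in _isotopes(el))
    return total


def monoisotopic_mass(c: ElementalComposition) -> float:
    """Mass built from each element's lightest stable isotope, Da."""
    total = 0.0
    for el, n in c.items():
        total += n * _isotopes(el)[0][0]
    return total


def _convolve_patterns(
    p1: np.ndarray, m1: np.ndarray, p2: np.ndarray, m2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Convolve two aggregated patterns on the integer mass-number lattice.

    Each pattern carries, per nominal-mass bin, its total probability and the
    probability-weighted mean mass of that bin (fine structure within a bin
    is collapsed to its centroid).
    """
    probs = np.convolve(p1, p2)
    moment = np.convolve(p1 * m1, p2) + np.convolve(p1, p2 * m2)
    with np.errstate(invalid="ignore", divide="ignore"):
        masses = np.where(probs > 0, moment / np.where(probs > 0, probs, 1.0), 0.0)
    return probs, masses


def _element_pattern(el: str, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Aggregated isotope pattern of ``n`` atoms of ``el`` via binary squaring."""
    iso = _isotopes(el)
    base = round(iso[0][0])
    size = round(iso[-1][0]) - base + 1
    p = np.zeros(size)
    m = np.zeros(size)
    for mass_val, ab in iso:
        k = round(mass_val) - base
        m[k] = (m[k] * p[k] + mass_val * ab) / (p[k] + ab) if p[k] + ab > 0 else 0.0
        p[k] += ab
    acc_p, acc_m = np.array([1.0]), np.array([0.0])
    cur_p, cur_m = p, m
    while n:
        if n & 1:
            acc_p, acc_m = _convolve_patterns(acc_p, acc_m, cur_p, cur_m)
            acc_p, acc_m = _trim(acc_p, acc_m)
        n >>= 1
        if n:
            cur_p, cur_m = _convolve_patterns(cur_p, cur_m, cur_p, cur_m)
            cur_p, cur_m = _trim(cur_p, cur_m)
    return acc_p, acc_m


def _trim(p: np.ndarray, m: np.ndarray, eps: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    keep = np.nonzero(p >= eps * p.max())[0]
    # keep a contiguous block so lattice indexing stays aligned
    lo, hi = keep[0], keep[-1] + 1
    p2 = p[lo:hi].copy()
    m2 = m[lo:hi] + 0.0
    if lo:
        # masses are absolute per-bin centroids, no offset bookkeeping needed
        pass
    return p2, m2


def natural_isotope_distribution(
    c: ElementalComposition, prune: float = 1e-6
) -> IsotopeDistribution:
    """Natural-abundance isotope envelope of a composition.

    Exact elemental-pattern convolution aggregated on the nominal-mass
    lattice (fine structure within one nominal mass is centroided), pruned at
    ``prune`` relative probability and renormalized.
    """
    if not c:
        raise ValueError("empty composition")
    acc_p, acc_m = np.array([1.0]), np.array([0.0])
    for el, n in sorted(c.items()):
        ep, em = _element_pattern(el, n)
        acc_p, acc_m = _convolve_patterns(acc_p, acc_m, ep, em)
        acc_p, acc_m = _trim(acc_p, acc_m)
    keep = acc_p >= prune * acc_p.max()
    masses, probs = acc_m[keep], acc_p[keep]
    order = np.argsort(masses)
    return IsotopeDistribution(masses[order], probs[order], "mass")


def mz(mass_da: float, ion: OligomerIon) -> float:
    """m/z of an oligomer ion: ``(n * M + z * m_p) / z`` (proton adducts)."""
    return (ion.n_monomers * mass_da + ion.charge * PROTON_MASS) / ion.charge


# ---------------------------------------------------------------------------
# exchangeable-proton inventory


def exchangeable_protons(
    p: PeptideSpec,
    region: tuple[int, int] | None = None,
    table: ExchangeTable = DEFAULT_EXCHANGE_TABLE,
) -> int:
    """Count exchangeable side-chain/terminus hydrogens over a residue range.

    ``region`` is a 1-based inclusive ``(first, last)`` pair; terminus
    hydrogens are included only when the region touches that terminus.  For
    wild-type amyloid-beta 1-40 the full chain gives 27, residues 1-16 give
    19 and residues 17-40 give 8.
    """
    n = len(p)
    lo, hi = region if region is not None else (1, n)
    if not (1 <= lo <= hi <= n):
        raise ValueError(f"region ({lo}, {hi}) out of bounds for length {n}")
    total = sum(table.count(aa) for aa in p.sequence[lo - 1 : hi])
    if lo == 1:
        total += table.n_term
    if hi == n:
        total += table.c_term
    return total


def total_exchangeable(ion: OligomerIon, per_monomer: int, charge_protons_exchange: bool = True) -> int:
    """Total exchangeable protons of an oligomer ion.

    Each monomer contributes its neutral-form count; in positive mode the
    charging protons are themselves exchangeable and add ``charge`` more
    (the 5+ monomer of amyloid-beta 1-40: 27 + 5 = 32).
    """
    if per_monomer < 0:
        raise ValueError("per_monomer must be non-negative")
    extra = ion.charge if charge_protons_exchange else 0
    return ion.n_monomers * per_monomer + extra
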