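"""Oligomer/charge-state assignment and drift-time conformer detection.

Native ESI spectra of an oligomerizing peptide contain isobaric families:
every (n-mer, charge) pair with the same charge per monomer (CpM = z/n)
lands in the same m/z window and can only be told apart by the isotope-peak
spacing (1/z) or by ion-mobility drift time.  This module enumerates such
families, infers charge from peak spacing, projects 2-D IM-MS maps onto the
drift axis, detects compact/extended conformer splits, and slices the map at
a chosen drift time to obtain conformer-specific envelopes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .peptide_chemistry import ISOTOPE_SPACING, OligomerIon, mz
from .spectra import CentroidList, Spectrum

__all__ = [
    "IsobarFamily",
    "DriftMap",
    "DriftProfile",
    "ChargeCall",
    "ConformerPeak",
    "charge_per_monomer",
    "isobar_family",
    "infer_charge_from_spacing",
    "drift_profile",
    "detect_conformer_split",
    "slice_envelope_at_drift",
]


def charge_per_monomer(ion: OligomerIon) -> float:
    """Charge density CpM = z / n; equal-CpM ions of one peptide are isobars."""
    return ion.charge / ion.n_monomers


@dataclass(frozen=True)
class IsobarFamily:
    """All (n-mer, charge) ions of one monomer mass sharing an m/z window."""

    window: tuple[float, float]
    members: tuple[OligomerIon, ...]
    monomer_mass: float

    @property
    def common_cpm(self) -> float | None:
        """The shared charge density, if every member has the same one."""
        if not self.members:
            return None
        cpms = {round(charge_per_monomer(m), 9) for m in self.members}
        return charge_per_monomer(self.members[0]) if len(cpms) == 1 else None


def isobar_family(
    monomer_mass: float,
    window: tuple[float, float],
    n_max: int,
    z_max: int,
) -> IsobarFamily:
    """Enumerate all oligomer ions whose m/z falls inside ``window``."""
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must satisfy hi > lo")
    if n_max < 1 or z_max < 1:
        raise ValueError("n_max and z_max must be >= 1")
    members = [
        ion
        for n in range(1, n_max + 1)
        for z in range(1, z_max + 1)
        if lo <= mz(monomer_mass, ion := OligomerIon(n, z)) <= hi
    ]
    members.sort(key=lambda m: (m.n_monomers, m.charge))
    return IsobarFamily((lo, hi), tuple(members), monomer_mass)


@dataclass(frozen=True)
class ChargeCall:
    """Charge inferred from isotope spacing, with a dispersion-based confidence."""

    charge: int | None
    confidence: float
    mixed: bool = False

    @property
    def status(self) -> str:
        return "unassignable" if self.charge is None else "assigned"


def infer_charge_from_spacing(
    c: CentroidList,
    spacing_constant: float = ISOTOPE_SPACING,
    max_dispersion: float = 0.20,
    min_rel_area: float = 0.05,
    z_max: int = 16,
) -> ChargeCall:
    """Read the charge off the isotope comb: z = round(spacing / gap).

    Uses the median adjacent spacing of peaks above ``min_rel_area`` of the
    strongest peak; relative spacing dispersion beyond ``max_dispersion``
    yields an unassignable call.  In an overlapped comb (two charges in one
    window) the finest spacing dominates, so the higher, dominant charge is
    returned; a strongly periodic area pattern across the comb flags the
    call as mixed.
    """
    sel = c.areas >= min_rel_area * c.areas.max() if len(c) else np.array([], bool)
    pos = c.positions[sel]
    area = c.areas[sel]
    if pos.size < 3:
        raise ValueError("need at least 3 resolved isotope peaks")
    gaps = np.diff(pos)
    med = float(np.median(gaps))
    disp = float(np.std(gaps) / med) if med > 0 else np.inf
    if med <= 0 or disp > max_dispersion:
        return ChargeCall(None, 0.0)
    z = int(round(spacing_constant / med))
    if z < 1 or z > z_max:
        return ChargeCall(None, 0.0)
    confidence = float(max(0.0, 1.0 - disp / max_dispersion))
    # mixed-comb heuristic: if peak areas at some stride k (2..4) are
    # systematically larger, a coarser comb is superposed on this one
    mixed = False
    for k in (2, 3, 4):
        if area.size < 2 * k:
            continue
        means = [area[r::k].mean() for r in range(k)]
        if max(means) > 3.0 * (sum(means) - max(means)) / (k - 1):
            mixed = True
            break
    return ChargeCall(z, confidence, mixed)


@dataclass
class DriftMap:
    """2-D IM-MS data: intensity over an (m/z, drift time) grid."""

    mz: np.ndarray          # (M,) ascending m/z
    drift: np.ndarray       # (T,) ascending drift time, ms
    intensity: np.ndarray   # (M, T) non-negative

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.drift = np.asarray(self.drift, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.mz.size, self.drift.size):
            raise ValueError("intensity must be shaped (len(mz), len(drift))")
        if np.any(np.diff(self.mz) <= 0) or np.any(np.diff(self.drift) <= 0):
            raise ValueError("mz and drift axes must be strictly increasing")
        if np.any(self.drift < 0):
            raise ValueError("drift times must be non-negative")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def to_triples_text(self, path: str) -> None:
        """Write sparse three-column text: mz, drift_ms, intensity (non-zero)."""
        with open(path, "w") as fh:
            fh.write("# mz drift_ms intensity\n")
            for i, x in enumerate(self.mz):
                for j, t in enumerate(self.drift):
                    v = self.intensity[i, j]
                    if v > 0:
                        fh.write(f"{x:.9g} {t:.9g} {v:.9g}\n")

    @classmethod
    def from_triples_text(cls, path: str) -> "DriftMap":
        data = np.loadtxt(path, ndmin=2, comments="#")
        if data.size == 0 or data.shape[1] != 3:
            raise ValueError(f"{path}: expected three columns (mz, drift, intensity)")
        mz_axis = np.unique(data[:, 0])
        dt_axis = np.unique(data[:, 1])
        grid = np.zeros((mz_axis.size, dt_axis.size))
        i = np.searchsorted(mz_axis, data[:, 0])
        j = np.searchsorted(dt_axis, data[:, 1])
        grid[i, j] += data[:, 2]
        return cls(mz_axis, dt_axis, grid)


@dataclass
class DriftProfile:
    """Intensity versus drift time, summed over an m/z window."""

    drift: np.ndarray
    intensity: np.ndarray
    window: tuple[float, float]

    def __post_init__(self) -> None:
        self.drift = np.asarray(self.drift, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.drift.shape != self.intensity.shape:
            raise ValueError("drift and intensity must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


def drift_profile(dmap: DriftMap, window: tuple[float, float]) -> DriftProfile:
    """Project an m/z window of the map onto the drift-time axis."""
    lo, hi = window
    sel = (dmap.mz >= lo) & (dmap.mz <= hi)
    if not sel.any():
        raise ValueError(f"m/z window {window} does not overlap the map")
    return DriftProfile(dmap.drift.copy(), dmap.intensity[sel].sum(axis=0), (lo, hi))


@dataclass(frozen=True)
class ConformerPeak:
    """One drift-time population: apex (ms), share of the profile, label."""

    apex_ms: float
    share: float
    label: str


def detect_conformer_split(
    p: DriftProfile,
    min_prominence: float = 0.10,
) -> list[ConformerPeak]:
    """Find drift-time populations; two or more means a conformer split.

    Local maxima with prominence of at least ``min_prominence`` of the
    profile maximum are kept; shares come from valley-to-valley integration
    after subtracting a flat baseline (the mean of the lowest-quartile bins,
    robust against the positive offset left by noise clipped at zero).
    The shortest-drift apex is labelled ``compact``, the longest
    ``extended`` (matching the usual ordering of collisional cross section
    at fixed charge); any in between are ``intermediate``.
    """
    y = p.intensity
    if y.max() <= 0:
        raise ValueError("empty drift profile")
    quartile = np.sort(y)[: max(1, y.size // 4)]
    y = np.clip(y - quartile.mean(), 0.0, None)
    apexes, _ = find_peaks(y, prominence=min_prominence * y.max())
    if apexes.size == 0:
        apexes = np.array([int(np.argmax(y))])
    bounds = [0]
    for a, b in zip(apexes[:-1], apexes[1:]):
        bounds.append(a + int(np.argmin(y[a : b + 1])))
    bounds.append(y.size - 1)
    total = y.sum()
    peaks = []
    for i, apex in enumerate(apexes):
        share = float(y[bounds[i] : bounds[i + 1] + 1].sum() / total)
        peaks.append((float(p.drift[apex]), share))
    # renormalize (valley bins are shared between neighbours)
    s = sum(sh for _, sh in peaks)
    out: list[ConformerPeak] = []
    for i, (apex_ms, share) in enumerate(peaks):
        if len(peaks) == 1:
            label = "single"
        elif i == 0:
            label = "compact"
        elif i == len(peaks) - 1:
            label = "extended"
        else:
            label = "intermediate"
        out.append(ConformerPeak(apex_ms, share / s, label))
    return out


def slice_envelope_at_drift(
    dmap: DriftMap,
    drift_apex: float,
    half_width: float,
) -> Spectrum:
    """m/z spectrum summed over a drift slab around ``drift_apex``.

    A zero half-width selects the single nearest drift bin.  Feeds
    conformer-specific deconvolution (compact versus extended uptake).
    """
    if not dmap.drift[0] <= drift_apex <= dmap.drift[-1]:
        raise ValueError(
            f"drift apex {drift_apex} outside map range "
            f"[{dmap.drift[0]}, {dmap.drift[-1]}]"
        )
    if half_width < 0:
        raise ValueError("half_width must be non-negative")
    if half_width == 0:
        j = int(np.argmin(np.abs(dmap.drift - drift_apex)))
        inten = dmap.intensity[:, j]
    else:
        sel = np.abs(dmap.drift - drift_apex) <= half_width
        if not sel.any():
            raise ValueError("empty drift slab")
        inten = dmap.intensity[:, sel].sum(axis=1)
    return Spectrum(dmap.mz.copy(), inten,
                    {"drift_apex_ms": drift_apex, "half_width_ms": half_width})
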