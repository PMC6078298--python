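"""Spectrum I/O, smoothing, centroiding and uptake arithmetic.

Raw envelopes come in as plain two-column text (m/z, intensity; whitespace
or comma separated) or mzML.  Processing follows the conventional HDX-MS
route: Savitzky-Golay smoothing, peak centering (intensity-weighted
centroids over valley-split peak supports), and centroid-difference uptake
relative to an undeuterated control, normalized per monomeric unit
(the HDX/M quantity).

The mzML writer here is deliberately minimal (one MS1 spectrum per scan,
64-bit float arrays, no compression); it exists so synthetic fixtures can be
round-tripped through the same reader path as instrument exports.
"""

from __future__ import annotations

import base64
import struct
import warnings
import zlib
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
from lxml import etree
from scipy.signal import find_peaks, savgol_filter

from .exchange_model import DELTA_M_D
from .peptide_chemistry import PROTON_MASS, OligomerIon

__all__ = [
    "Spectrum",
    "CentroidList",
    "read_spectrum",
    "write_spectrum_xy",
    "write_mzml",
    "smooth",
    "centroid",
    "weighted_centroid",
    "uptake",
    "to_monomer_mass_domain",
]


@dataclass
class Spectrum:
    """A 1-D profile or centroided spectrum with free-form metadata labels."""

    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size == 0:
            raise ValueError("spectrum must be non-empty")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass
class CentroidList:
    """Centered peaks: (position, area) pairs on an m/z or mass axis."""

    positions: np.ndarray
    areas: np.ndarray
    domain: str = "m/z"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.positions.shape != self.areas.shape or self.positions.ndim != 1:
            raise ValueError("positions and areas must be 1-D arrays of equal length")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.areas < 0):
            raise ValueError("areas must be non-negative")

    def __len__(self) -> int:
        return int(self.positions.size)

    def to_tsv(self) -> str:
        lines = ["position\tarea\tdomain"]
        for p, a in zip(self.positions, self.areas):
            lines.append(f"{p:.6f}\t{a:.8e}\t{self.domain}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "CentroidList":
        rows = [ln.split("\t") for ln in text.strip().splitlines()[1:]]
        if not rows:
            return cls(np.array([]), np.array([]))
        pos = np.array([float(r[0]) for r in rows])
        area = np.array([float(r[1]) for r in rows])
        return cls(pos, area, rows[0][2])


# ---------------------------------------------------------------------------
# I/O


def read_spectrum(
    path: str,
    format: str = "xy",
    average: bool = False,
    scan: int = 0,
    metadata: dict | None = None,
) -> Spectrum:
    """Read a spectrum from two-column text or mzML.

    For mzML, ``scan`` selects one spectrum; ``average=True`` averages the
    intensities of all scans instead (requires a shared m/z grid).
    """
    meta = dict(metadata or {})
    meta.setdefault("path", str(path))
    if format == "xy":
        return _read_xy(path, meta)
    if format == "mzML":
        return _read_mzml(path, meta, average=average, scan=scan)
    raise ValueError(f"unknown format {format!r} (expected 'xy' or 'mzML')")


def _read_xy(path: str, meta: dict) -> Spectrum:
    try:
        text = open(path).read()
    except OSError as exc:
        raise ValueError(f"cannot read {path}: {exc}") from exc
    cleaned = text.replace(",", " ").replace(";", " ")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # loadtxt warns on empty input
            data = np.loadtxt(StringIO(cleaned), ndmin=2, comments="#")
    except ValueError as exc:
        raise ValueError(f"malformed two-column file {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"empty spectrum file {path}")
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns, got {data.shape[1]}")
    order = np.argsort(data[:, 0], kind="stable")
    return Spectrum(data[order, 0], data[order, 1], meta)


def _decode_binary_array(bda, path: str) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array kind, values)."""
    kind = None
    dtype = "<d"
    compressed = False
    for cv in bda.iterfind(f"{{{_MZML_NS}}}cvParam"):
        acc = cv.get("accession", "")
        if acc == "MS:1000514":
            kind = "mz"
        elif acc == "MS:1000515":
            kind = "intensity"
        elif acc == "MS:1000521":
            dtype = "<f"
        elif acc == "MS:1000523":
            dtype = "<d"
        elif acc == "MS:1000574":
            compressed = True
    binary = bda.find(f"{{{_MZML_NS}}}binary")
    if binary is None or not (binary.text or "").strip():
        return kind, np.array([])
    raw = base64.b64decode(binary.text)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: str, meta: dict, average: bool, scan: int) -> Spectrum:
    """Minimal namespaced mzML reader (MS1 spectra, 32/64-bit float arrays,
    plain or zlib-compressed binary)."""
    try:
        tree = etree.parse(path)
    except (OSError, etree.XMLSyntaxError) as exc:
        raise ValueError(f"malformed mzML file {path}: {exc}") from exc
    scans = []
    for sp in tree.iter(f"{{{_MZML_NS}}}spectrum"):
        arrays: dict[str, np.ndarray] = {}
        for bda in sp.iter(f"{{{_MZML_NS}}}binaryDataArray"):
            kind, values = _decode_binary_array(bda, path)
            if kind:
                arrays[kind] = values
        if "mz" not in arrays or "intensity" not in arrays:
            raise ValueError(
                f"{path}: spectrum {sp.get('id', '?')} lacks m/z or intensity array")
        scans.append((arrays["mz"], arrays["intensity"]))
    if not scans:
        raise ValueError(f"no spectra in mzML file {path}")
    if average:
        grid = scans[0][0]
        for m, _ in scans[1:]:
            if m.shape != grid.shape or not np.allclose(m, grid):
                raise ValueError(f"{path}: scans lack a shared m/z grid; cannot average")
        inten = np.mean([i for _, i in scans], axis=0)
        meta["n_scans_averaged"] = len(scans)
        return Spectrum(grid, inten, meta)
    if not 0 <= scan < len(scans):
        raise ValueError(f"{path}: scan index {scan} out of range ({len(scans)} scans)")
    meta["scan"] = scan
    return Spectrum(scans[scan][0], scans[scan][1], meta)


def write_spectrum_xy(spectrum: Spectrum, path: str) -> None:
    """Write plain two-column text (m/z, intensity)."""
    with open(path, "w") as fh:
        for x, y in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{x:.9g} {y:.9g}\n")


_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _binary_array(parent, name_accession: tuple[str, str], values: np.ndarray) -> None:
    raw = struct.pack(f"<{values.size}d", *values.astype(float))
    b64 = base64.b64encode(raw).decode("ascii")
    arr = etree.SubElement(parent, "binaryDataArray", encodedLength=str(len(b64)))
    for acc, nm, val in (
        ("MS:1000523", "64-bit float", ""),
        ("MS:1000576", "no compression", ""),
        (name_accession[1], name_accession[0], ""),
    ):
        etree.SubElement(arr, "cvParam", cvRef="MS", accession=acc, name=nm, value=val)
    etree.SubElement(arr, "binary").text = b64


def write_mzml(spectra: list[Spectrum] | Spectrum, path: str) -> None:
    """Write one or more MS1 spectra as minimal uncompressed mzML."""
    if isinstance(spectra, Spectrum):
        spectra = [spectra]
    root = etree.Element("mzML", xmlns=_MZML_NS, version="1.1.0")
    cv_list = etree.SubElement(root, "cvList", count="1")
    etree.SubElement(
        cv_list, "cv", id="MS", fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    run = etree.SubElement(root, "run", id="synthetic")
    slist = etree.SubElement(run, "spectrumList", count=str(len(spectra)))
    for i, sp in enumerate(spectra):
        el = etree.SubElement(
            slist, "spectrum", index=str(i), id=f"scan={i + 1}",
            defaultArrayLength=str(len(sp)),
        )
        etree.SubElement(el, "cvParam", cvRef="MS", accession="MS:1000511",
                         name="ms level", value="1")
        etree.SubElement(el, "cvParam", cvRef="MS", accession="MS:1000128",
                         name="profile spectrum", value="")
        bdal = etree.SubElement(el, "binaryDataArrayList", count="2")
        _binary_array(bdal, ("m/z array", "MS:1000514"), sp.mz)
        _binary_array(bdal, ("intensity array", "MS:1000515"), sp.intensity)
    etree.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8",
                                  pretty_print=True)


# ---------------------------------------------------------------------------
# processing


def smooth(s: Spectrum, window: int = 5, polyorder: int = 3,
           passes: int = 1) -> Spectrum:
    """Savitzky-Golay smoothing, repeated ``passes`` times.

    Defaults follow the common "(3, 5)" convention read as polynomial order 3
    over a 5-point window; both are exposed because the vendor shorthand is
    ambiguous.  Negative filter undershoot (possible next to sharp features)
    is floored at zero to keep intensities physical.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(s):
        raise ValueError(f"window {window} larger than spectrum ({len(s)} points)")
    if window < polyorder + 2:
        raise ValueError("window must be >= polyorder + 2")
    if passes < 0:
        raise ValueError("passes must be non-negative")
    y = s.intensity.copy()
    for _ in range(passes):
        y = savgol_filter(y, window, polyorder)
    return Spectrum(s.mz.copy(), np.clip(y, 0.0, None), dict(s.metadata))


def centroid(
    s: Spectrum,
    min_rel_height: float = 0.01,
    min_height: float | None = None,
) -> CentroidList:
    """Center peaks: local maxima with valley-split supports.

    Each local maximum above ``min_height`` (absolute, optional) claims the
    contiguous points around it down to the valley shared with the next peak,
    restricted to points at least ``min_rel_height`` of its own apex.  The
    centroid is the intensity-weighted mean position over that support; the
    area is the summed intensity.
    """
    y = s.intensity
    if y.max() <= 0:
        return CentroidList(np.array([]), np.array([]), "m/z")
    apexes, _ = find_peaks(y)
    if apexes.size == 0:  # monotone or single-point spectra: use global max
        apexes = np.array([int(np.argmax(y))])
    if min_height is not None:
        apexes = apexes[y[apexes] >= min_height]
    if apexes.size == 0:
        return CentroidList(np.array([]), np.array([]), "m/z")
    # valley boundaries between consecutive kept apexes
    bounds = [0]
    for a, b in zip(apexes[:-1], apexes[1:]):
        bounds.append(a + int(np.argmin(y[a : b + 1])))
    bounds.append(len(y) - 1)
    positions, areas = [], []
    for i, apex in enumerate(apexes):
        lo, hi = bounds[i], bounds[i + 1]
        seg = np.arange(lo, hi + 1)
        floor = min_rel_height * y[apex]
        # contiguous support around the apex, clipped at the relative floor
        mask = y[seg] >= floor
        apos = int(np.searchsorted(seg, apex))
        left = apos
        while left > 0 and mask[left - 1]:
            left -= 1
        right = apos
        while right < len(seg) - 1 and mask[right + 1]:
            right += 1
        sup = seg[left : right + 1]
        w = y[sup]
        positions.append(float(np.dot(s.mz[sup], w) / w.sum()))
        areas.append(float(w.sum()))
    order = np.argsort(positions)
    pos = np.array(positions)[order]
    area = np.array(areas)[order]
    keep = np.concatenate([[True], np.diff(pos) > 0])
    return CentroidList(pos[keep], area[keep], "m/z")


def weighted_centroid(c: CentroidList, window: tuple[float, float] | None = None) -> float:
    """Intensity-weighted centroid of the peaks inside ``window``."""
    if window is None:
        sel = np.ones(len(c), dtype=bool)
    else:
        lo, hi = window
        sel = (c.positions >= lo) & (c.positions <= hi)
    if not sel.any():
        raise ValueError(f"no peaks in window {window}")
    pos, area = c.positions[sel], c.areas[sel]
    if area.sum() <= 0:
        raise ValueError("zero total area in window")
    return float(np.dot(pos, area) / area.sum())


def uptake(
    deut: float,
    control: float,
    ion: OligomerIon,
    negative_tolerance: float = 0.5,
) -> float:
    """Deuterons exchanged per monomer from an m/z centroid difference.

    ``(deut - control) * charge / (DELTA_M_D * n_monomers)`` — the HDX/M
    quantity.  A negative value beyond ``negative_tolerance`` deuterons is
    flagged with a warning but still returned.
    """
    value = (deut - control) * ion.charge / (DELTA_M_D * ion.n_monomers)
    if value < -negative_tolerance:
        warnings.warn(
            f"negative uptake {value:.2f} D/monomer for {ion.label}; "
            "check control pairing", stacklevel=2,
        )
    return value


def to_monomer_mass_domain(c: CentroidList, ion: OligomerIon) -> CentroidList:
    """Convert m/z centroids to the mass of one monomeric unit, Da.

    Inverts the proton-adduct m/z relation and divides by the oligomer
    order: ``(pos * z - z * m_p) / n``.  Equal-charge-density isobars map to
    identical monomer-domain masses.
    """
    if c.domain != "m/z":
        raise ValueError(f"expected m/z-domain centroids, got {c.domain!r}")
    pos = (c.positions * ion.charge - ion.charge * PROTON_MASS) / ion.n_monomers
    return CentroidList(pos, c.areas.copy(), "Da")
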