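"""Config-driven end-to-end runs and replicate comparison.

One run takes a control spectrum (no ND3) and a deuterated spectrum, plus
optionally a 2-D IM-MS map, and produces for every assigned oligomer ion:
the centroid uptake per monomer (HDX/M), the single-state mixture
decomposition, the charge density, and — when drift data is present — the
conformer split with conformer-specific decompositions.  Reports are
serializable to JSON and TSV and embed the resolved configuration for
provenance; identical configs reproduce reports bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .assignment import (
    DriftMap,
    charge_per_monomer,
    detect_conformer_split,
    drift_profile,
    slice_envelope_at_drift,
)
from .deconvolution import DeconvConfig, deconvolve_envelope
from .exchange_model import DELTA_M_D
from .peptide_chemistry import (
    DEFAULT_EXCHANGE_TABLE,
    OligomerIon,
    average_mass,
    composition,
    exchangeable_protons,
    monoisotopic_mass,
    mz,
    parse_sequence,
    total_exchangeable,
)
from .spectra import (
    CentroidList,
    centroid,
    read_spectrum,
    smooth,
    uptake,
    weighted_centroid,
)

log = logging.getLogger("hdxim")

__all__ = ["IonSpec", "RunConfig", "IonReport", "RunReport", "run", "compare_variants"]


@dataclass(frozen=True)
class IonSpec:
    """One ion to analyze; the m/z window defaults to the theoretical span."""

    n_monomers: int
    charge: int
    window: tuple[float, float] | None = None

    @property
    def ion(self) -> OligomerIon:
        return OligomerIon(self.n_monomers, self.charge)


@dataclass(frozen=True)
class RunConfig:
    """Resolved inputs and parameters of one end-to-end run."""

    control: str
    sequence: str
    ions: tuple[IonSpec, ...]
    deuterated: str | None = None
    drift_map: str | None = None
    control_format: str = "xy"
    deuterated_format: str = "xy"
    smooth_window: int = 5
    smooth_polyorder: int = 3
    smooth_passes: int = 1
    centroid_threshold: float = 0.01
    centroid_min_height: float | None = None
    deconv: DeconvConfig = field(default_factory=DeconvConfig)
    split_prominence: float = 0.10
    drift_half_width_ms: float = 0.5
    window_pad_mz: float = 1.0
    window_min_rel_area: float = 0.01  # noise floor within each ion window
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        ions = tuple(
            IonSpec(d["n_monomers"], d["charge"],
                    tuple(d["window"]) if d.get("window") else None)
            for d in data.pop("ions")
        )
        deconv = DeconvConfig(**data.pop("deconv", {}))
        return cls(ions=ions, deconv=deconv, **data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ConformerReport:
    label: str
    drift_apex_ms: float
    share: float
    uptake_per_monomer: float | None
    components: list[tuple[float, float]] | None


@dataclass
class IonReport:
    label: str
    n_monomers: int
    charge: int
    cpm: float
    window: tuple[float, float]
    control_centroid_mz: float
    deuterated_centroid_mz: float | None
    uptake_per_monomer: float | None
    components: list[tuple[float, float]] | None
    residual_norm: float | None
    split: bool | None
    conformers: list[ConformerReport] | None


@dataclass
class RunReport:
    ions: list[IonReport]
    config: dict
    version: str
    seed: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=_jsonable)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.ions:
            base = {
                "ion": r.label, "n_monomers": r.n_monomers, "charge": r.charge,
                "cpm": round(r.cpm, 4), "uptake_per_monomer": r.uptake_per_monomer,
                "split": r.split,
            }
            if r.components:
                for u, w in r.components:
                    rows.append({**base, "component_uptake": u, "component_weight": w})
            else:
                rows.append(base)
        return pd.DataFrame(rows)

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index=False)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _window_subset(c: CentroidList, window: tuple[float, float],
                   min_rel_area: float = 0.0) -> CentroidList:
    lo, hi = window
    sel = (c.positions >= lo) & (c.positions <= hi)
    pos, area = c.positions[sel], c.areas[sel]
    if min_rel_area > 0 and area.size:
        keep = area >= min_rel_area * area.max()
        pos, area = pos[keep], area[keep]
    return CentroidList(pos, area, c.domain)


def _default_window(ion: OligomerIon, mono_mass: float, avg_mass: float,
                    n_sites: int, pad: float) -> tuple[float, float]:
    # the envelope opens at the monoisotopic peak, not at the average mass
    low_edge = mz(mono_mass, ion)
    span = n_sites * DELTA_M_D / ion.charge
    return (low_edge - pad, mz(avg_mass, ion) + span + pad)


def _preprocess(path: str, fmt: str, cfg: RunConfig, label: str) -> CentroidList:
    t0 = time.perf_counter()
    spec = read_spectrum(path, fmt, metadata={"role": label})
    smoothed = smooth(spec, cfg.smooth_window, cfg.smooth_polyorder, cfg.smooth_passes)
    cents = centroid(smoothed, cfg.centroid_threshold, cfg.centroid_min_height)
    log.info("%s: %d points -> %d centroids (%.2f s)",
             label, len(spec), len(cents), time.perf_counter() - t0)
    return cents


def run(cfg: RunConfig) -> RunReport:
    """Execute read -> smooth -> centroid -> assign -> uptake -> deconvolve."""
    peptide = parse_sequence(cfg.sequence)
    per_monomer = exchangeable_protons(peptide, table=DEFAULT_EXCHANGE_TABLE)
    comp = composition(peptide)
    avg_mass = average_mass(comp)
    mono_mass = monoisotopic_mass(comp)

    ctrl_cents = _preprocess(cfg.control, cfg.control_format, cfg, "control")
    deut_cents = (
        _preprocess(cfg.deuterated, cfg.deuterated_format, cfg, "deuterated")
        if cfg.deuterated else None
    )
    dmap = DriftMap.from_triples_text(cfg.drift_map) if cfg.drift_map else None

    reports: list[IonReport] = []
    for spec_ion in cfg.ions:
        ion = spec_ion.ion
        n_sites = total_exchangeable(ion, per_monomer)
        window = spec_ion.window or _default_window(
            ion, mono_mass, avg_mass, n_sites, cfg.window_pad_mz)
        ctrl_w = _window_subset(ctrl_cents, window, cfg.window_min_rel_area)
        if len(ctrl_w) == 0:
            raise ValueError(f"{ion.label}: no control peaks in window {window}")
        c0 = weighted_centroid(ctrl_w)
        # the control envelope itself sits at the low-mass end of the window
        ctrl_env = _window_subset(
            ctrl_cents, (window[0], c0 + 4 * DELTA_M_D / ion.charge))

        deut_centroid = uptake_pm = None
        comps = res_norm = None
        split = None
        conf_reports = None
        if deut_cents is not None:
            deut_w = _window_subset(deut_cents, window, cfg.window_min_rel_area)
            if len(deut_w) == 0:
                raise ValueError(f"{ion.label}: no deuterated peaks in window {window}")
            deut_centroid = weighted_centroid(deut_w)
            uptake_pm = uptake(deut_centroid, c0, ion)
            result = deconvolve_envelope(ctrl_env, deut_w, ion, per_monomer,
                                         cfg.deconv)
            comps = [list(c) for c in result.components]
            res_norm = result.residual_norm

        if dmap is not None:
            profile = drift_profile(dmap, window)
            peaks = detect_conformer_split(profile, cfg.split_prominence)
            split = len(peaks) >= 2
            conf_reports = []
            for pk in peaks:
                conf_uptake = conf_comps = None
                if deut_cents is not None:
                    sl = slice_envelope_at_drift(dmap, pk.apex_ms,
                                                 cfg.drift_half_width_ms)
                    sl_sm = smooth(sl, cfg.smooth_window, cfg.smooth_polyorder,
                                   cfg.smooth_passes)
                    sl_cents = _window_subset(
                        centroid(sl_sm, cfg.centroid_threshold), window,
                        cfg.window_min_rel_area)
                    if len(sl_cents):
                        conf_uptake = uptake(weighted_centroid(sl_cents), c0, ion)
                        conf_res = deconvolve_envelope(ctrl_env, sl_cents, ion,
                                                       per_monomer, cfg.deconv)
                        conf_comps = [list(c) for c in conf_res.components]
                conf_reports.append(ConformerReport(
                    pk.label, pk.apex_ms, pk.share, conf_uptake, conf_comps))

        reports.append(IonReport(
            label=ion.label, n_monomers=ion.n_monomers, charge=ion.charge,
            cpm=charge_per_monomer(ion), window=tuple(window),
            control_centroid_mz=c0, deuterated_centroid_mz=deut_centroid,
            uptake_per_monomer=uptake_pm, components=comps,
            residual_norm=res_norm, split=split, conformers=conf_reports,
        ))

    report = RunReport(reports, cfg.to_dict(), _version, cfg.seed)
    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        (out / "report.tsv").write_text(report.to_tsv())
        log.info("report written to %s", out)
    return report


def compare_variants(reports: list[RunReport]) -> pd.DataFrame:
    """Uptake differences per monomer between equal-CpM oligomers and monomers.

    Within each report (one replicate), ions sharing a charge density are
    compared against the lowest-order member (the monomer of that density);
    differences are then aggregated across replicates (mean, SD, n).
    """
    rows = []
    for rep_idx, rep in enumerate(reports):
        by_cpm: dict[float, list[IonReport]] = {}
        for ion_rep in rep.ions:
            if ion_rep.uptake_per_monomer is None:
                continue
            by_cpm.setdefault(round(ion_rep.cpm, 6), []).append(ion_rep)
        for cpm, group in by_cpm.items():
            group = sorted(group, key=lambda r: r.n_monomers)
            base = group[0]
            for other in group[1:]:
                rows.append({
                    "pair": f"{other.label}-{base.label}",
                    "cpm": cpm,
                    "replicate": rep_idx,
                    "difference_d_per_monomer":
                        other.uptake_per_monomer - base.uptake_per_monomer,
                })
    if not rows:
        import warnings

        warnings.warn("no matching equal-CpM ion pairs across reports")
        return pd.DataFrame(
            columns=["pair", "cpm", "mean_difference", "sd", "n_replicates"])
    df = pd.DataFrame(rows)
    agg = (
        df.groupby(["pair", "cpm"])["difference_d_per_monomer"]
        .agg(mean_difference="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0,
             n_replicates="count")
        .reset_index()
    )
    return agg
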