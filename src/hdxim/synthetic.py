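"""Ground-truthed synthetic ESI spectra and IM-MS maps.

The forward model mirrors the assumptions of the analysis: each oligomeric
species is a mixture of conformers, each conformer exchanging as a single
equal-probability state with its own uptake fraction; envelopes sit at
proton-adduct m/z positions with Gaussian peak shapes, drift-time
populations are Gaussian, and noise is additive Gaussian (optionally
Poisson).  HDX reagent flow labels map to a purely phenomenological
multiplicative scaling of uptake fractions — lower make-up gas flow means
lower labeling, nothing mechanistic.

Every random draw flows through one ``numpy`` generator seeded from the
scenario config, so identical configs reproduce spectra bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .exchange_model import single_state
from .peptide_chemistry import (
    PROTON_MASS,
    DEFAULT_EXCHANGE_TABLE,
    ExchangeTable,
    OligomerIon,
    composition,
    exchangeable_protons,
    natural_isotope_distribution,
    parse_sequence,
    total_exchangeable,
    WT_ABETA_1_40,
    SCR_ABETA_1_40,
)
from .spectra import Spectrum, write_spectrum_xy
from .assignment import DriftMap

__all__ = [
    "FLOW_SCALING",
    "ConformerSpec",
    "SpeciesSpec",
    "ScenarioConfig",
    "GroundTruth",
    "simulate_spectrum",
    "simulate_drift_map",
    "fixture_suite",
]

#: Phenomenological uptake-fraction scaling per HDX reagent flow label
#: (mL/min of make-up gas).  Not a physical model of the ND3 chemistry.
FLOW_SCALING = {20: 0.4, 30: 0.6, 40: 0.8, 50: 1.0}


@dataclass(frozen=True)
class ConformerSpec:
    """One conformational state: uptake fraction, mixture weight, drift shape."""

    fraction: float
    weight: float
    drift_apex_ms: float | None = None
    drift_width_ms: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.weight <= 0:
            raise ValueError("weight must be positive")


@dataclass(frozen=True)
class SpeciesSpec:
    """One oligomer ion with abundance and its conformer mixture."""

    ion: OligomerIon
    abundance: float
    conformers: tuple[ConformerSpec, ...]

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")
        if not self.conformers:
            raise ValueError("at least one conformer required")
        total = sum(c.weight for c in self.conformers)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("conformer weights must sum to 1")


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to simulate one scenario deterministically."""

    sequence: str
    species: tuple[SpeciesSpec, ...]
    peak_sigma: float = 0.02          # m/z-domain Gaussian peak width
    noise_sigma: float = 0.01         # additive Gaussian sd, relative to max signal
    poisson_noise: bool = False
    flow_ml_min: int = 50             # HDX reagent flow label (see FLOW_SCALING)
    mz_step: float = 0.005
    mz_pad: float = 1.0
    drift_step_ms: float = 0.05
    seed: int = 0
    exchange_table: ExchangeTable = field(default=DEFAULT_EXCHANGE_TABLE)

    def __post_init__(self) -> None:
        parse_sequence(self.sequence)  # validates
        if self.peak_sigma <= 0 or self.mz_step <= 0:
            raise ValueError("peak_sigma and mz_step must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.flow_ml_min not in FLOW_SCALING:
            raise ValueError(f"flow label must be one of {sorted(FLOW_SCALING)}")
        if not self.species:
            raise ValueError("at least one species required")

    @property
    def flow_scale(self) -> float:
        return FLOW_SCALING[self.flow_ml_min]


@dataclass
class GroundTruth:
    """Exactly what the pipeline is expected to recover."""

    species: list[dict]
    flow_ml_min: int
    flow_scale: float
    seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def _species_envelopes(cfg: ScenarioConfig):
    """Per species: list of (mz positions, probs, conformer amplitude factor)."""
    peptide = parse_sequence(cfg.sequence)
    per_monomer = exchangeable_protons(peptide, table=cfg.exchange_table)
    monomer_comp = composition(peptide)
    out = []
    truth_species = []
    for sp in cfg.species:
        ion = sp.ion
        natural = natural_isotope_distribution(monomer_comp * ion.n_monomers)
        n_sites = total_exchangeable(ion, per_monomer)
        conf_envs = []
        truth_confs = []
        for conf in sp.conformers:
            eff = conf.fraction * cfg.flow_scale
            env = single_state(natural, n_sites, eff)
            mz_pos = (env.distribution.masses + ion.charge * PROTON_MASS) / ion.charge
            conf_envs.append((mz_pos, env.distribution.probs, sp.abundance * conf.weight, conf))
            truth_confs.append({
                "fraction": conf.fraction,
                "effective_fraction": eff,
                "uptake_per_monomer": eff * n_sites / ion.n_monomers,
                "weight": conf.weight,
                "drift_apex_ms": conf.drift_apex_ms,
                "drift_width_ms": conf.drift_width_ms,
            })
        out.append((sp, conf_envs))
        truth_species.append({
            "label": ion.label,
            "n_monomers": ion.n_monomers,
            "charge": ion.charge,
            "abundance": sp.abundance,
            "n_exchangeable_total": n_sites,
            "n_exchangeable_per_monomer": per_monomer,
            "conformers": truth_confs,
        })
    truth = GroundTruth(truth_species, cfg.flow_ml_min, cfg.flow_scale, cfg.seed)
    return out, truth


def _mz_grid(conf_envs_all, cfg: ScenarioConfig) -> np.ndarray:
    lo = min(pos.min() for envs in conf_envs_all for pos, *_ in envs) - cfg.mz_pad
    hi = max(pos.max() for envs in conf_envs_all for pos, *_ in envs) + cfg.mz_pad
    n = int(np.ceil((hi - lo) / cfg.mz_step)) + 1
    return lo + cfg.mz_step * np.arange(n)


def _gaussian_comb(grid: np.ndarray, pos: np.ndarray, amp: np.ndarray,
                   sigma: float) -> np.ndarray:
    """Sum of Gaussians, evaluated only within 6 sigma of each peak."""
    y = np.zeros_like(grid)
    norm = 1.0 / (sigma * np.sqrt(2 * np.pi))
    for p, a in zip(pos, amp):
        i0 = np.searchsorted(grid, p - 6 * sigma)
        i1 = np.searchsorted(grid, p + 6 * sigma)
        y[i0:i1] += a * norm * np.exp(-0.5 * ((grid[i0:i1] - p) / sigma) ** 2)
    return y


def simulate_spectrum(cfg: ScenarioConfig) -> tuple[Spectrum, GroundTruth]:
    """Forward-simulate a 1-D spectrum of all species and conformers."""
    per_species, truth = _species_envelopes(cfg)
    envs_all = [envs for _, envs in per_species]
    grid = _mz_grid(envs_all, cfg)
    signal = np.zeros_like(grid)
    for envs in envs_all:
        for pos, probs, amp, _ in envs:
            signal += _gaussian_comb(grid, pos, amp * probs, cfg.peak_sigma)
    rng = np.random.default_rng(cfg.seed)
    signal = _apply_noise(signal, cfg, rng)
    meta = {"flow_ml_min": cfg.flow_ml_min, "seed": cfg.seed, "polarity": "positive"}
    return Spectrum(grid, signal, meta), truth


def _apply_noise(signal: np.ndarray, cfg: ScenarioConfig, rng) -> np.ndarray:
    peak = signal.max() if signal.max() > 0 else 1.0
    if cfg.poisson_noise:
        # treat the profile as expected counts scaled so the apex is 1e4 counts
        scale = 1e4 / peak
        signal = rng.poisson(signal * scale) / scale
    if cfg.noise_sigma > 0:
        signal = signal + rng.normal(0.0, cfg.noise_sigma * peak, signal.shape)
    return np.clip(signal, 0.0, None)


def simulate_drift_map(cfg: ScenarioConfig) -> tuple[DriftMap, GroundTruth]:
    """Forward-simulate a 2-D IM-MS map (separable m/z x drift Gaussians)."""
    per_species, truth = _species_envelopes(cfg)
    envs_all = [envs for _, envs in per_species]
    for envs in envs_all:
        for *_, conf in envs:
            if conf.drift_apex_ms is None or conf.drift_width_ms is None:
                raise ValueError("every conformer needs drift_apex_ms and drift_width_ms")
    grid = _mz_grid(envs_all, cfg)
    apexes = [conf.drift_apex_ms for envs in envs_all for *_, conf in envs]
    widths = [conf.drift_width_ms for envs in envs_all for *_, conf in envs]
    t_lo = max(0.0, min(a - 5 * w for a, w in zip(apexes, widths)))
    t_hi = max(a + 5 * w for a, w in zip(apexes, widths))
    drift = t_lo + cfg.drift_step_ms * np.arange(
        int(np.ceil((t_hi - t_lo) / cfg.drift_step_ms)) + 1
    )
    inten = np.zeros((grid.size, drift.size))
    for envs in envs_all:
        for pos, probs, amp, conf in envs:
            mz_prof = _gaussian_comb(grid, pos, amp * probs, cfg.peak_sigma)
            dt_prof = np.exp(-0.5 * ((drift - conf.drift_apex_ms) / conf.drift_width_ms) ** 2)
            dt_prof /= dt_prof.sum() * cfg.drift_step_ms
            inten += np.outer(mz_prof, dt_prof) * cfg.drift_step_ms
    rng = np.random.default_rng(cfg.seed)
    peak = inten.max() if inten.max() > 0 else 1.0
    if cfg.noise_sigma > 0:
        inten = inten + rng.normal(0.0, cfg.noise_sigma * peak, inten.shape)
    inten = np.clip(inten, 0.0, None)
    return DriftMap(grid, drift, inten), truth


# ---------------------------------------------------------------------------
# canonical fixture scenarios
#
# Uptake targets mirror the states reported for the wild-type system:
# monomer (2+) major forms at 4/10/18/28 D, dimer (4+) at 4/9/14 D per
# monomer, a compact/extended trimer (6+) split with the compact form
# exchanging less, a fully-scrambled-like single-population trimer, and a
# small unstructured-peptide control (Leu-enkephalin-like, unimodal).


def _confs_from_uptakes(ion: OligomerIon, n_sites: int,
                        uptakes_per_monomer, weights,
                        drift=None) -> tuple[ConformerSpec, ...]:
    confs = []
    for i, (u, w) in enumerate(zip(uptakes_per_monomer, weights)):
        fraction = u * ion.n_monomers / n_sites
        apex, width = (drift[i] if drift else (None, None))
        confs.append(ConformerSpec(fraction, w, apex, width))
    return tuple(confs)


def canonical_scenarios(seed: int = 1) -> dict[str, tuple[ScenarioConfig, bool]]:
    """The bundled test scenarios; value flag marks drift-map scenarios."""
    wt = WT_ABETA_1_40
    per = 27  # exchangeable side-chain/terminus protons per monomer
    mon2 = OligomerIon(1, 2)
    dim4 = OligomerIon(2, 4)
    tri6 = OligomerIon(3, 6)
    scenarios: dict[str, tuple[ScenarioConfig, bool]] = {}
    scenarios["wt_monomer"] = (
        ScenarioConfig(
            wt,
            (SpeciesSpec(mon2, 1.0,
                         _confs_from_uptakes(mon2, per + 2, [4, 10, 18, 28],
                                             [0.30, 0.30, 0.25, 0.15])),),
            seed=seed,
        ),
        False,
    )
    scenarios["wt_dimer"] = (
        ScenarioConfig(
            wt,
            (SpeciesSpec(dim4, 1.0,
                         _confs_from_uptakes(dim4, 2 * per + 4, [4, 9, 14],
                                             [0.40, 0.35, 0.25])),),
            seed=seed + 1,
        ),
        False,
    )
    scenarios["wt_trimer_drift"] = (
        ScenarioConfig(
            wt,
            (SpeciesSpec(tri6, 1.0,
                         _confs_from_uptakes(tri6, 3 * per + 6, [6, 10],
                                             [0.60, 0.40],
                                             drift=[(5.0, 0.45), (8.0, 0.55)])),),
            seed=seed + 2,
        ),
        True,
    )
    scenarios["scr_like_trimer"] = (
        ScenarioConfig(
            SCR_ABETA_1_40,
            (SpeciesSpec(tri6, 1.0,
                         _confs_from_uptakes(tri6, 3 * per + 6, [5],
                                             [1.0], drift=[(6.0, 0.5)])),),
            seed=seed + 3,
        ),
        True,
    )
    leuenk = OligomerIon(1, 1)
    scenarios["leuenk_like"] = (
        ScenarioConfig(
            "YGGFL",  # Leu-enkephalin-like unstructured control, unimodal
            (SpeciesSpec(leuenk, 1.0,
                         (ConformerSpec(0.8, 1.0),)),),
            seed=seed + 4,
        ),
        False,
    )
    return scenarios


def fixture_suite(outdir: str | Path, seed: int = 1) -> dict[str, dict]:
    """Write the canonical scenarios (control + deuterated + manifest) to disk.

    Returns a manifest dict keyed by scenario name; the same content is
    written as ``<name>_manifest.json``.  Byte-identical across calls with
    the same seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifests: dict[str, dict] = {}
    for name, (cfg, is_drift) in canonical_scenarios(seed).items():
        control_cfg = ScenarioConfig(
            cfg.sequence,
            tuple(
                SpeciesSpec(sp.ion, sp.abundance,
                            tuple(ConformerSpec(0.0, c.weight, c.drift_apex_ms,
                                                c.drift_width_ms)
                                  for c in sp.conformers))
                for sp in cfg.species
            ),
            peak_sigma=cfg.peak_sigma, noise_sigma=cfg.noise_sigma,
            flow_ml_min=cfg.flow_ml_min, mz_step=cfg.mz_step,
            mz_pad=cfg.mz_pad, drift_step_ms=cfg.drift_step_ms,
            seed=cfg.seed + 1000,
        )
        ctrl_spec, _ = simulate_spectrum(control_cfg)
        deut_spec, truth = simulate_spectrum(cfg)
        files = {
            "control": f"{name}_control.xy",
            "deuterated": f"{name}_deuterated.xy",
        }
        write_spectrum_xy(ctrl_spec, outdir / files["control"])
        write_spectrum_xy(deut_spec, outdir / files["deuterated"])
        if is_drift:
            dmap, _ = simulate_drift_map(cfg)
            files["drift_map"] = f"{name}_driftmap.txt"
            dmap.to_triples_text(outdir / files["drift_map"])
        manifest = {
            "scenario": name,
            "sequence": cfg.sequence,
            "files": files,
            "ground_truth": json.loads(truth.to_json()),
        }
        with open(outdir / f"{name}_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        manifests[name] = manifest
    return manifests
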