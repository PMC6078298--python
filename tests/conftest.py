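import pytest
from hypothesis import settings

import hdxim as h
from hdxim.synthetic import (
    ConformerSpec,
    ScenarioConfig,
    SpeciesSpec,
    canonical_scenarios,
    simulate_spectrum,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def control_scenario(cfg: ScenarioConfig, seed_offset: int = 1000) -> ScenarioConfig:
    """The undeuterated counterpart of a scenario (all fractions zero)."""
    return ScenarioConfig(
        cfg.sequence,
        tuple(
            SpeciesSpec(
                sp.ion, sp.abundance,
                tuple(ConformerSpec(0.0, c.weight, c.drift_apex_ms, c.drift_width_ms)
                      for c in sp.conformers),
            )
            for sp in cfg.species
        ),
        peak_sigma=cfg.peak_sigma, noise_sigma=cfg.noise_sigma,
        flow_ml_min=cfg.flow_ml_min, mz_step=cfg.mz_step, mz_pad=cfg.mz_pad,
        drift_step_ms=cfg.drift_step_ms, seed=cfg.seed + seed_offset,
    )


def preprocess(spectrum: h.Spectrum) -> h.CentroidList:
    return h.centroid(h.smooth(spectrum))


@pytest.fixture(scope="session")
def wt_peptide() -> h.PeptideSpec:
    return h.parse_sequence(h.WT_ABETA_1_40)


@pytest.fixture(scope="session")
def wt_natural(wt_peptide) -> h.IsotopeDistribution:
    return h.natural_isotope_distribution(h.composition(wt_peptide))


@pytest.fixture(scope="session")
def scenarios():
    return canonical_scenarios(seed=1)


@pytest.fixture(scope="session")
def monomer_pair(scenarios):
    """Centroided control/deuterated pair of the wild-type monomer scenario."""
    cfg, _ = scenarios["wt_monomer"]
    ctrl_spec, _ = simulate_spectrum(control_scenario(cfg))
    deut_spec, truth = simulate_spectrum(cfg)
    return preprocess(ctrl_spec), preprocess(deut_spec), truth, cfg
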