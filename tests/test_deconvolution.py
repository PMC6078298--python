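"""Gaussian vectorization, boosted Gold solver, and component merging."""

import numpy as np
import pytest
from scipy.optimize import nnls

import hdxim as h
from hdxim.deconvolution import build_design_matrix, merge_components, vectorize
from hdxim.exchange_model import DELTA_M_D, poisson_binomial_pmf


@pytest.fixture(scope="module")
def small_family(wt_natural):
    # 20-member family over the monomer's 29 exchangeable sites
    return h.build_family(wt_natural, 29, grid=20)


@pytest.fixture(scope="module")
def small_system(small_family, wt_natural):
    lo = wt_natural.masses.min() - 3.0
    hi = wt_natural.masses.max() + 29 * DELTA_M_D + 3.0
    return build_design_matrix(small_family, (lo, hi), n=500, sigma=1.5)


def nnls_components(y, A, family, min_weight=0.01):
    """Independent oracle: non-negative least squares plus the same merge."""
    w, _ = nnls(A.matrix, y)
    return merge_components(w / w.sum(), family, min_weight)


class TestVectorize:
    def test_unit_peak_quadrature(self):
        d = h.IsotopeDistribution(np.array([50.0]), np.array([1.0]))
        v = vectorize(d, (40.0, 60.0), n=201, sigma=0.5)
        step = 20.0 / 200
        assert v.sum() * step == pytest.approx(1.0, rel=1e-6)

    def test_linearity(self):
        d1 = h.IsotopeDistribution(np.array([45.0]), np.array([1.0]))
        d2 = h.IsotopeDistribution(np.array([55.0]), np.array([1.0]))
        both = h.CentroidList([45.0, 55.0], [0.5, 0.5])
        v = vectorize(both, (40.0, 60.0), n=101, sigma=0.5)
        v12 = 0.5 * (vectorize(d1, (40.0, 60.0), n=101, sigma=0.5)
                     + vectorize(d2, (40.0, 60.0), n=101, sigma=0.5))
        np.testing.assert_allclose(v, v12, atol=1e-12)

    def test_fraction_zero_member_equals_natural(self, small_family, wt_natural):
        rng = (wt_natural.masses.min() - 2, wt_natural.masses.max() + 2)
        v0 = vectorize(small_family.members[0].distribution, rng, 300, 0.7)
        vn = vectorize(wt_natural, rng, 300, 0.7)
        np.testing.assert_allclose(v0, vn)

    def test_truncation_warning(self):
        d = h.IsotopeDistribution(np.array([10.0, 99.0]), np.array([0.5, 0.5]))
        with pytest.warns(UserWarning, match="truncated"):
            vectorize(d, (0.0, 50.0), n=100, sigma=1.0)

    def test_columns_normalized(self, small_system):
        sums = small_system.matrix.sum(axis=0)
        np.testing.assert_allclose(sums, sums[0])


class TestGoldDeconvolve:
    def test_pure_single_state_recovered(self, small_system):
        k = 7
        y = small_system.matrix[:, k]
        w = h.gold_deconvolve(y, small_system, iterations=2000, boosts=20)
        assert w[max(0, k - 1) : k + 2].sum() > 0.99

    def test_two_state_mixture_matches_nnls_oracle(self, small_system, small_family):
        y = 0.5 * small_system.matrix[:, 3] + 0.5 * small_system.matrix[:, 15]
        w = h.gold_deconvolve(y, small_system)
        gold = merge_components(w, small_family, 0.01)
        oracle = nnls_components(y, small_system, small_family)
        assert gold.n_states == oracle.n_states == 2
        for (ug, wg), (uo, wo) in zip(gold.components, oracle.components):
            assert ug == pytest.approx(uo, abs=29 / 19)  # one grid step
            assert wg == pytest.approx(wo, abs=0.05)
        assert all(abs(wg - 0.5) < 0.05 for _, wg in gold.components)

    def test_three_component_noiseless_mixture(self, small_system, small_family):
        weights = {2: 0.2, 9: 0.3, 17: 0.5}
        y = sum(w * small_system.matrix[:, k] for k, w in weights.items())
        w = h.gold_deconvolve(y, small_system)
        res = merge_components(w, small_family, 0.01)
        assert res.n_states == 3
        truth_uptakes = [small_family.uptakes[k] for k in weights]
        for (u, wt), ut, wt_true in zip(res.components, truth_uptakes,
                                        weights.values()):
            assert u == pytest.approx(ut, abs=1.0)
            assert wt == pytest.approx(wt_true, abs=0.05)

    def test_all_zero_input_rejected(self, small_system):
        with pytest.raises(ValueError):
            h.gold_deconvolve(np.zeros(small_system.matrix.shape[0]), small_system)

    def test_nonnegativity_preserved_every_iteration(self):
        rng = np.random.default_rng(11)
        A = rng.uniform(0, 1, (30, 8))
        A /= A.sum(axis=0)
        y = A @ rng.dirichlet(np.ones(8))
        for iters in (1, 3, 10, 50, 137):
            w = h.gold_deconvolve(y, A, iterations=iters, boosts=min(iters, 5))
            assert np.all(w >= 0)

    def test_residual_nonincreasing_over_blocks(self, small_system):
        # the multiplicative update alone (boost power 1) must not let the
        # noiseless residual grow as iterations accumulate; boosting itself
        # may transiently perturb the fit while sparsifying
        y = 0.4 * small_system.matrix[:, 4] + 0.6 * small_system.matrix[:, 12]
        res = []
        for iters in (100, 500, 2000, 8000):
            w = h.gold_deconvolve(y, small_system, iterations=iters,
                                  boosts=1, p=1.0)
            fit = small_system.matrix @ w
            scale = fit @ y / (fit @ fit)
            res.append(np.linalg.norm(y - scale * fit))
        assert all(b <= a * 1.01 for a, b in zip(res, res[1:]))


class TestMergeComponents:
    def test_single_member(self, small_family):
        w = np.zeros(20)
        w[5] = 1.0
        res = merge_components(w, small_family)
        assert res.n_states == 1
        assert res.components[0] == (pytest.approx(small_family.uptakes[5]), 1.0)

    def test_adjacent_members_interpolated(self):
        # members at 9.8 and 10.2 D with equal weight -> one state at 10.0 D
        uptakes = np.array([9.0, 9.8, 10.2, 11.0])
        w = np.array([0.0, 0.5, 0.5, 0.0])
        res = merge_components(w, uptakes)
        assert res.n_states == 1
        assert res.components[0][0] == pytest.approx(10.0)
        assert res.components[0][1] == pytest.approx(1.0)

    def test_four_separated_clusters(self):
        uptakes = np.linspace(0, 29, 30)
        w = np.zeros(30)
        for k in (2, 9, 16, 25):
            w[k] = 0.25
        res = merge_components(w, uptakes)
        assert res.n_states == 4

    def test_all_below_threshold_low_confidence(self):
        uptakes = np.linspace(0, 10, 11)
        w = np.full(11, 1.0 / 11)
        res = merge_components(w, uptakes, min_weight=0.5)
        assert res.low_confidence
        assert res.n_states == 1
        assert res.components[0][0] == pytest.approx(5.0)

    def test_weights_renormalized_and_increasing(self):
        uptakes = np.linspace(0, 20, 21)
        w = np.zeros(21)
        w[3], w[12] = 0.2, 0.6
        res = merge_components(w, uptakes)
        assert sum(wt for _, wt in res.components) == pytest.approx(1.0)
        ups = [u for u, _ in res.components]
        assert ups == sorted(ups)


class TestDeconvolveEnvelope:
    def test_control_equals_deuterated_single_zero_state(self, monomer_pair):
        ctrl, _, _, _ = monomer_pair
        res = h.deconvolve_envelope(ctrl, ctrl, h.OligomerIon(1, 2), 27)
        assert res.n_states == 1
        assert res.components[0][0] == pytest.approx(0.0, abs=0.5)

    def test_monomer_mixture_recovered(self, monomer_pair):
        ctrl, deut, truth, _ = monomer_pair
        res = h.deconvolve_envelope(ctrl, deut, h.OligomerIon(1, 2), 27)
        true_states = [(c["uptake_per_monomer"], c["weight"])
                       for c in truth.species[0]["conformers"]]
        assert res.n_states == len(true_states)
        for (u, w), (ut, wt) in zip(res.components, true_states):
            assert u == pytest.approx(ut, abs=1.0)
            assert w == pytest.approx(wt, abs=0.05)

    def test_heterogeneous_rate_single_state_never_split(self, wt_natural):
        # per-site probabilities vary widely but the species is ONE state;
        # the equal-probability family is wider, so it must fit with 1 member
        rng = np.random.default_rng(5)
        for trial in range(5):
            ps = rng.beta(2, 3, size=29)
            pmf = poisson_binomial_pmf(ps)
            masses = (wt_natural.masses[:, None]
                      + np.arange(30)[None, :] * DELTA_M_D).ravel()
            probs = (wt_natural.probs[:, None] * pmf[None, :]).ravel()
            order = np.argsort(masses)
            keep = probs[order] > 1e-9
            deut = h.CentroidList(masses[order][keep], probs[order][keep], "Da")
            ctrl = h.CentroidList(wt_natural.masses, wt_natural.probs, "Da")
            res = h.deconvolve_envelope(ctrl, deut, h.OligomerIon(1, 2), 27)
            assert res.n_states == 1, f"trial {trial}: split a single state"

    def test_empty_input_rejected(self, monomer_pair):
        ctrl, _, _, _ = monomer_pair
        empty = h.CentroidList(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            h.deconvolve_envelope(empty, ctrl, h.OligomerIon(1, 2), 27)
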