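"""Spectrum I/O, smoothing, centroiding and uptake arithmetic."""

import numpy as np
import pytest

import hdxim as h
from hdxim.exchange_model import DELTA_M_D


def gaussian_spectrum(centers, amps, sigma=0.02, lo=2160.0, hi=2175.0, step=0.002):
    x = np.arange(lo, hi, step)
    y = np.zeros_like(x)
    for c, a in zip(centers, amps):
        y += a * np.exp(-0.5 * ((x - c) / sigma) ** 2)
    return h.Spectrum(x, y)


class TestReadSpectrum:
    def test_two_column_text(self, tmp_path):
        p = tmp_path / "s.xy"
        p.write_text("2165.0 100\n2165.5 50\n")
        s = h.read_spectrum(str(p))
        assert len(s) == 2
        assert s.intensity.tolist() == [100.0, 50.0]

    def test_comma_separated(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("2165.0,100\n2165.5,50\n")
        assert len(h.read_spectrum(str(p))) == 2

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.xy"
        p.write_text("")
        with pytest.raises(ValueError, match="empty|malformed"):
            h.read_spectrum(str(p))

    def test_malformed_file_names_path(self, tmp_path):
        p = tmp_path / "bad.xy"
        p.write_text("2165.0 abc\n")
        with pytest.raises(ValueError, match="bad.xy"):
            h.read_spectrum(str(p))

    def test_mzml_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(7)
        s = h.Spectrum(np.sort(rng.uniform(100, 2000, 64)),
                       rng.uniform(0, 1e5, 64))
        path = tmp_path / "s.mzML"
        h.write_mzml(s, str(path))
        back = h.read_spectrum(str(path), format="mzML")
        np.testing.assert_array_equal(back.mz, s.mz)
        np.testing.assert_array_equal(back.intensity, s.intensity)

    def test_mzml_scan_averaging(self, tmp_path):
        x = np.linspace(100, 200, 50)
        s1 = h.Spectrum(x, np.full(50, 2.0))
        s2 = h.Spectrum(x, np.full(50, 4.0))
        path = tmp_path / "two.mzML"
        h.write_mzml([s1, s2], str(path))
        avg = h.read_spectrum(str(path), format="mzML", average=True)
        np.testing.assert_allclose(avg.intensity, 3.0)


class TestSmooth:
    def test_constant_unchanged(self):
        s = h.Spectrum(np.arange(50.0), np.full(50, 7.0))
        np.testing.assert_allclose(h.smooth(s).intensity, 7.0)

    def test_quadratic_reproduced_exactly(self):
        x = np.arange(50.0)
        s = h.Spectrum(x, 3 + 0.5 * (x - 25) ** 2)
        np.testing.assert_allclose(h.smooth(s, 5, 3).intensity, s.intensity,
                                   rtol=1e-10)

    def test_total_ion_current_preserved_interior(self):
        s = gaussian_spectrum([2165.0], [100.0], sigma=0.05)
        sm = h.smooth(s, 5, 3, passes=3)
        assert sm.intensity.sum() == pytest.approx(s.intensity.sum(), rel=0.01)

    def test_delta_peak_widened_matches_reference_filter(self):
        from scipy.signal import savgol_filter

        y = np.zeros(41)
        y[20] = 100.0
        s = h.Spectrum(np.arange(41.0), y)
        sm = h.smooth(s, 5, 2)
        assert (sm.intensity > 1.0).sum() > 1  # delta has been widened
        reference = np.clip(savgol_filter(y, 5, 2), 0.0, None)
        np.testing.assert_allclose(sm.intensity, reference, atol=1e-12)

    def test_window_larger_than_spectrum_rejected(self):
        s = h.Spectrum(np.arange(3.0), np.ones(3))
        with pytest.raises(ValueError):
            h.smooth(s, 5, 3)


class TestCentroid:
    def test_single_gaussian_apex(self):
        s = gaussian_spectrum([2165.0], [100.0])
        c = h.centroid(s)
        assert len(c) == 1
        assert c.positions[0] == pytest.approx(2165.0, abs=0.002)

    def test_two_resolved_gaussians_area_ratio(self):
        s = gaussian_spectrum([2165.0, 2167.0], [100.0, 50.0])
        c = h.centroid(s)
        assert len(c) == 2
        # areas proportional to amplitudes (equal widths), oracle: integral
        assert c.areas[0] / c.areas[1] == pytest.approx(2.0, rel=0.02)

    def test_flat_noise_below_threshold_empty(self):
        rng = np.random.default_rng(3)
        s = h.Spectrum(np.arange(200.0), rng.uniform(0, 1.0, 200))
        assert len(h.centroid(s, min_height=10.0)) == 0

    def test_symmetric_peak_centroid_within_grid_step(self):
        step = 0.002
        s = gaussian_spectrum([2165.0005], [10.0], step=step)
        c = h.centroid(s)
        apex = s.mz[np.argmax(s.intensity)]
        assert abs(c.positions[np.argmax(c.areas)] - apex) <= step


class TestWeightedCentroid:
    def test_single_peak(self):
        c = h.CentroidList([2165.0], [10.0])
        assert h.weighted_centroid(c) == 2165.0

    def test_equal_area_midpoint(self):
        c = h.CentroidList([2165.0, 2167.0], [5.0, 5.0])
        assert h.weighted_centroid(c) == pytest.approx(2166.0)

    def test_empty_window_rejected(self):
        c = h.CentroidList([2165.0], [10.0])
        with pytest.raises(ValueError):
            h.weighted_centroid(c, (2200.0, 2210.0))

    def test_forward_simulated_monomer_shift(self, wt_natural):
        # a fraction-f single state shifts the 2+ centroid by f*29*dm/2 in m/z
        ion = h.OligomerIon(1, 2)
        f = 0.5
        env = h.single_state(wt_natural, 29, f)
        pos0 = (wt_natural.masses + 2 * h.PROTON_MASS) / 2
        pos1 = (env.distribution.masses + 2 * h.PROTON_MASS) / 2
        c0 = h.weighted_centroid(h.CentroidList(pos0, wt_natural.probs))
        c1 = h.weighted_centroid(h.CentroidList(pos1, env.distribution.probs))
        assert c1 - c0 == pytest.approx(f * 29 * DELTA_M_D / 2, abs=1e-3)


class TestUptake:
    def test_identical_centroids_zero(self):
        assert h.uptake(2165.0, 2165.0, h.OligomerIon(1, 2)) == 0.0

    def test_full_side_chain_exchange(self):
        ion = h.OligomerIon(1, 2)
        assert h.uptake(2165.0 + 27 * DELTA_M_D / 2, 2165.0, ion) == pytest.approx(27.0)

    def test_dimer_per_monomer_convention(self):
        # 52 deuterons on the 4+ dimer: m/z shift 52*dm/4 -> 26 D/monomer
        ion = h.OligomerIon(2, 4)
        assert h.uptake(2165.0 + 52 * DELTA_M_D / 4, 2165.0, ion) == pytest.approx(26.0)

    def test_negative_uptake_warns_but_returns(self):
        with pytest.warns(UserWarning, match="negative uptake"):
            v = h.uptake(2160.0, 2165.0, h.OligomerIon(1, 2))
        assert v < 0

    def test_invariant_under_intensity_rescaling(self):
        c1 = h.CentroidList([2165.0, 2166.0], [1.0, 3.0])
        c2 = h.CentroidList([2165.0, 2166.0], [10.0, 30.0])
        assert h.weighted_centroid(c1) == pytest.approx(h.weighted_centroid(c2))


class TestMonomerMassDomain:
    def test_doubly_protonated_monomer(self):
        c = h.CentroidList([2165.9], [1.0])
        out = h.to_monomer_mass_domain(c, h.OligomerIon(1, 2))
        assert out.positions[0] == pytest.approx(2 * 2165.9 - 2 * h.PROTON_MASS)
        assert out.domain == "Da"

    def test_isobars_map_to_identical_monomer_mass(self):
        c = h.CentroidList([2165.9], [1.0])
        a = h.to_monomer_mass_domain(c, h.OligomerIon(1, 2))
        b = h.to_monomer_mass_domain(c, h.OligomerIon(2, 4))
        assert a.positions[0] == pytest.approx(b.positions[0], abs=1e-9)

    def test_round_trip_identity(self):
        ion = h.OligomerIon(3, 6)
        masses = np.array([4329.8, 4330.8, 4331.8])
        positions = (3 * masses + 6 * h.PROTON_MASS) / 6
        back = h.to_monomer_mass_domain(h.CentroidList(positions, np.ones(3)), ion)
        np.testing.assert_allclose(back.positions, masses, atol=1e-9)

    def test_tsv_round_trip(self):
        c = h.CentroidList([2165.0, 2166.0], [1.5, 2.5])
        again = h.CentroidList.from_tsv(c.to_tsv())
        np.testing.assert_allclose(again.positions, c.positions)
        np.testing.assert_allclose(again.areas, c.areas)
        assert again.domain == "m/z"
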