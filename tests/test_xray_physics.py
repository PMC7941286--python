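import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special

from mrtdose.xray_physics import (FilterElement, PhotonSpectrum,
                                  RingParameters, apply_filters,
                                  attenuation_coefficient,
                                  bending_magnet_spectrum, critical_energy,
                                  filter_transmission, material_table,
                                  mean_energy, read_spectrum, sample_energies,
                                  write_spectrum)

# independently transcribed standard-reference mass attenuation values
# (total with coherent, cm^2/g) used to pin the packaged tables
PUBLISHED_MU = {
    "water": {10: 5.329, 30: 0.3756, 60: 0.2059, 100: 0.1707},
    "aluminium": {10: 26.23, 30: 1.128, 60: 0.2778, 100: 0.1704},
    "beryllium": {10: 0.6466, 30: 0.1792, 60: 0.1493, 100: 0.1328},
    "air": {10: 5.120, 30: 0.3538, 60: 0.1875, 100: 0.1541},
    "tungsten": {10: 96.91, 30: 22.73, 60: 3.713, 100: 4.438},
}


class TestCriticalEnergy:
    def test_closed_form_value(self, ring):
        # 0.665 * 2.4^2 * 1.45
        assert critical_energy(ring) == pytest.approx(5.554, abs=5e-3)

    def test_vanishing_field_emits_nothing(self):
        weak = RingParameters(2.4, 1e-12, 160.0)
        assert critical_energy(weak) == pytest.approx(0.0, abs=1e-11)

    def test_quadratic_in_electron_energy(self, ring):
        double = RingParameters(4.8, 1.45, 160.0)
        assert critical_energy(double) == pytest.approx(
            4 * critical_energy(ring))

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            RingParameters(-1.0, 1.45, 160.0)


class TestBendingMagnetSpectrum:
    def test_linear_in_ring_current(self):
        grid = np.linspace(5, 150, 100)
        a = bending_magnet_spectrum(RingParameters(ring_current_ma=160), grid)
        b = bending_magnet_spectrum(RingParameters(ring_current_ma=80), grid)
        assert np.allclose(a.flux_density, 2 * b.flux_density)

    def test_high_energy_falloff_matches_quadrature_oracle(self, ring):
        # trapezoid-on-log-grid oracle for G1(y) = y * int_y^inf K_5/3
        def g1_oracle(y):
            x = np.geomspace(y, y + 60.0, 20000)
            return y * np.trapezoid(special.kv(5 / 3, x), x)

        eps_c = critical_energy(ring)
        s = bending_magnet_spectrum(ring, np.array([eps_c, 10 * eps_c]))
        ratio = s.flux_density[1] / s.flux_density[0]
        oracle = g1_oracle(10.0) / (10.0 * g1_oracle(1.0))
        assert ratio == pytest.approx(oracle, rel=1e-3)
        assert ratio < 1e-2

    def test_empty_grid_rejected(self, ring):
        with pytest.raises(ValueError):
            bending_magnet_spectrum(ring, np.array([]))

    def test_single_broad_maximum_per_bandwidth(self, ring):
        # the per-keV photon flux diverges softly (~E^-2/3); the universal
        # single-maximum shape G1(y) appears per relative bandwidth, E*Phi
        grid = np.geomspace(0.2, 150.0, 300)
        s = bending_magnet_spectrum(ring, grid)
        per_bw = grid * s.flux_density
        i = np.argmax(per_bw)
        d = np.diff(per_bw)
        assert 0 < i < grid.size - 1
        assert np.all(d[:i] > 0) and np.all(d[i:] < 0)


class TestAttenuation:
    def test_water_total_matches_reference(self):
        assert attenuation_coefficient("water", 30.0) == pytest.approx(
            0.3756, rel=0.02)

    def test_tables_match_published_tabulation_within_2pct(self):
        for material, vals in PUBLISHED_MU.items():
            for e, mu in vals.items():
                assert attenuation_coefficient(material, e) == pytest.approx(
                    mu, rel=0.02), (material, e)

    def test_table_node_identity(self):
        tab = material_table("water")
        i = len(tab.energy_kev) // 2
        assert tab.mu_over_rho(tab.energy_kev[i]) == pytest.approx(
            tab.mu_total[i], rel=1e-12)

    def test_total_bounds_partials_and_sum(self):
        for material in PUBLISHED_MU:
            tab = material_table(material)
            for kind in ("photoelectric", "incoherent", "coherent"):
                assert np.all(tab.mu_total + 1e-12 >=
                              getattr(tab, "mu_" + kind))
            total = (tab.mu_photoelectric + tab.mu_incoherent
                     + tab.mu_coherent)
            assert np.allclose(total, tab.mu_total, rtol=0.02)

    def test_unknown_material_and_range(self):
        with pytest.raises(ValueError):
            attenuation_coefficient("lead", 30.0)
        with pytest.raises(ValueError):
            attenuation_coefficient("water", 2.0)


class TestFilterTransmission:
    def test_zero_thickness_is_unity(self):
        assert filter_transmission([FilterElement("aluminium", 0.0)],
                                   30.0) == 1.0

    def test_aluminium_3p5mm_at_30kev(self):
        t = filter_transmission([FilterElement("aluminium", 3.5)], 30.0)
        # exp(-1.128 * 2.699 * 0.35) from the validated table
        assert t == pytest.approx(0.344, abs=0.01)

    def test_adding_a_filter_never_increases_transmission(self):
        e = np.linspace(5, 150, 50)
        base = filter_transmission([FilterElement("beryllium", 2.0)], e)
        more = filter_transmission([FilterElement("beryllium", 2.0),
                                    FilterElement("water", 0.5)], e)
        assert np.all(more <= base + 1e-15)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(t1=st.floats(0, 5), t2=st.floats(0, 5))
    def test_stack_order_irrelevant_and_bounded(self, t1, t2):
        a = [FilterElement("aluminium", t1), FilterElement("water", t2)]
        b = a[::-1]
        e = np.array([10.0, 30.0, 100.0])
        ta, tb = filter_transmission(a, e), filter_transmission(b, e)
        assert np.allclose(ta, tb)
        assert np.all((0 <= ta) & (ta <= 1))

    def test_negative_thickness_rejected(self):
        with pytest.raises(ValueError):
            FilterElement("aluminium", -1.0)


class TestApplyFiltersAndMeanEnergy:
    def test_empty_filter_list_is_identity(self, filtered_spectrum):
        out = apply_filters(filtered_spectrum, [])
        assert np.array_equal(out.flux_density, filtered_spectrum.flux_density)

    def test_filtered_flux_nowhere_larger(self, ring):
        raw = bending_magnet_spectrum(ring)
        filt = apply_filters(raw, [FilterElement("aluminium", 3.5)])
        assert np.all(filt.flux_density <= raw.flux_density)

    def test_filtered_beam_peaks_between_20_and_40_kev(self, filtered_spectrum):
        peak = filtered_spectrum.energy_kev[
            np.argmax(filtered_spectrum.flux_density)]
        assert 20.0 < peak < 40.0

    def test_filtered_mean_energy_near_30_kev(self, filtered_spectrum):
        assert mean_energy(filtered_spectrum) == pytest.approx(30.0, abs=2.0)

    def test_mean_energy_of_delta_like_spectrum(self):
        e = np.linspace(10, 20, 11)
        phi = np.zeros_like(e)
        phi[4] = 7.0
        assert mean_energy(PhotonSpectrum(e, phi)) == pytest.approx(e[4])

    def test_mean_energy_scale_invariant(self, filtered_spectrum):
        scaled = PhotonSpectrum(filtered_spectrum.energy_kev,
                                filtered_spectrum.flux_density * 17.0)
        assert mean_energy(scaled) == pytest.approx(
            mean_energy(filtered_spectrum))

    def test_all_zero_flux_rejected(self):
        s = PhotonSpectrum(np.array([10.0, 20.0]), np.zeros(2))
        with pytest.raises(ValueError):
            mean_energy(s)


class TestSampleEnergies:
    def test_law_of_large_numbers(self, filtered_spectrum):
        e = sample_energies(filtered_spectrum, 100_000, 7)
        assert abs(e.mean() - mean_energy(filtered_spectrum)) < 0.5

    def test_seed_reproducibility(self, filtered_spectrum):
        a = sample_energies(filtered_spectrum, 1000, 3)
        b = sample_energies(filtered_spectrum, 1000, 3)
        assert np.array_equal(a, b)

    def test_single_bin_spectrum_is_nearly_constant(self):
        e = np.linspace(10, 20, 21)
        phi = np.zeros_like(e)
        phi[10] = 1.0
        s = sample_energies(PhotonSpectrum(e, phi), 500, 0)
        assert np.all(np.abs(s - 15.0) <= 0.5 + 1e-12)

    def test_degenerate_spectrum_rejected(self):
        s = PhotonSpectrum(np.array([10.0, 20.0]), np.array([0.0, 0.0]))
        with pytest.raises(ValueError):
            sample_energies(s, 10, 0)


def test_spectrum_io_round_trip(tmp_path, filtered_spectrum):
    path = tmp_path / "spec.csv"
    write_spectrum(path, filtered_spectrum)
    back = read_spectrum(path)
    assert np.allclose(back.energy_kev, filtered_spectrum.energy_kev)
    assert np.allclose(back.flux_density, filtered_spectrum.flux_density)
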