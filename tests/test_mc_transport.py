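import numpy as np
import pytest
from scipy import integrate

from mrtdose.mc_transport import (PhantomSpec, Photon, TransportConfig,
                                  _sample_source, interact_in_water,
                                  klein_nishina_total_barn, launch_photon,
                                  mean_scatter_fraction,
                                  nominal_window_probability,
                                  run_static_field, transmit_to_phantom)
from mrtdose.beam_geometry import slit_centres_mm

_MEC2 = 510.99895
_RE2 = 0.07941


def kn_mean_fraction_quadrature(e_kev):
    """Oracle: <E'/E> from the Klein-Nishina differential cross section."""
    k = e_kev / _MEC2

    def dkn(mu):
        r = 1.0 / (1.0 + k * (1.0 - mu))
        return 0.5 * _RE2 * r**2 * (r + 1.0 / r - (1.0 - mu**2)) * 2 * np.pi

    num, _ = integrate.quad(lambda m: dkn(m) / (1.0 + k * (1.0 - m)), -1, 1)
    den, _ = integrate.quad(dkn, -1, 1)
    return num / den


class TestComptonSampling:
    def test_thomson_limit(self):
        assert klein_nishina_total_barn(1e-3) == pytest.approx(0.6652,
                                                               abs=2e-4)

    def test_mean_scatter_fraction_matches_quadrature(self):
        mc = mean_scatter_fraction(30.0, n=400_000, seed=0)
        assert mc == pytest.approx(kn_mean_fraction_quadrature(30.0),
                                   rel=0.005)

    def test_cross_section_decreases_with_energy(self):
        e = np.array([10.0, 30.0, 100.0])
        s = klein_nishina_total_barn(e)
        assert np.all(np.diff(s) < 0)


class TestSource:
    def test_weights_unity_without_importance_sampling(self, layout,
                                                       filtered_spectrum,
                                                       msc):
        cfg = TransportConfig(importance_sampling=False)
        rng = np.random.default_rng(0)
        *_, w = _sample_source(1000, layout, filtered_spectrum, msc, cfg, rng)
        assert np.all(w == 1.0)

    def test_angular_spread_matches_configured_divergence(self, layout,
                                                          filtered_spectrum,
                                                          msc):
        cfg = TransportConfig(importance_sampling=False)
        rng = np.random.default_rng(1)
        _, _, tx, _, _, _ = _sample_source(1_000_000, layout,
                                           filtered_spectrum, msc, cfg, rng)
        sigma = layout.horizontal_divergence_mrad * 1e-3 / 2.35482
        assert tx.std() == pytest.approx(sigma, rel=0.01)

    def test_slit_hit_fraction_matches_open_fraction(self, layout,
                                                     filtered_spectrum, msc):
        cfg = TransportConfig(importance_sampling=False)
        rng = np.random.default_rng(2)
        x0, _, tx, _, _, _ = _sample_source(400_000, layout,
                                            filtered_spectrum, msc, cfg, rng)
        x_in = x0 + tx * layout.source_to_msc_m * 1e3
        central = np.abs(x_in) < 2.0
        centres = slit_centres_mm(msc)
        hit = (np.abs(x_in[central, None] - centres[None, :])
               <= msc.slit_width_um * 5e-4).any(axis=1)
        frac = hit.mean()
        open_frac = msc.slit_width_um / msc.pitch_um
        n = central.sum()
        assert abs(frac - open_frac) < 4 * np.sqrt(open_frac / n)

    def test_launch_photon_reproducible(self, layout, filtered_spectrum):
        a = launch_photon(layout, filtered_spectrum, 5)
        b = launch_photon(layout, filtered_spectrum, 5)
        assert np.array_equal(a.position_mm, b.position_mm)
        assert a.energy_kev == b.energy_kev
        assert a.weight == 1.0

    def test_importance_weight_is_window_probability(self, layout,
                                                     filtered_spectrum, msc):
        cfg = TransportConfig()
        p = launch_photon(layout, filtered_spectrum, 0, msc=msc, config=cfg)
        z = nominal_window_probability(msc, layout, cfg)
        assert p.weight == pytest.approx(z, rel=0.05)


class TestTransmit:
    def test_slit_centre_attenuated_by_air_only(self, msc, layout):
        c = float(slit_centres_mm(msc)[msc.n_slits // 2])
        tan = c / (layout.source_to_msc_m * 1e3)
        d = np.array([tan, 0.0, 1.0])
        d /= np.linalg.norm(d)
        ph = Photon(np.zeros(3), d, 30.0)
        out = transmit_to_phantom(ph, msc, layout)
        from mrtdose.xray_physics import material_table
        expect = np.exp(-material_table("air").linear_mu(30.0)
                        * layout.msc_to_sample_m * 100.0)
        assert out.weight == pytest.approx(expect, rel=1e-6)
        assert 0.95 < expect < 1.0  # a few percent at 30 keV

    def test_lamella_centre_terminated(self, msc, layout):
        c = float(slit_centres_mm(msc)[msc.n_slits // 2]) \
            + msc.pitch_um * 5e-4
        tan = c / (layout.source_to_msc_m * 1e3)
        d = np.array([tan, 0.0, 1.0])
        d /= np.linalg.norm(d)
        assert transmit_to_phantom(Photon(np.zeros(3), d, 30.0), msc,
                                   layout) is None

    def test_without_air_weight_unchanged(self, msc, layout):
        c = float(slit_centres_mm(msc)[msc.n_slits // 2])
        tan = c / (layout.source_to_msc_m * 1e3)
        d = np.array([tan, 0.0, 1.0])
        d /= np.linalg.norm(d)
        out = transmit_to_phantom(Photon(np.zeros(3), d, 30.0), msc, layout,
                                  air_enabled=False)
        assert out.weight == 1.0

    def test_outside_aperture_terminated(self, msc, layout):
        tan = 3.0 / (layout.source_to_msc_m * 1e3)  # 6 mm > 4 mm half-aperture
        d = np.array([2 * tan, 0.0, 1.0])
        d /= np.linalg.norm(d)
        assert transmit_to_phantom(Photon(np.zeros(3), d, 30.0), msc,
                                   layout) is None


class TestInteractInWater:
    def test_zero_cross_sections_deposit_nothing(self, rng):
        ph = Photon(np.zeros(3), np.array([0.0, 0.0, 1.0]), 30.0)
        events, survivor = interact_in_water(ph, PhantomSpec(), rng,
                                             mu_scale=0.0)
        assert events == [] and survivor is not None

    def test_deposits_bounded_by_photon_energy(self):
        rng = np.random.default_rng(0)
        phantom = PhantomSpec(entrance_layer_mm=0.0)
        total = 0.0
        for _ in range(200):
            ph = Photon(np.zeros(3), np.array([0.0, 0.0, 1.0]), 30.0)
            events, _ = interact_in_water(ph, phantom, rng, mu_scale=30.0)
            dep = sum(e[-1] for e in events)
            assert dep <= 30.0 + 1e-9
            total += dep
        assert total > 0.0


class TestStaticField:
    def test_energy_conservation(self, static_field):
        m = static_field.meta
        assert m["scored_kev"] <= m["entered_phantom_kev"] <= \
            m["launched_kev"] * (1 + 1e-9)

    def test_seed_reproducibility(self, filtered_spectrum, msc, layout,
                                  phantom):
        cfg = TransportConfig(n_histories=2e6, seed=9, batches=4)
        a = run_static_field(cfg, filtered_spectrum, msc, layout, phantom)
        b = run_static_field(cfg, filtered_spectrum, msc, layout, phantom)
        assert np.array_equal(a.dose, b.dose)

    def test_uncertainty_scales_inverse_sqrt_n(self, filtered_spectrum, msc,
                                               layout, phantom):
        rels = []
        for n in (2e6, 32e6):  # 16x range
            cfg = TransportConfig(n_histories=n, seed=11, batches=8)
            g = run_static_field(cfg, filtered_spectrum, msc, layout, phantom)
            sel = g.dose > 0.2 * g.dose.max()
            rels.append(np.median(g.stderr[sel] / g.dose[sel]))
        assert rels[0] / rels[1] == pytest.approx(4.0, rel=0.35)

    def test_peaks_sit_at_slit_projections_with_nominal_width(
            self, static_field, msc, layout):
        prof = static_field.dose[np.abs(static_field.y_mm) < 0.3].mean(axis=0)
        x = static_field.x_mm
        # central beam: nearest slit projection to the axis
        c_slit = slit_centres_mm(msc)
        c_slit = c_slit[np.argmin(np.abs(c_slit - 0.2))] * layout.magnification
        sel = np.abs(x - c_slit) < 0.2
        peak_x = x[sel][np.argmax(prof[sel])]
        assert abs(peak_x - c_slit) < 0.01
        half = prof[sel].max() / 2
        fwhm = (prof[sel] >= half).sum() * static_field.pitch_x_mm * 1e3
        assert fwhm == pytest.approx(msc.slit_width_um, abs=10.0)

    def test_mirror_symmetry_within_errors(self, static_field):
        prof = static_field.dose.sum(axis=0)
        err = np.sqrt((static_field.stderr**2).sum(axis=0))
        diff = np.abs(prof - prof[::-1])
        tol = 3 * np.sqrt(err**2 + err[::-1] ** 2) + 1e-12
        assert (diff <= tol).mean() > 0.95

    def test_importance_sampling_unbiased(self, filtered_spectrum, msc,
                                          layout, phantom):
        """Peak dose per history is IS-invariant (variance reduction only)."""
        doses = {}
        for is_on, n in ((True, 3e6), (False, 3e6)):
            cfg = TransportConfig(n_histories=n, seed=13, batches=4,
                                  importance_sampling=is_on)
            g = run_static_field(cfg, filtered_spectrum, msc, layout, phantom)
            sel = np.abs(g.x_mm - 0.2039) <= 0.02
            rows = np.abs(g.y_mm) < 0.5
            prof = g.dose[rows][:, sel]
            errs = g.stderr[rows][:, sel]
            doses[is_on] = (prof.mean(),
                            np.sqrt((errs**2).sum()) / errs.size)
        delta = abs(doses[True][0] - doses[False][0])
        tol = 4 * np.hypot(doses[True][1], doses[False][1])
        assert delta < tol

    def test_opaque_collimator_no_scatter_gives_zero_valley(
            self, filtered_spectrum, msc, layout):
        cfg = TransportConfig(n_histories=2e6, seed=3, batches=4,
                              photon_scatter=False, air_scatter=False)
        g = run_static_field(cfg, filtered_spectrum, msc, layout,
                             PhantomSpec())
        valley = g.dose[:, np.abs(g.x_mm) <= 0.05]
        assert np.all(valley == 0.0)
        assert g.dose.max() > 0.0


def test_transport_config_invariants():
    with pytest.raises(ValueError):
        TransportConfig(n_histories=1, batches=2)
    with pytest.raises(ValueError):
        TransportConfig(split_scatter=0)
    with pytest.raises(ValueError):
        Photon(np.zeros(3), np.array([0, 0, 1.0]), -5.0)
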