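"""Transport primitives and the random-walk kernel.

Each sampler is checked against an independent closed-form oracle (exponential
CDF, Henyey-Greenstein density, Lambertian cosine moment, rotation-matrix
construction); the kernel is checked against symmetry and pairing identities.
"""

import math

import numpy as np
import pytest
import scipy.integrate
import scipy.stats
from hypothesis import given, settings, strategies as st

import ringoxsim as rx
from ringoxsim.finger_model import OpticalProperties, TissueLabel
from ringoxsim.transport import hg_pdf_cos


class TestFreePathSampler:
    def test_one_mfp_at_u_inverse_e(self):
        props = rx.optical_properties(TissueLabel.DERMIS_PULP, 656)
        s = rx.sample_free_path(props, math.exp(-1.0))
        assert s == pytest.approx(1 / 8.65, rel=1e-12)

    def test_invalid_variates_rejected(self):
        props = rx.optical_properties(TissueLabel.DERMIS_PULP, 656)
        with pytest.raises(ValueError):
            rx.sample_free_path(props, 0.0)
        with pytest.raises(ValueError):
            rx.sample_free_path(props, 1.1)

    def test_distribution_matches_exponential_cdf(self, rng):
        """Empirical CDF of draws matches 1 - exp(-(mu_a+mu_s) l) (KS test)."""
        props = rx.optical_properties(TissueLabel.ARTERIAL_BLOOD, 943)
        draws = rx.sample_free_path(props, 1.0 - rng.random(100_000))
        stat = scipy.stats.kstest(draws, "expon", args=(0, 1 / 65.64))
        assert stat.pvalue > 0.01


class TestHGSampler:
    def test_isotropic_limit(self, rng):
        c = rx.sample_hg_cos(0.0, rng.random(1_000_000))
        assert abs(c.mean()) < 3 * c.std() / 1000.0
        assert c.min() >= -1.0 and c.max() <= 1.0

    def test_invalid_anisotropy_rejected(self):
        with pytest.raises(ValueError):
            rx.sample_hg_cos(1.0, 0.5)

    def test_density_matches_closed_form(self, rng):
        """Histogram of draws matches the HG density via quadrature (chi^2)."""
        g = 0.91
        draws = rx.sample_hg_cos(g, rng.random(200_000))
        edges = np.array([-1.0, 0.0, 0.5, 0.8, 0.9, 0.95, 0.98, 0.99, 0.995, 1.0])
        counts, _ = np.histogram(draws, bins=edges)
        probs = np.array(
            [
                scipy.integrate.quad(lambda c: hg_pdf_cos(g, c), lo, hi)[0]
                for lo, hi in zip(edges[:-1], edges[1:])
            ]
        )
        probs /= probs.sum()
        res = scipy.stats.chisquare(counts, probs * counts.sum())
        assert res.pvalue > 0.01


class TestDeflect:
    def test_identity_when_no_deflection(self):
        d = np.array([0.0, 0.6, 0.8])
        out = rx.deflect(d, 1.0, 0.3)
        assert np.allclose(out, d, atol=1e-9)

    def test_agreement_with_rotation_matrix_oracle(self, rng):
        """Deflected vector has the requested angle to the input, unit norm."""
        for _ in range(300):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            ct = rng.uniform(-1, 1)
            phi = rng.uniform(0, 2 * np.pi)
            out = rx.deflect(d, ct, phi)
            assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-9)
            assert float(np.dot(out, d)) == pytest.approx(ct, abs=1e-9)

    def test_azimuth_sweeps_cone(self, rng):
        """For fixed ct, averaging over azimuths recovers ct * d (cone axis)."""
        d = np.array([0.3, -0.5, np.sqrt(1 - 0.09 - 0.25)])
        ct = 0.6
        phis = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        outs = rx.deflect(np.tile(d, (400, 1)), np.full(400, ct), phis)
        assert np.allclose(outs.mean(axis=0), ct * d, atol=1e-3)


class TestBoundaryEvent:
    def test_pure_transmitter_always_transmits(self, rng):
        sp = rx.SurfaceScattering(0.0, 1.0)
        n = np.array([0.0, 0.0, 1.0])
        refl, dirs = rx.boundary_event(sp, n, rng.random(1000), rng.random(1000), rng.random(1000))
        assert not refl.any()
        assert np.all(dirs[:, 2] < 0)  # transmitted side is -normal

    def test_reflect_fraction_and_sides(self, rng):
        sp = rx.surface_params(TissueLabel.ARTERIAL_BLOOD)
        n = np.array([0.0, 1.0, 0.0])
        m = 200_000
        refl, dirs = rx.boundary_event(sp, n, rng.random(m), rng.random(m), rng.random(m))
        se = math.sqrt(0.53 * 0.47 / m)
        assert refl.mean() == pytest.approx(0.53, abs=3 * se)
        assert np.all(dirs[refl, 1] > 0)
        assert np.all(dirs[~refl, 1] < 0)

    def test_lambertian_mean_cosine_is_two_thirds(self, rng):
        """Analytic moment of the cosine-weighted hemisphere."""
        n = np.array([0.0, 0.0, 1.0])
        m = 200_000
        dirs = rx.lambertian_direction(n, rng.random(m), rng.random(m))
        se = dirs[:, 2].std() / math.sqrt(m)
        assert dirs[:, 2].mean() == pytest.approx(2.0 / 3.0, abs=3 * se)
        assert np.allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-9)


class TestPropagate:
    def test_outward_photon_exits_immediately(self):
        g = rx.build_finger_model(1)
        p = rx.Photon(
            position=(20.0, 0.0, g.semi_axis_z - 1e-4), direction=(0.0, 0.0, 1.0)
        )
        ev = rx.propagate(p, g, seed=1)
        assert ev.kind == "EXITED"
        assert ev.exit_angle_deg == pytest.approx(0.0, abs=0.1)
        assert ev.exit_axial_mm == pytest.approx(20.0, abs=1e-6)
        assert ev.n_events <= 1

    def test_exterior_start_rejected(self):
        g = rx.build_finger_model(1)
        with pytest.raises(ValueError):
            rx.propagate(rx.Photon((0.0, 0.0, 50.0), (0.0, 0.0, -1.0)), g)

    def test_terminal_kinds_exhaustive(self):
        g = rx.build_finger_model(1)
        kinds = set()
        for i in range(200):
            p = rx.Photon((20.0, 0.0, 0.0), (0.0, 0.0, 1.0), wavelength=656)
            kinds.add(rx.propagate(p, g, seed=i).kind)
        assert kinds <= {"EXITED", "ABSORBED", "END_CAP", "CAPPED"}
        assert "ABSORBED" in kinds


class TestRunSimulation:
    def test_reproducible_bitwise(self, model1_dia):
        src = rx.SourceSpec(theta_deg=30.0, wavelength=943, n_photons=20_000, seed=9)
        a = rx.run_simulation(model1_dia, src)
        b = rx.run_simulation(model1_dia, src)
        assert np.array_equal(a.bin_counts, b.bin_counts)
        assert a.meta_dict() == b.meta_dict()

    def test_conservation_and_bounds(self, pair_150_943):
        d, s = pair_150_943
        for r in (d, s):
            r.check_conservation()
            assert r.detected_total <= r.n_launched
            assert np.all(r.bin_counts >= 0)

    def test_zero_budget_rejected(self, model1_dia):
        with pytest.raises(ValueError):
            rx.SourceSpec(theta_deg=0.0, n_photons=0)
        with pytest.raises(ValueError):
            rx.SourceSpec(theta_deg=400.0)

    def test_symmetric_phantom_profile_mirrors_about_source(self):
        """No interior solids + circular section: exit profile is mirror
        symmetric about the source meridian within counting noise."""
        ph = rx.make_phantom(9.0, 9.0, epidermis_thickness=0.2)
        src = rx.SourceSpec(theta_deg=90.0, wavelength=943, n_photons=120_000, seed=5)
        res = rx.run_simulation(ph, src)
        c = res.bin_counts
        src_bin = 12
        for k in range(1, 24):
            a = c[(src_bin + k) % 48]
            b = c[(src_bin - k) % 48]
            assert abs(a - b) <= 6 * math.sqrt(a + b + 1)

    def test_identical_phase_geometries_give_identical_walks(self):
        """Common random numbers: without arteries the phase pair is exact."""
        ph = rx.make_phantom(9.0, 11.0, epidermis_thickness=0.2)
        src = rx.SourceSpec(theta_deg=150.0, wavelength=656, n_photons=30_000, seed=17)
        a = rx.run_simulation(ph, src)
        b = rx.run_simulation(ph, src)
        assert np.array_equal(a.bin_counts, b.bin_counts)
        assert rx.pi_ratio(a.detected_total, b.detected_total, a.n_launched) == 0.0

    def test_systolic_artery_dims_far_side_weight(self, pair_150_943):
        """Paired seeds: growing the artery radius cannot brighten the
        artery-shadow window (bins 60-120 deg)."""
        d, s = pair_150_943
        win = np.arange(8, 17)
        assert d.bin_counts[win].sum() >= s.bin_counts[win].sum()

    def test_detector_axial_window_tallies_missed(self, model1_dia):
        src = rx.SourceSpec(theta_deg=150.0, wavelength=943, n_photons=20_000, seed=4)
        det = rx.DetectorArray(axial_window=(15.0, 25.0))
        res = rx.run_simulation(model1_dia, src, detectors=det)
        assert res.missed > 0
        res.check_conservation()

    def test_save_load_round_trip(self, tmp_path, pair_150_943):
        d, _ = pair_150_943
        d.save(tmp_path, "run")
        back = rx.SimResult.load(tmp_path, "run")
        assert np.array_equal(back.bin_counts, d.bin_counts)
        assert back.meta_dict() == d.meta_dict()


class TestBeerLambertLimit:
    @pytest.mark.parametrize("mu_a,d_mm", [(0.05, 5.0), (0.2, 10.0)])
    def test_unscattered_slab_transmission(self, mu_a, d_mm):
        """mu_s = 0: transmission through a diameter equals exp(-mu_a d)."""
        ph = rx.make_phantom(d_mm / 2.0, d_mm / 2.0, epidermis_thickness=0.0)
        props = {TissueLabel.DERMIS_PULP: OpticalProperties(mu_a, 0.0, 1.38, 0.9)}
        src = rx.SourceSpec(
            theta_deg=0.0, wavelength=943, n_photons=100_000, seed=23, half_angle_deg=0.0
        )
        res = rx.run_simulation(ph, src, properties=props)
        p = math.exp(-mu_a * d_mm)
        se = math.sqrt(p * (1 - p) / res.n_launched)
        assert res.detected_total / res.n_launched == pytest.approx(p, abs=3 * se)
        # pencil beam, no scattering: every exit is at the far pole
        assert res.bin_counts[24] == res.detected_total


@given(
    g=st.floats(-0.99, 0.99),
    u=st.floats(1e-9, 1.0, exclude_max=True),
)
@settings(max_examples=300, deadline=None)
def test_hg_cosine_stays_in_range(g, u):
    """The HG inverse CDF maps any (g, u) into a valid cosine."""
    c = float(rx.sample_hg_cos(g, u))
    assert -1.0 <= c <= 1.0
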