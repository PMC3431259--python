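"""Generators: geometry sampling, rendering, refraction warp, cohorts."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from octmorph.core import OutOfFieldError
from octmorph.geometry import GroundTruthGeometry, solve_half_angle
from octmorph.optics import RayField, refract_directions
from octmorph.synthetic import (CohortConfig, RenderConfig, apply_refraction_warp,
                                generate_cohort, generate_eye_geometry, render_bscan)


def zero_sd_config():
    return CohortConfig(parameter_sds={k: 0.0 for k in CohortConfig().parameter_sds})


class TestGeometrySampling:
    def test_zero_sd_draws_hit_population_means_exactly(self):
        g = generate_eye_geometry(zero_sd_config(), seed=5)
        assert g.true_pcal == pytest.approx(12.99, abs=1e-12)
        assert g.true_pgal == pytest.approx(9.24, abs=1e-12)
        assert g.true_pgcl == pytest.approx(8.15, abs=1e-12)
        assert g.true_agal == pytest.approx(9.69, abs=1e-12)
        assert g.posterior_radius == pytest.approx(5.80, abs=1e-12)

    def test_same_seed_reproduces_geometry(self, table1_config):
        a = generate_eye_geometry(table1_config, seed=42)
        b = generate_eye_geometry(table1_config, seed=42)
        assert a == b

    def test_monte_carlo_means_match_configured_gaussians(self, table1_config):
        """Marginals of the directly drawn parameters recover the configured
        means within 3 standard errors at n = 10,000."""
        n = 10_000
        rng = np.random.default_rng(0)
        seeds = rng.integers(0, 2**31 - 1, size=n)
        draws = np.array([
            [(g := generate_eye_geometry(table1_config, seed=int(s))).true_pcal,
             g.true_pgal, g.graft_thickness_mm * 1000] for s in seeds])
        for i, (mean, sd) in enumerate([(12.99, 0.69), (9.24, 0.72), (194.5, 43.1)]):
            se = sd / math.sqrt(n)
            assert abs(draws[:, i].mean() - mean) < 3 * se

    def test_arc_chord_identities_hold_analytically(self, table1_config):
        for seed in range(30):
            g = generate_eye_geometry(table1_config, seed=seed)
            th = g.spur_half_angle
            assert g.true_pcal == pytest.approx(2 * th * g.posterior_radius, abs=1e-9)
            assert g.true_acw == pytest.approx(
                2 * g.posterior_radius * math.sin(th), abs=1e-9)
            assert g.true_pgal == pytest.approx(
                2 * g.graft_half_angle * g.graft_radius, abs=1e-9)
            assert g.true_pgal >= g.true_pgcl
            assert g.true_agal >= g.true_agcl
            assert g.true_pcal >= g.true_acw

    @given(st.floats(0.64, 0.995))
    def test_half_angle_solver_inverts_sinc(self, ratio):
        h = solve_half_angle(ratio)
        assert math.sin(h) / h == pytest.approx(ratio, abs=1e-9)

    def test_infeasible_ratio_rejected(self):
        with pytest.raises(ValueError):
            solve_half_angle(1.2)

    def test_graftless_eye_has_nan_graft_truths(self):
        g = GroundTruthGeometry.from_parameters(12.99, 5.8, None, None, None, 0.0)
        assert not g.has_graft
        assert math.isnan(g.true_pgal)
        assert g.true_pcal == pytest.approx(12.99)


class TestRendering:
    def test_noiseless_binarization_recovers_occupancy(self, mean_eye):
        """Thresholding the noiseless render at the intensity midpoint gives
        back the analytic tissue mask exactly."""
        cfg = RenderConfig(speckle_model="none")
        img, _ = render_bscan(mean_eye, cfg)
        mid = (cfg.tissue_intensity_mean + cfg.background_intensity_mean) / 2
        mask = img.intensities > mid
        assert set(np.unique(img.intensities)) == {40, 180}
        # re-render must agree with itself (occupancy is deterministic)
        img2, _ = render_bscan(mean_eye, cfg)
        assert np.array_equal(mask, img2.intensities > mid)
        # tissue exists and is a minority of the field
        assert 0.05 < mask.mean() < 0.6

    def test_unit_indices_warp_is_identity_for_images(self, mean_eye):
        base = RenderConfig(speckle_model="none")
        warped = RenderConfig(speckle_model="none", refraction_warp=True,
                              n_air=1.0, n_cornea=1.0, n_aqueous=1.0)
        img_a, _ = render_bscan(mean_eye, base)
        img_b, _ = render_bscan(mean_eye, warped)
        assert np.array_equal(img_a.intensities, img_b.intensities)

    def test_speckle_is_seed_deterministic(self, mean_eye):
        cfg = RenderConfig(seed=9)
        a, _ = render_bscan(mean_eye, cfg)
        b, _ = render_bscan(mean_eye, cfg)
        assert np.array_equal(a.intensities, b.intensities)
        c, _ = render_bscan(mean_eye, RenderConfig(seed=10))
        assert not np.array_equal(a.intensities, c.intensities)

    def test_geometry_exceeding_field_raises(self, mean_eye):
        small = RenderConfig(lateral_extent_mm=8.0, image_width_px=300)
        with pytest.raises(OutOfFieldError):
            render_bscan(mean_eye, small)

    def test_landmarks_lie_on_true_surfaces(self, mean_eye, noiseless_render):
        _, lm = noiseless_render
        assert lm.spur_right[0] == pytest.approx(mean_eye.x_spur)
        z = mean_eye.graft_posterior_surface(lm.graft_post_right[0])
        assert lm.graft_post_right[1] == pytest.approx(float(z), abs=1e-9)


class TestRefractionWarp:
    def test_unit_indices_give_identity_polylines(self, mean_eye):
        cfg = RenderConfig(speckle_model="none", n_air=1, n_cornea=1, n_aqueous=1)
        out = apply_refraction_warp(mean_eye, cfg)
        post = out["posterior"]
        assert np.allclose(post[:, 1], mean_eye.posterior_surface(post[:, 0]),
                           atol=1e-9)

    def test_flat_interface_normal_incidence_scales_depth(self):
        """Below a flat horizontal interface the apparent depth grows by the
        group index: optical depth = n * physical depth."""
        iface = np.array([[-5.0, 1.0], [5.0, 1.0]])
        x = np.linspace(-2, 2, 41)
        rays = RayField.forward(x, iface, None, (1.0, 1.388, 1.343), z_max=6.0)
        target = np.array([[-2.0, 3.0], [2.0, 3.0]])  # 2 mm below the interface
        warped = rays.warp_polyline(target)
        assert np.allclose(warped[:, 1], 1.0 + 1.388 * 2.0, atol=1e-6)

    def test_total_internal_reflection_flags_columns(self):
        # a steep interface with a dense medium above a rare one
        xs = np.linspace(-1, 1, 21)
        steep = np.column_stack([xs, 1.0 + 3.0 * xs])
        rays = RayField.forward(xs, steep, None, (2.0, 1.0, 1.0), z_max=6.0)
        assert rays.tir.any()

    def test_refraction_bends_toward_normal_into_denser_medium(self):
        tx, tz, tir = refract_directions(0.0, 1.0, np.array([1.0]), 1.0, 1.5)
        assert not tir[0]
        assert np.hypot(tx[0], tz[0]) == pytest.approx(1.0, abs=1e-12)
        # angle to the normal shrinks entering the denser medium
        norm = np.array([1.0, -1.0]) / math.sqrt(2)
        cos_in = -(norm @ np.array([0.0, 1.0]))
        cos_out = -(norm @ np.array([tx[0], tz[0]]))
        assert cos_out > cos_in


class TestCohortGeneration:
    def test_cohort_is_seed_deterministic(self):
        a, da = generate_cohort(CohortConfig(seed=3))
        b, db = generate_cohort(CohortConfig(seed=3))
        assert a.equals(b) and da.equals(db)

    def test_trephine_on_surgical_grid(self):
        coh, _ = generate_cohort(CohortConfig(n_eyes=300, seed=1))
        grid = set(np.round(np.arange(7.0, 9.51, 0.25), 2))
        assert set(np.round(coh.trephine_mm, 2)) <= grid

    def test_zero_observer_noise_gives_perfect_agreement(self):
        from octmorph.agreement import PairedMeasurements, icc
        cfg = CohortConfig(seed=2, observer_noise_sd={
            k: 0.0 for k in CohortConfig().observer_noise_sd})
        _, dup = generate_cohort(cfg)
        for param in dup["parameter"].unique():
            val, _ = icc(PairedMeasurements.from_long(dup, param))
            assert val == pytest.approx(1.0, abs=1e-12)

    def test_zero_link_noise_gives_monotone_trephine_pgal(self):
        from octmorph.agreement import spearman_rho
        coh, _ = generate_cohort(CohortConfig(seed=4, trephine_pgal_noise_sd=0.0))
        rho, _ = spearman_rho(coh.trephine_mm, coh.pgal_mm)
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_arc_cord_ordering_per_eye(self):
        coh, _ = generate_cohort(CohortConfig(n_eyes=500, seed=6))
        assert (coh.pgal_mm >= coh.pgcl_mm).all()
        assert (coh.agal_mm >= coh.agcl_mm).all()
        assert (coh.pcal_mm >= coh.pgcl_mm).all()

    def test_moment_recovery_of_linked_parameters(self):
        """Cohort means converge to the implied population values."""
        cfg = CohortConfig(n_eyes=10_000, seed=11)
        coh, _ = generate_cohort(cfg)
        mean_t = float(np.dot(cfg.trephine_levels, cfg.trephine_weights))
        pgal_mean = cfg.pgal_intercept + cfg.trephine_pgal_slope * mean_t
        assert coh.pgal_mm.mean() == pytest.approx(pgal_mean, abs=3 * 0.72 / 100)
        assert coh.pcal_mm.mean() == pytest.approx(12.99, abs=3 * 0.69 / 100 + 0.02)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_eyes=1)
        with pytest.raises(ValueError):
            CohortConfig(trephine_levels=(7.1,))
        with pytest.raises(ValueError):
            RenderConfig(tissue_intensity_mean=30, background_intensity_mean=40)
        with pytest.raises(ValueError):
            RenderConfig(n_cornea=0.9)
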