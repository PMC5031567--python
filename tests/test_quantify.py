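"""Calibration fitting, conjugate-view formula, geometry, TAC building."""

from types import SimpleNamespace

import numpy as np
import pytest

import marrowdose as md
from marrowdose.errors import CalibrationError, GeometryError, PipelineError
from marrowdose.quantify import source_attenuation_factor


class TestCalibrationFit:
    def test_noise_free_exact_recovery(self):
        series = md.generate_calibration_series(100.0, [0, 3, 6, 9, 12, 15],
                                                mu_true=0.11, sens_true=10.0)
        calib = md.fit_calibration(series, 100.0)
        assert calib.mu_eff == pytest.approx(0.11, rel=1e-8)
        assert calib.sensitivity == pytest.approx(10.0, rel=1e-8)

    def test_noised_recovery_within_3_percent(self):
        # >= 1e5 counts per point keeps the relative Poisson error small
        series = md.generate_calibration_series(100.0, [0, 3, 6, 9, 12, 15],
                                                0.11, 10.0, noise=True,
                                                seed=4, duration_s=1000.0)
        calib = md.fit_calibration(series, 100.0)
        assert calib.mu_eff == pytest.approx(0.11, rel=0.03)
        assert calib.sensitivity == pytest.approx(10.0, rel=0.03)

    def test_duplicate_depths_rejected(self):
        with pytest.raises(CalibrationError):
            md.fit_calibration([(5.0, 100.0), (5.0, 100.0), (5.0, 100.0)], 10.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(CalibrationError):
            md.fit_calibration([(0.0, 1000.0), (5.0, 500.0)], 100.0)


class TestConjugateView:
    def test_no_attenuation_limit(self):
        calib = md.Calibration(mu_eff=1e-9, sensitivity=10.0)
        a = md.conjugate_view_activity(1000.0, 1000.0, 20.0, calib, 1e-9)
        assert a == pytest.approx(100.0, rel=1e-6)

    def test_thin_source_closed_form(self):
        calib = md.Calibration(mu_eff=0.11, sensitivity=10.0)
        a = md.conjugate_view_activity(500.0, 500.0, 20.0, calib, 1e-9)
        assert a == pytest.approx(500.0 * np.exp(1.1) / 10.0, rel=1e-6)

    def test_self_attenuation_factor_properties(self):
        assert source_attenuation_factor(0.11, 0.0) == 1.0
        xs = np.linspace(0.5, 20, 30)
        fs = [source_attenuation_factor(0.11, x) for x in xs]
        assert all(f >= 1.0 for f in fs)
        assert np.all(np.diff(fs) > 0)

    def test_activity_monotone_in_thickness(self):
        calib = md.Calibration(mu_eff=0.11, sensitivity=10.0)
        a = [md.conjugate_view_activity(100.0, 100.0, t, calib, 8.0)
             for t in (10.0, 15.0, 20.0, 30.0)]
        assert np.all(np.diff(a) > 0)

    def test_geometry_errors(self):
        calib = md.Calibration(mu_eff=0.11, sensitivity=10.0)
        with pytest.raises(GeometryError):
            md.conjugate_view_activity(1.0, 1.0, -5.0, calib, 1.0)
        with pytest.raises(GeometryError):
            md.conjugate_view_activity(1.0, 1.0, 10.0, calib, 12.0)


def masks_from_areas(n_high, n_low):
    grid = np.zeros((1, n_high + n_low), dtype=bool)
    high = grid.copy(); high[0, :n_high] = True
    low = grid.copy(); low[0, n_high:] = True
    return SimpleNamespace(high=high, low=low, body=high | low)


class TestCompartmentGeometry:
    def test_high_mass_from_area_and_slab(self):
        masks = masks_from_areas(500, 6600)
        geo = md.compartment_geometry(70.0, 20.0, masks, pixel_size_cm=1.0)
        assert geo.m_high_kg == pytest.approx(4.0)

    def test_low_thickness_from_residual_mass(self):
        masks = masks_from_areas(500, 6600)
        geo = md.compartment_geometry(70.0, 20.0, masks, pixel_size_cm=1.0)
        assert geo.low_thickness_cm == pytest.approx(10.0)
        assert geo.m_low_kg == pytest.approx(66.0)

    def test_empty_high_mask_degenerates(self):
        masks = masks_from_areas(0, 7000)
        geo = md.compartment_geometry(70.0, 20.0, masks, pixel_size_cm=1.0)
        assert geo.m_high_kg == 0.0
        assert geo.low_thickness_cm == pytest.approx(10.0)

    def test_overweight_high_compartment_rejected(self):
        masks = masks_from_areas(10000, 1000)
        with pytest.raises(GeometryError):
            md.compartment_geometry(50.0, 20.0, masks, pixel_size_cm=1.0)


def run_tac(spec, noise=False, seed_base=100):
    """Build TACs with truth masks (isolates quantification from segmentation)."""
    images, truth = md.generate_study(spec, noise=noise)
    calib = md.Calibration(mu_eff=spec.mu_eff, sensitivity=spec.sensitivity)
    masks = SimpleNamespace(body=truth.body_mask, high=truth.high_mask,
                            low=truth.body_mask & ~truth.high_mask)
    geometry = md.compartment_geometry(truth.weight_kg, spec.thickness_cm,
                                       masks, spec.pixel_size_cm)
    series = md.build_tac(images, [masks] * len(images), calib, geometry)
    return series, truth


class TestBuildTac:
    def test_phantom_recovery_noise_free(self, spec):
        (high, low), truth = run_tac(spec)
        np.testing.assert_allclose(high.activity_mbq, truth.activity_high_mbq,
                                   rtol=0.05)
        np.testing.assert_allclose(low.activity_mbq, truth.activity_low_mbq,
                                   rtol=0.05)

    def test_zero_background_phantom(self):
        from test_phantom import single_focus_spec
        spec = single_focus_spec(activity_mbq=10.0, background_mbq=0.0)
        (high, low), truth = run_tac(spec)
        np.testing.assert_allclose(high.activity_mbq, truth.activity_high_mbq,
                                   rtol=0.05)
        assert np.all(low.activity_mbq < 0.05 * truth.activity_high_mbq)

    def test_uniform_only_phantom(self):
        # no foci at all: everything quantifies through the low path
        spec = md.PhantomSpec(shape=(60, 40), body_center=(30, 20),
                              body_semi_axes=(28, 17), thickness_cm=18.0,
                              low_amplitudes=(100.0,), low_lambdas=(0.01,),
                              times_h=(2.0, 24.0, 48.0, 168.0))
        images, truth = md.generate_study(spec)
        calib = md.Calibration(mu_eff=spec.mu_eff, sensitivity=spec.sensitivity)
        masks = SimpleNamespace(body=truth.body_mask,
                                high=np.zeros_like(truth.body_mask),
                                low=truth.body_mask)
        geometry = md.compartment_geometry(truth.weight_kg, spec.thickness_cm,
                                           masks, spec.pixel_size_cm)
        high, low = md.build_tac(images, [masks] * len(images), calib, geometry)
        np.testing.assert_allclose(low.activity_mbq, truth.activity_low_mbq,
                                   rtol=0.05)
        assert np.all(high.activity_mbq == 0)

    def test_reassignment_is_zero_sum(self, spec):
        # high+low after the under/overlying transfer equals the raw
        # conjugate-view totals, recomputed here independently
        images, truth = md.generate_study(spec)
        calib = md.Calibration(mu_eff=spec.mu_eff, sensitivity=spec.sensitivity)
        masks = SimpleNamespace(body=truth.body_mask, high=truth.high_mask,
                                low=truth.body_mask & ~truth.high_mask)
        geometry = md.compartment_geometry(truth.weight_kg, spec.thickness_cm,
                                           masks, spec.pixel_size_cm)
        high, low = md.build_tac(images, [masks] * len(images), calib, geometry)
        for i, (ant, post) in enumerate(images):
            gm = md.geometric_mean(ant, post)
            r_h = float(gm.values[masks.high].sum())
            r_l = float(gm.values[masks.low].sum())
            raw_h = md.conjugate_view_activity(r_h, r_h, geometry.abdominal_thickness_cm,
                                               calib, geometry.slab_thickness_cm)
            raw_l = md.conjugate_view_activity(r_l, r_l, geometry.low_thickness_cm,
                                               calib, geometry.low_thickness_cm)
            assert high.activity_mbq[i] + low.activity_mbq[i] == \
                pytest.approx(raw_h + raw_l, rel=1e-12)

    def test_quantification_linear_in_counts(self, spec):
        images, truth = md.generate_study(spec)
        calib = md.Calibration(mu_eff=spec.mu_eff, sensitivity=spec.sensitivity)
        masks = SimpleNamespace(body=truth.body_mask, high=truth.high_mask,
                                low=truth.body_mask & ~truth.high_mask)
        geometry = md.compartment_geometry(truth.weight_kg, spec.thickness_cm,
                                           masks, spec.pixel_size_cm)
        high1, low1 = md.build_tac(images, [masks] * len(images), calib, geometry)
        scaled = [tuple(md.PlanarImage(counts=im.counts * 3.0, view=im.view,
                                       time_pi=im.time_pi, duration=im.duration,
                                       pixel_size=im.pixel_size)
                        for im in pair) for pair in images]
        high3, low3 = md.build_tac(scaled, [masks] * len(images), calib, geometry)
        np.testing.assert_allclose(high3.activity_mbq, 3 * high1.activity_mbq,
                                   rtol=1e-12)
        np.testing.assert_allclose(low3.activity_mbq, 3 * low1.activity_mbq,
                                   rtol=1e-12)

    def test_total_body_activity_at_2h_matches_truth(self, spec):
        (high, low), truth = run_tac(spec)
        total_est = high.activity_mbq[0] + low.activity_mbq[0]
        total_true = truth.activity_high_mbq[0] + truth.activity_low_mbq[0]
        assert total_est == pytest.approx(total_true, rel=0.05)

    def test_missing_view_dropped_then_too_few_points(self, spec):
        images, truth = md.generate_study(spec)
        calib = md.Calibration(mu_eff=spec.mu_eff, sensitivity=spec.sensitivity)
        masks = SimpleNamespace(body=truth.body_mask, high=truth.high_mask,
                                low=truth.body_mask & ~truth.high_mask)
        geometry = md.compartment_geometry(truth.weight_kg, spec.thickness_cm,
                                           masks, spec.pixel_size_cm)
        broken = [images[0], (images[1][0], None)] + list(images[2:])
        with pytest.warns(UserWarning):
            high, _ = md.build_tac(broken, [masks] * len(broken), calib, geometry)
        assert len(high) == 3
        worse = [images[0], (None, None), (images[2][0], None), images[3]]
        with pytest.warns(UserWarning):
            with pytest.raises(PipelineError):
                md.build_tac(worse, [masks] * len(worse), calib, geometry)
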