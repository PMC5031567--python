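"""Phantom generator: calibration series, projections, truth, cohorts."""

import numpy as np
import pytest
from scipy import integrate

import marrowdose as md
from marrowdose.errors import CalibrationError, ParameterError
from marrowdose.phantom import FocusSpec, PhantomSpec, ellipse_mask


class TestCalibrationSeries:
    def test_zero_depth_rate_is_activity_times_sensitivity(self):
        series = md.generate_calibration_series(100.0, [0.0, 5.0, 10.0],
                                                mu_true=0.11, sens_true=10.0)
        assert series[0][1] == pytest.approx(1000.0)

    def test_half_value_depth(self):
        d_half = np.log(2) / 0.11
        series = md.generate_calibration_series(100.0, [0.0, d_half, 10.0],
                                                mu_true=0.11, sens_true=10.0)
        assert series[1][1] == pytest.approx(500.0)

    def test_too_few_depths_rejected(self):
        with pytest.raises(CalibrationError):
            md.generate_calibration_series(100.0, [0.0, 5.0], 0.11, 10.0)
        with pytest.raises(CalibrationError):
            md.generate_calibration_series(100.0, [1.0, 1.0, 1.0], 0.11, 10.0)

    def test_poisson_mean_matches_analytic(self):
        # 1000 noisy replicates at depth 0: mean rate within 1% of 1000 c/s
        rates = [md.generate_calibration_series(
            100.0, [0.0, 5.0, 10.0], 0.11, 10.0, noise=True, seed=s,
            duration_s=60.0)[0][1] for s in range(1000)]
        assert np.mean(rates) == pytest.approx(1000.0, rel=0.01)

    def test_seed_reproducibility(self):
        a = md.generate_calibration_series(100.0, [0, 4, 8], 0.11, 10.0,
                                           noise=True, seed=7)
        b = md.generate_calibration_series(100.0, [0, 4, 8], 0.11, 10.0,
                                           noise=True, seed=7)
        assert a == b


def single_focus_spec(activity_mbq=10.0, background_mbq=0.0):
    """Minimal phantom: one 8 cm slab focus, optional uniform background."""
    shape = (60, 40)
    focus = FocusSpec(name="organ", center=(30.0, 20.0), semi_axes=(6.0, 5.0),
                      thickness_cm=8.0, amplitudes=(activity_mbq,),
                      lambdas=(0.01,))
    return PhantomSpec(shape=shape, body_center=(30.0, 20.0),
                       body_semi_axes=(28.0, 17.0), thickness_cm=18.0,
                       foci=[focus],
                       low_amplitudes=(background_mbq,), low_lambdas=(0.01,),
                       times_h=(2.0, 24.0, 48.0, 168.0))


class TestProjection:
    def test_posterior_is_mirrored_anterior(self, spec):
        ant = md.project_planar(spec, 24.0, "anterior")
        post = md.project_planar(spec, 24.0, "posterior")
        np.testing.assert_allclose(post.counts, ant.counts[:, ::-1])

    def test_gm_equals_anterior_for_depth_symmetric_phantom(self, spec):
        ant = md.project_planar(spec, 24.0, "anterior")
        post = md.project_planar(spec, 24.0, "posterior")
        gm = md.geometric_mean(ant, post)
        np.testing.assert_allclose(gm.values, ant.rate, rtol=1e-12)

    def test_negative_time_rejected(self, spec):
        with pytest.raises(ParameterError):
            md.project_planar(spec, -1.0, "anterior")

    def test_noise_reproducible_under_seed(self, spec):
        a = md.project_planar(spec, 24.0, "anterior", noise=True, seed=3)
        b = md.project_planar(spec, 24.0, "anterior", noise=True, seed=3)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_single_focus_conjugate_round_trip(self):
        # noise-free forward projection inverted by the conjugate-view
        # formula recovers the focus activity within 2%
        spec = single_focus_spec(activity_mbq=10.0)
        ant = md.project_planar(spec, 2.0, "anterior")
        post = md.project_planar(spec, 2.0, "posterior")
        gm = md.geometric_mean(ant, post)
        calib = md.Calibration(mu_eff=spec.mu_eff, sensitivity=spec.sensitivity)
        rate = float(gm.values[spec.high_mask].sum())
        est = md.conjugate_view_activity(rate, rate, spec.thickness_cm, calib,
                                         source_thickness_cm=8.0)
        true = spec.high_activity(2.0)
        assert est == pytest.approx(true, rel=0.02)


class TestGenerateStudy:
    def test_truth_tia_closed_form(self):
        spec = single_focus_spec()
        spec.low_amplitudes, spec.low_lambdas = (50.0, 50.0), (0.3, 0.0114)
        _, truth = md.generate_study(spec)
        assert truth.tia_low == pytest.approx(50 / 0.3 + 50 / 0.0114, rel=1e-12)

    def test_zero_activity_gives_zero_images_and_dose(self):
        spec = single_focus_spec(activity_mbq=0.0, background_mbq=0.0)
        images, truth = md.generate_study(spec)
        assert all(np.all(img.counts == 0) for pair in images for img in pair)
        assert truth.dose.d_bm_gy == 0.0

    def test_truth_tia_matches_quadrature(self, spec, study_noise_free):
        _, truth = study_noise_free
        quad_low, _ = integrate.quad(spec.low_activity, 0, np.inf)
        quad_high, _ = integrate.quad(spec.high_activity, 0, np.inf)
        assert truth.tia_low == pytest.approx(quad_low, rel=1e-3)
        assert truth.tia_high == pytest.approx(quad_high, rel=1e-3)

    def test_truth_dose_is_mird_sum_of_truth_tias(self, study_noise_free):
        _, truth = study_noise_free
        sv = md.default_svalues()
        recomputed = md.bone_marrow_dose(truth.tia_bm, truth.tia_high,
                                         truth.tia_low, sv,
                                         marrow_mass_kg=truth.marrow_mass_kg)
        assert truth.dose.d_bm_gy == pytest.approx(recomputed.d_bm_gy, rel=1e-12)

    def test_images_reproducible_under_seed(self, spec):
        imgs_a, _ = md.generate_study(spec, noise=True)
        imgs_b, _ = md.generate_study(spec, noise=True)
        for (a1, p1), (a2, p2) in zip(imgs_a, imgs_b):
            np.testing.assert_array_equal(a1.counts, a2.counts)
            np.testing.assert_array_equal(p1.counts, p2.counts)


class TestSpecValidation:
    def test_focus_outside_body_rejected(self):
        with pytest.raises(ParameterError, match="outside"):
            PhantomSpec(shape=(40, 40), body_center=(20, 20),
                        body_semi_axes=(10, 10),
                        foci=[FocusSpec("f", (20, 32), (3, 3), 8.0,
                                        (1.0,), (0.01,))])

    def test_nonpositive_decay_rejected(self):
        with pytest.raises(ParameterError):
            PhantomSpec(low_lambdas=(0.0,), low_amplitudes=(1.0,))

    def test_yaml_round_trip(self, tmp_path, spec):
        spec.to_yaml(tmp_path / "spec.yaml")
        back = PhantomSpec.from_yaml(tmp_path / "spec.yaml")
        assert back.times_h == spec.times_h
        assert back.weight_kg == pytest.approx(spec.weight_kg)
        np.testing.assert_array_equal(back.high_mask, spec.high_mask)


class TestCohort:
    def test_degenerate_flat_cohort_flagged(self):
        records = md.generate_cohort(10, slopes={"hb": 0.0},
                                     noise_sd={"hb": 0.0}, seed=0)
        table = md.cohort_dataframe(records)
        with pytest.raises(md.errors.DegenerateInputError):
            md.pearson_test(table.dose_per_fraction_gy, table.hb_decrease)

    def test_noiseless_negative_slope_gives_perfect_anticorrelation(self):
        records = md.generate_cohort(20, slopes={"hb": -30.0},
                                     noise_sd={"hb": 0.0}, seed=0)
        res = md.correlate_cohort(records)["hb"]
        assert res.r == pytest.approx(-1.0)
        assert res.perfect_fit

    def test_slope_recovery_at_n200(self):
        # single-cohort slope SE is ~16% of the truth at this noise level,
        # so recovery is judged by the median over independent cohorts
        slopes, rs = [], []
        for seed in range(9):
            records = md.generate_cohort(200, slopes={"hb": -30.0},
                                         noise_sd={"hb": 6.0}, seed=seed)
            res = md.correlate_cohort(records)["hb"]
            slopes.append(res.slope)
            rs.append(res.r)
        assert all(np.sign(r) == -1 for r in rs)
        assert np.median(slopes) == pytest.approx(-30.0, rel=0.15)

    def test_small_n_rejected(self):
        with pytest.raises(ParameterError):
            md.generate_cohort(2)

    def test_reproducible(self):
        a = md.cohort_dataframe(md.generate_cohort(10, seed=3))
        b = md.cohort_dataframe(md.generate_cohort(10, seed=3))
        assert a.equals(b)
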