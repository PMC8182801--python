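import numpy as np
import pytest
from scipy.stats import norm, skewnorm

from thermex.stats import (
    DistributionFit,
    FitFailure,
    build_histogram,
    fit_normal_to_histogram,
    fit_skew_normal_to_histogram,
    half_normal_approx,
    linearity_screen,
    sigma_thresholds,
    tabulate_outliers,
)


class TestHistogram:
    def test_small_example(self):
        h = build_histogram([10, 30, 40], bin_width=25)
        assert list(h.bin_edges) == [0, 25, 50]
        assert list(h.counts) == [1, 2]

    def test_empty_input(self):
        h = build_histogram([])
        assert h.n == 0 and h.counts.size == 0

    def test_counts_match_direct_tally(self, rng):
        draws = rng.standard_normal(10_000) * 40
        h = build_histogram(draws, bin_width=25)
        assert h.n == 10_000
        for lo, hi, c in zip(h.bin_edges[:-1], h.bin_edges[1:], h.counts):
            assert c == int(np.sum((draws >= lo) & (draws < hi)))

    def test_negative_values_covered(self):
        h = build_histogram([-30, -1, 1], bin_width=25)
        assert h.bin_edges[0] == -50 and h.n == 3

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            build_histogram([1.0, np.nan])


class TestNormalHistogramFit:
    def test_recovers_generator_parameters(self, rng):
        draws = rng.normal(161, 51, size=50_000)
        fit = fit_normal_to_histogram(build_histogram(draws, 25))
        mean, sd, amp = fit.params
        assert mean == pytest.approx(161, abs=2)
        assert sd == pytest.approx(51, abs=2)
        # amplitude ~ N * bin_width at a perfect fit of the scaled pdf
        assert amp == pytest.approx(50_000 * 25, rel=0.05)

    def test_degenerate_input_raises(self):
        h = build_histogram([10.0, 40.0], 25)
        with pytest.raises(FitFailure):
            fit_normal_to_histogram(h)


class TestSkewNormalFit:
    def test_zero_shape_limit_matches_normal_fit(self, rng):
        draws = rng.normal(100, 40, size=30_000)
        h = build_histogram(draws, 25)
        nfit = fit_normal_to_histogram(h)
        sfit = fit_skew_normal_to_histogram(h)
        x = np.linspace(-60, 260, 200)
        assert np.allclose(sfit.density(x), nfit.density(x), rtol=0.08, atol=2)

    def test_parameter_recovery(self, rng):
        xi, omega, shape = 0.0, 70.0, 4.0
        draws = skewnorm.rvs(shape, loc=xi, scale=omega, size=60_000, random_state=rng)
        fit = fit_skew_normal_to_histogram(build_histogram(draws, 25))
        fxi, fomega, fshape, _ = fit.params
        assert fxi == pytest.approx(xi, abs=8)
        assert fomega == pytest.approx(omega, abs=8)
        assert fshape == pytest.approx(shape, abs=1.5)

    def test_positive_skew_gives_positive_shape(self, rng):
        draws = skewnorm.rvs(6, loc=10, scale=50, size=20_000, random_state=rng)
        fit = fit_skew_normal_to_histogram(build_histogram(draws, 25))
        assert fit.params[2] > 0


class TestHalfNormalApprox:
    def test_symmetric_input_gives_equal_sides(self):
        sfit = DistributionFit("skew_normal", (10.0, 40.0, 0.0, 1000.0))
        hn = half_normal_approx(sfit)
        centre, sd_lo, sd_hi, _ = hn.params
        assert centre == pytest.approx(10.0, abs=1e-4)
        assert sd_lo == pytest.approx(40.0, rel=1e-4)
        assert sd_hi == pytest.approx(40.0, rel=1e-4)

    def test_positive_shape_widens_upper_side(self):
        sfit = DistributionFit("skew_normal", (0.0, 60.0, 5.0, 1000.0))
        hn = half_normal_approx(sfit)
        _, sd_lo, sd_hi, _ = hn.params
        assert sd_hi > sd_lo

    def test_density_continuous_and_matches_peak(self):
        sfit = DistributionFit("skew_normal", (0.0, 60.0, 5.0, 1000.0))
        hn = half_normal_approx(sfit)
        centre = hn.params[0]
        left, right = hn.density(np.array([centre - 1e-9, centre + 1e-9]))
        assert left == pytest.approx(right, rel=1e-9)
        assert hn.density(np.array([centre]))[0] == pytest.approx(
            sfit.density(np.array([centre]))[0], rel=1e-6
        )


class TestSigmaThresholds:
    def test_published_normal_thresholds(self):
        fit = DistributionFit("normal", (161.0, 51.0, 1.0))
        assert sigma_thresholds(fit, k=3) == (8.0, 314.0)

    def test_published_half_normal_thresholds(self):
        fit = DistributionFit("two_half_normal", (33.0, 40.0, 56.0, 1.0))
        assert sigma_thresholds(fit, k=3) == (-87.0, 201.0)

    def test_k_zero_collapses_to_centre(self):
        fit = DistributionFit("two_half_normal", (33.0, 40.0, 56.0, 1.0))
        assert sigma_thresholds(fit, k=0) == (33.0, 33.0)

    def test_monotone_in_k(self):
        fit = DistributionFit("normal", (100.0, 20.0, 1.0))
        los, his = zip(*(sigma_thresholds(fit, k) for k in (1, 2, 3, 4)))
        assert all(a > b for a, b in zip(los, los[1:]))
        assert all(a < b for a, b in zip(his, his[1:]))


def _result(alpha_v, n_points, r2=0.999, temps=(100.0, 293.0), aniso=0.5, vfit=None):
    """Minimal ExpansionResult stand-in built through the real constructors."""
    from thermex.expansion import ExpansionResult, VolumeFit

    vf = vfit if vfit is not None else VolumeFit(
        slope=0.1, intercept=1000.0, r_squared=(None if n_points == 2 else r2),
        alpha_v_298=alpha_v, su_alpha_v=(None if n_points == 2 else 5.0),
        n_points=n_points, t_min=min(temps), t_max=max(temps),
        residuals=np.zeros(n_points),
    )
    third = alpha_v / 3.0
    return ExpansionResult(
        alpha_v=vf, alpha_l=(third, third, third), su_l=(None,) * 3,
        principal_axes=np.eye(3), anisotropy=aniso, nte_class="none",
        conclusive_nte=(),
    )


class TestLinearityScreenAndOutliers:
    def test_exactly_linear_family_passes(self):
        from thermex.expansion import volumetric_fit

        pts = [(t, 900 + 0.2 * t) for t in (100, 160, 220, 293)]
        res = _result(200, 4, vfit=volumetric_fit(pts))
        passed, failed = linearity_screen([("FAM-1", res)])
        assert passed == ["FAM-1"] and not failed

    def test_temperature_mislabel_fails_and_is_diagnosed(self):
        from thermex.expansion import volumetric_fit

        temps = [100.0, 160.0, 220.0, 260.0, 293.0]
        vols = [900 + 0.2 * t for t in temps]
        temps[1] = 262.0  # mislabelled by ~+100 K
        pts = sorted(zip(temps, vols))
        res = _result(200, 5, vfit=volumetric_fit(pts))
        passed, failed = linearity_screen([("FAM-1", res)])
        assert not passed and failed[0].family_id == "FAM-1"
        # removing the worst-residual point restores a good linear fit
        pts.pop(failed[0].worst_point)
        assert volumetric_fit(pts).r_squared > 0.96

    def test_volume_jump_fails_screen(self):
        from thermex.expansion import volumetric_fit

        pts = [(t, 900 + 0.2 * t + (40 if t > 200 else 0)) for t in (100, 160, 220, 293)]
        res = _result(200, 4, vfit=volumetric_fit(pts))
        passed, failed = linearity_screen([("FAM-1", res)])
        assert not passed

    def test_outlier_tables(self):
        results = [
            ("HOT-1", _result(400.0, 5)),
            ("OK-1", _result(150.0, 3)),
            ("NEG-1", _result(-40.0, 2)),
            ("ANISO-1", _result(150.0, 4, aniso=4.0)),
        ]
        report = tabulate_outliers(results, thresholds=(8.0, 314.0))
        assert report.extreme_positive == ["HOT-1"]
        assert report.suspect_negative == ["NEG-1"]
        assert report.extreme_anisotropy == ["ANISO-1"]

    def test_no_extremes_gives_empty_tables(self):
        report = tabulate_outliers([("OK-1", _result(150.0, 3))], thresholds=(8.0, 314.0))
        assert not report.extreme_positive
        assert not report.suspect_negative
        assert not report.extreme_anisotropy
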