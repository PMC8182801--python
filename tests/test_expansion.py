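import numpy as np
import pytest

from thermex.cells import UnitCell, orthogonalization_matrix
from thermex.expansion import (
    DuplicateTemperatureError,
    InconsistentSettingError,
    UndefinedAnisotropyError,
    anisotropy,
    build_strain_series,
    classify_nte,
    expansion_for_family_cells,
    principal_fit,
    strain_tensor_pair,
    volumetric_fit,
)


def hand_coded_hc1_slope_se(t, y):
    """Independent sandwich estimator: n/(n-2) * H diag(u^2) H' with H = pinv(X).

    The pseudoinverse form is the numerically stable statement of
    (X'X)^-1 X' diag(u^2) X (X'X)^-1 and keeps the comparison meaningful at
    1e-10 even for ill-conditioned small samples.
    """
    t, y = np.asarray(t, float), np.asarray(y, float)
    n = len(t)
    x = np.column_stack([np.ones(n), t])
    h = np.linalg.pinv(x)
    u = y - x @ (h @ y)
    cov = n / (n - 2) * h @ np.diag(u * u) @ h.T
    return float(np.sqrt(cov[1, 1]))


class TestVolumetricFit:
    def test_two_point_exact_line(self):
        fit = volumetric_fit([(100.0, 1000.0), (300.0, 1030.0)])
        assert fit.slope == pytest.approx(0.15)
        assert fit.v_298 == pytest.approx(1029.7)
        assert fit.alpha_v_298 == pytest.approx(145.67, abs=0.01)
        assert fit.su_alpha_v is None and fit.r_squared is None
        assert fit.two_point

    def test_collinear_series_has_unit_r_squared(self):
        pts = [(t, 900.0 + 0.2 * t) for t in (100, 150, 200, 293)]
        fit = volumetric_fit(pts)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.su_alpha_v == pytest.approx(0.0, abs=1e-6)

    def test_hc1_slope_error_matches_sandwich_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 12))
            t = np.sort(rng.uniform(90, 300, n))
            # heteroscedastic noise growing with T
            y = 950 + 0.18 * t + rng.normal(0, 1e-3 * t, n)
            fit = volumetric_fit(list(zip(t, y)))
            se = hand_coded_hc1_slope_se(t, y)
            su_expected = 1e6 * se * abs(fit.intercept) / fit.v_298**2
            assert fit.su_alpha_v == pytest.approx(su_expected, rel=1e-10)

    def test_duplicate_temperatures_rejected(self):
        with pytest.raises(DuplicateTemperatureError):
            volumetric_fit([(100.0, 1000.0), (100.0, 1001.0), (200.0, 1010.0)])


class TestStrainTensor:
    def test_self_strain_is_zero(self):
        cell = UnitCell(6, 7, 8, 90, 101, 90)
        assert np.allclose(strain_tensor_pair(cell, cell), np.zeros((3, 3)), atol=1e-14)

    def test_isotropic_closed_form(self):
        a = UnitCell(10, 10, 10, 90, 90, 90)
        b = UnitCell(10.2, 10.2, 10.2, 90, 90, 90)
        assert np.allclose(strain_tensor_pair(a, b), 0.02 * np.eye(3), atol=1e-12)

    def test_monoclinic_beta_change_keeps_b_eigenvector(self):
        a = UnitCell(6, 7, 9, 90, 100, 90)
        b = UnitCell(6, 7, 9, 90, 101, 90)
        e = strain_tensor_pair(a, b)
        assert abs(e[0, 1]) < 1e-15 and abs(e[1, 2]) < 1e-15
        evals, evecs = np.linalg.eigh(e)
        i = int(np.argmax(np.abs(evecs[1])))
        assert np.allclose(np.abs(evecs[:, i]), [0, 1, 0])

    def test_matches_explicit_matrix_oracle(self, rng):
        from conftest import random_cell

        for _ in range(50):
            a, b = random_cell(rng), random_cell(rng)
            ma, mb = orthogonalization_matrix(a), orthogonalization_matrix(b)
            f = mb @ np.linalg.inv(ma)
            expected = 0.5 * (f + f.T) - np.eye(3)
            got = strain_tensor_pair(a, b, setting_guard=None)
            assert np.allclose(got, expected, atol=1e-12)

    def test_polymorph_guard(self):
        a = UnitCell(6, 7, 9, 90, 100, 90)
        b = UnitCell(7.5, 8.0, 9.5, 90, 100, 90)  # > 12% deformation
        with pytest.raises(InconsistentSettingError):
            strain_tensor_pair(a, b)


class TestPrincipalFit:
    def test_isotropic_two_point_closed_form(self):
        a = UnitCell(10, 10, 10, 90, 90, 90)
        b = UnitCell(10.2, 10.2, 10.2, 90, 90, 90)
        res = expansion_for_family_cells([a, b], [100.0, 300.0])
        # k = 1e-4 per K -> alpha(298) = 1e-4 / (1 + 1e-4 * 198) = 98.06 ppm
        for alpha in res.alpha_l:
            assert alpha == pytest.approx(98.06, abs=0.01)
        assert res.alpha_v.alpha_v_298 == pytest.approx(288.6, abs=0.1)
        assert res.sum_alpha_l == pytest.approx(294.2, abs=0.1)
        # first-order identity: sum(alpha_L) approximates alpha_V within 2%
        assert abs(res.sum_alpha_l - res.alpha_v.alpha_v_298) / res.alpha_v.alpha_v_298 < 0.02

    def test_monoclinic_axis_exactly_on_b(self):
        ref = UnitCell(6, 8, 10, 90, 104, 90)
        k = np.array([[8e-5, 0, 3e-5], [0, 5e-5, 0], [3e-5, 0, 1.2e-4]])
        a_ref = orthogonalization_matrix(ref)
        cells, temps = [ref], [100.0]
        from thermex.cells import cell_from_metric

        for t in (160.0, 220.0, 293.0):
            m = (np.eye(3) + (t - 100.0) * k) @ a_ref
            cells.append(cell_from_metric(m.T @ m))
            temps.append(t)
        res = expansion_for_family_cells(cells, temps)
        hits = [np.allclose(axis, [0, 1, 0]) for axis in res.principal_axes]
        assert sum(hits) == 1

    def test_planted_slope_tensor_recovered(self, rng):
        """Anisotropic family with a rotated planted rate tensor: eigenvalues
        recovered to < 0.5% at zero noise."""
        from thermex.cells import cell_from_metric

        planted = np.array([120e-6, 40e-6, -30e-6])
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        k = q @ np.diag(planted) @ q.T
        ref = UnitCell(7, 9, 11, 90, 90, 90)
        a_ref = orthogonalization_matrix(ref)
        temps = [90.0, 150.0, 210.0, 293.0]
        cells = []
        for t in temps:
            m = (np.eye(3) + (t - 90.0) * k) @ a_ref
            cells.append(cell_from_metric(m.T @ m))
        series = build_strain_series(cells, temps, setting_guard=None)
        alphas, _, _, corrs = principal_fit(series)
        # undo the 298 K referencing (alpha = 1e6 k / corr) to compare raw rates;
        # the linear-strain construction truncates at second order, so agreement
        # is to 0.5% of the dominant rate
        recovered = np.sort([a * c / 1e6 for a, c in zip(alphas, corrs)])
        assert np.allclose(recovered, np.sort(planted), atol=5e-3 * np.abs(planted).max())

    def test_rotation_invariance_of_eigenvalues(self):
        """Consistently permuting all cells' axes leaves eigenvalues unchanged."""
        ref = UnitCell(7, 9, 11, 90, 90, 90)
        k = np.diag([110e-6, 60e-6, 20e-6])
        from thermex.cells import cell_from_metric

        a_ref = orthogonalization_matrix(ref)
        temps = [100.0, 200.0, 293.0]
        cells, swapped = [], []
        for t in temps:
            m = (np.eye(3) + (t - 100.0) * k) @ a_ref
            cell = cell_from_metric(m.T @ m)
            cells.append(cell)
            swapped.append(UnitCell(cell.b, cell.a, cell.c, cell.beta, cell.alpha, cell.gamma))
        r1 = principal_fit(build_strain_series(cells, temps, setting_guard=None))
        r2 = principal_fit(build_strain_series(swapped, temps, setting_guard=None))
        assert np.allclose(r1[0], r2[0], rtol=1e-8)


class TestAnisotropyAndNte:
    def test_isotropic_gives_zero(self):
        assert anisotropy((100.0, 100.0, 100.0)) == 0.0

    @pytest.mark.parametrize(
        "triple,printed",
        [
            ((-254, 160, 228), 3.575),
            ((-225, 52, 339), 3.383),
        ],
    )
    def test_published_extreme_values(self, triple, printed):
        # printed inputs are rounded to integers, so agree within 1%
        assert anisotropy(triple) == pytest.approx(printed, rel=0.01)

    def test_zero_sum_is_undefined(self):
        with pytest.raises(UndefinedAnisotropyError):
            anisotropy((-100.0, 0.0, 100.0))

    def test_volumetric_denominator_option(self):
        assert anisotropy((-10.0, 10.0, 40.0), denominator=50.0) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "alphas,sus,expected_class,expected_conclusive",
        [
            ((-249, -99, 623), (34, 22, 64), "biaxial", (True, True)),
            ((5, 50, 100), (1, 1, 1), "none", ()),
            ((-5, 50, 100), (8, 1, 1), "uniaxial", (False,)),
            ((-50, -40, -30), (5, 5, 5), "triaxial", (True, True, True)),
            ((-50, 40, 90), (None, None, None), "uniaxial", (False,)),
        ],
    )
    def test_nte_classification(self, alphas, sus, expected_class, expected_conclusive):
        cls, conclusive = classify_nte(alphas, sus)
        assert cls == expected_class
        assert conclusive == expected_conclusive
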