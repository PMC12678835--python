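import warnings

import numpy as np
import pytest

from afmindent import core_io
from afmindent.calibration import (
    TipProfile,
    average_loading_curves,
    calibrate_tip,
    contact_depth_map,
    contact_radius_profile,
    depth_scaling_kappa,
    evaluate_tip,
    fit_tip_profile,
    load_index_from_profile_index,
    load_index_profile,
    power_law_cap,
    profile_index,
    smooth_load_curve,
)
from afmindent.config import CalibrationConfig
from afmindent.exceptions import DataError, GeometryError, ParameterError
from afmindent.synthetic import (
    IndenterTruth,
    elastic_reference_curve,
    power_law_elastic_force,
)
from afmindent.units import c_si_to_um, c_um_to_si
from tests.conftest import E_STAR_REF


class TestScalarRelations:
    def test_profile_index_printed_values(self):
        assert profile_index(1.45) == pytest.approx(2.22, abs=5e-3)
        assert profile_index(1.5) == pytest.approx(2.0, rel=1e-12)
        assert profile_index(2.0) == pytest.approx(1.0, rel=1e-12)

    def test_profile_index_undefined_at_linear_loading(self):
        with pytest.raises(ParameterError, match="linear"):
            profile_index(1.0)
        with pytest.raises(ParameterError):
            profile_index(0.8)

    def test_index_relations_mutual_inverse(self):
        m = np.linspace(1.1, 3.0, 40)
        np.testing.assert_allclose(load_index_from_profile_index(profile_index(m)), m, rtol=1e-12)

    def test_kappa_closed_forms(self):
        assert depth_scaling_kappa(2.0) == pytest.approx(2.0, abs=1e-12)
        assert depth_scaling_kappa(1.0) == pytest.approx(np.pi / 2, abs=1e-12)
        assert depth_scaling_kappa(4.0) == pytest.approx(8.0 / 3.0, abs=1e-12)

    def test_kappa_increasing_and_above_one(self):
        n = np.linspace(0.5, 10, 200)
        k = depth_scaling_kappa(n)
        assert np.all(np.diff(k) > 0)
        assert np.all(k > 1)

    def test_contact_depth_map_hertz_and_cone(self):
        assert contact_depth_map(40e-9, 2.0) == pytest.approx(20e-9, rel=1e-12)
        assert contact_depth_map(40e-9, 1.0) == pytest.approx(40e-9 * 2 / np.pi, rel=1e-12)
        assert contact_depth_map(40e-9, 1.0) == pytest.approx(25.46e-9, rel=1e-3)

    def test_contact_radius_examples(self):
        # S = 0.01 N/m at E* = 3.79 MPa -> a = 1.32 nm
        assert contact_radius_profile(0.01, 3.79e6) == pytest.approx(1.3193e-9, rel=1e-4)
        # Hertz R = 50 nm, h = 10 nm: S = 2 E* sqrt(R h / 2)
        R, h = 50e-9, 10e-9
        S = 2 * E_STAR_REF * np.sqrt(R * h / 2)
        assert contact_radius_profile(S, E_STAR_REF) == pytest.approx(
            np.sqrt(R * h / 2), rel=1e-12
        )
        assert np.sqrt(R * h / 2) == pytest.approx(15.81e-9, rel=1e-3)

    def test_contact_radius_invalid_modulus(self):
        with pytest.raises(ParameterError):
            contact_radius_profile(0.01, -1.0)

    def test_c_unit_conversion_round_trip(self):
        for n in (1.0, 2.0, 7.55):
            c = 1.0 / (2 * 50e-9) ** (n - 1)
            assert c_um_to_si(c_si_to_um(c, n), n) == pytest.approx(c, rel=1e-12)


class TestSmoothLoadCurve:
    def test_exact_quadratic_recovered(self):
        h = np.linspace(0, 1e-7, 200)[1:]
        alpha, beta = 2.0, 3.0e7
        F = alpha * h + beta * h**2
        poly = smooth_load_curve(h, F, order=2)
        assert poly.coeffs[0] == pytest.approx(alpha, rel=1e-9)
        assert poly.coeffs[1] == pytest.approx(beta, rel=1e-9)
        # derivative is analytic
        np.testing.assert_allclose(poly.stiffness(h), alpha + 2 * beta * h, rtol=1e-8)

    def test_order_one_rejected(self):
        h = np.linspace(0, 1e-7, 50)[1:]
        with pytest.raises(ParameterError):
            smooth_load_curve(h, 2.0 * h, order=1)

    def test_hertz_data_order6_relative_accuracy(self):
        h = np.linspace(0, 1e-7, 400)[1:]
        F = power_law_elastic_force(E_STAR_REF, 1.0 / (2 * 50e-9), 2.0, h)
        poly = smooth_load_curve(h, F, order=6, relative_weight=False)
        sel = h >= 0.1 * h.max()
        dev = np.abs(poly.force(h[sel]) - F[sel]) / F.max()
        assert dev.max() < 1e-3

    def test_quadratic_load_index_analytic(self):
        h = np.linspace(0, 1e-7, 300)[1:]
        alpha, beta = 1.0, 5e7
        F = alpha * h + beta * h**2
        poly = smooth_load_curve(h, F, order=2)
        m = load_index_profile(poly, h)
        np.testing.assert_allclose(m, (alpha + 2 * beta * h) / (alpha + beta * h), rtol=1e-6)
        assert m[0] < 1.1 and m[-1] > 1.7  # limits: 1 near contact, 2 at depth


class TestAverageLoadingCurves:
    def test_identical_curves_mean_is_input(self):
        h = np.linspace(0, 1e-7, 100)[1:]
        F = 3.0 * h
        grid = np.linspace(0, 9e-8, 50)[1:]
        mean, sd, n = average_loading_curves([(h, F)] * 64, grid)
        np.testing.assert_allclose(mean, 3.0 * grid, rtol=1e-12)
        np.testing.assert_allclose(sd, 0.0, atol=1e-18)
        assert n == 64

    def test_two_hertz_curves_average_of_closed_forms(self):
        h = np.linspace(0, 1e-7, 4000)[1:]  # dense: limits interpolation error
        c = 1.0 / (2 * 50e-9)
        F1 = power_law_elastic_force(2e6, c, 2.0, h)
        F2 = power_law_elastic_force(6e6, c, 2.0, h)
        grid = np.linspace(0, 9e-8, 60)[1:]
        mean, _, _ = average_loading_curves([(h, F1), (h, F2), (h, F1), (h, F2)], grid)
        expect = 0.5 * (
            power_law_elastic_force(2e6, c, 2.0, grid) + power_law_elastic_force(6e6, c, 2.0, grid)
        )
        np.testing.assert_allclose(mean, expect, rtol=1e-4)

    def test_grid_beyond_support_rejected(self):
        h = np.linspace(0, 1e-8, 50)[1:]
        grid = np.linspace(0, 1e-6, 50)[1:]
        with pytest.warns(UserWarning), pytest.raises(DataError):
            average_loading_curves([(h, 2.0 * h)] * 5, grid)

    def test_shallow_curves_excluded_with_warning(self):
        h_deep = np.linspace(0, 1e-7, 100)[1:]
        h_shallow = np.linspace(0, 3e-8, 100)[1:]
        grid = np.linspace(0, 9e-8, 50)[1:]
        with pytest.warns(UserWarning, match="excluded"):
            _, _, n = average_loading_curves(
                [(h_deep, 2 * h_deep)] * 3 + [(h_shallow, 2 * h_shallow)], grid
            )
        assert n == 3


def _calibrate(tip_truth, noise=0.0, ncurves=8, seed=1, config=None):
    rng = np.random.default_rng(seed)
    inds = []
    for _ in range(ncurves):
        rc = elastic_reference_curve(
            tip_truth, e_star=E_STAR_REF, f_max=250e-9, noise_sd=noise, rng=rng
        )
        z0, f0 = core_io.detect_contact_point(rc, deep_refine=True)
        inds.append(core_io.to_indentation(rc, z0, f0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return calibrate_tip(inds, config or CalibrationConfig())


class TestFitTipProfile:
    def test_truncated_cone_radius_function_recovered(self):
        # the local-kappa depth mapping is approximate for non-power-law tips,
        # so the recovered radius function (not each coefficient) is checked
        truth = IndenterTruth(kind="polynomial", coeffs=np.array([20e-9, 0.55]))
        res = _calibrate(truth)
        for h_c in (50e-9, 100e-9, 200e-9):
            a_true = truth.contact_radius(h_c)
            a_rec = res.tip.radius(h_c, warn_extrapolation=False)
            assert a_rec == pytest.approx(a_true, rel=0.05)
        assert res.tip.poly_coeffs[0] == pytest.approx(20e-9, rel=0.15)
        assert res.tip.poly_coeffs[1] == pytest.approx(0.55, rel=0.15)

    def test_paraboloid_radius_at_half_R(self):
        truth = IndenterTruth(kind="paraboloid", R=50e-9)
        res = _calibrate(truth)
        a = evaluate_tip(res.tip, 20e-9, warn_extrapolation=False)
        assert a == pytest.approx(np.sqrt(2 * 50e-9 * 20e-9), rel=0.02)
        assert np.sqrt(2 * 50e-9 * 20e-9) == pytest.approx(44.7e-9, rel=1e-3)

    def test_too_few_points_rejected(self, config):
        h_c = np.linspace(20e-9, 100e-9, 10)
        a = 2.0 * h_c
        with pytest.raises(DataError, match="20"):
            fit_tip_profile(a, h_c, config)

    def test_monotone_radius_from_hertz_synthetic(self):
        truth = IndenterTruth(kind="paraboloid", R=50e-9)
        res = _calibrate(truth)
        dense = np.linspace(res.tip.h_c_min + 1e-12, res.tip.h_c_max, 500)
        a = res.tip.radius(dense, warn_extrapolation=False)
        assert np.all(np.diff(a) > 0)


class TestEvaluateTip:
    def test_cap_passes_through_origin(self):
        tip = TipProfile.from_power_law(c=1.0 / (2 * 50e-9), n=2.0)
        assert evaluate_tip(tip, 0.0) == 0.0

    def test_extrapolation_warns(self):
        tip = TipProfile.from_polynomial([1e-8, 0.5], h_c_min=5e-9, h_c_max=2e-7)
        with pytest.warns(UserWarning, match="beyond"):
            evaluate_tip(tip, 4e-7)
        assert tip.extrapolated(4e-7)
        assert not tip.extrapolated(1e-7)

    def test_serialization_round_trip(self, tmp_path):
        tip = TipProfile.from_polynomial([1e-8, 0.5, 1e5], h_c_min=5e-9, h_c_max=2e-7,
                                         cap_limit=5e-9)
        path = tip.to_json(tmp_path / "tip.json")
        tip2 = TipProfile.from_json(path)
        h_c = np.linspace(0, 2e-7, 50)
        np.testing.assert_allclose(
            tip.radius(h_c, warn_extrapolation=False),
            tip2.radius(h_c, warn_extrapolation=False),
            rtol=1e-12,
        )


class TestFullChainRecovery:
    def test_power_law_tip_noiseless_within_2pc(self, power_law_tip):
        res = _calibrate(power_law_tip)
        assert res.tip.cap_n == pytest.approx(power_law_tip.n, rel=0.02)
        c_um_true = c_si_to_um(power_law_tip.c, power_law_tip.n)
        assert c_si_to_um(res.tip.cap_c, res.tip.cap_n) == pytest.approx(c_um_true, rel=0.02)

    def test_load_index_constant_for_power_law(self, power_law_tip):
        # the polynomial ratio wiggles at the very edges of its fit range, so
        # constancy is checked over the interior
        res = _calibrate(power_law_tip)
        m_expect = 1 + 1 / power_law_tip.n
        frac = res.depth / res.depth.max()
        sel = (frac >= 0.1) & (frac <= 0.9)
        np.testing.assert_allclose(res.load_index[sel], m_expect, rtol=0.025)

    def test_power_law_cap_inversion_exact(self):
        # closed-form oracle: generate F = b h^m directly, no pipeline
        h = np.linspace(0, 3e-7, 2000)[1:]
        c, n = 5e8, 2.5
        F = power_law_elastic_force(E_STAR_REF, c, n, h)
        c_fit, n_fit = power_law_cap(h, F, E_STAR_REF, float(h.max()))
        assert n_fit == pytest.approx(n, rel=1e-6)
        assert c_fit == pytest.approx(c, rel=1e-4)
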