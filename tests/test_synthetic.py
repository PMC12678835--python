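import numpy as np
import pytest

from afmindent.calibration import depth_scaling_kappa
from afmindent.exceptions import GeometryError, ParameterError
from afmindent.synthetic import (
    DEFAULT_TIP_TRUTH,
    IndenterTruth,
    MaterialTruth,
    elastoplastic_curve,
    elastoplastic_state,
    generate_dataset,
    power_law_elastic_force,
    relaxation_curve,
    sneddon_elastic_curve,
)


class TestPowerLawElasticForce:
    def test_hertz_identity_at_n2(self):
        R = 50e-9
        h = np.linspace(0, 1e-7, 50)
        F = power_law_elastic_force(3.79e6, 1.0 / (2 * R), 2.0, h)
        np.testing.assert_allclose(F, (4.0 / 3.0) * 3.79e6 * np.sqrt(R) * h**1.5, rtol=1e-13)

    def test_reference_modulus_example(self):
        # E* = 3.79 MPa, R = 50 nm, h = 10 nm -> F = 1.12996e-9 N (Hertz)
        F = power_law_elastic_force(3.79e6, 1.0 / (2 * 50e-9), 2.0, 10e-9)
        assert F == pytest.approx(1.1299596846298936e-09, rel=1e-12)
        assert F == pytest.approx(1.13e-9, rel=5e-3)

    def test_zero_depth_zero_force(self):
        assert power_law_elastic_force(3.79e6, 1e7, 2.0, 0.0) == 0.0

    def test_load_index_matches_inverse_relation(self):
        # F ~ h^((n+1)/n), so a log-log fit recovers m = 1 + 1/n
        n = 2.5
        h = np.geomspace(1e-9, 1e-7, 200)
        F = power_law_elastic_force(3.79e6, 1e8, n, h)
        slope = np.polyfit(np.log(h), np.log(F), 1)[0]
        assert slope == pytest.approx(1 + 1 / n, abs=1e-6)

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            power_law_elastic_force(3.79e6, -1.0, 2.0, 1e-9)
        with pytest.raises(ParameterError):
            power_law_elastic_force(3.79e6, 1e7, 2.0, -1e-9)


class TestSneddonElasticCurve:
    def test_paraboloid_gives_hertz_exponent(self):
        tip = IndenterTruth(kind="paraboloid", R=53e-9)
        curve = sneddon_elastic_curve(tip, 3.79e6, 2e-7, n_points=400)
        h, F = curve.loading()
        sel = h > 0.05 * h.max()
        slope = np.polyfit(np.log(h[sel]), np.log(F[sel]), 1)[0]
        assert slope == pytest.approx(1.5, abs=1e-3)

    def test_truncated_cone_matches_quadrature_oracle(self):
        # independent oracle: same local-exponent mapping on a 10x finer grid,
        # integrated by trapezoid, written from scratch here
        coeffs = np.array([20e-9, 0.55])
        tip = IndenterTruth(kind="polynomial", coeffs=coeffs)
        e_star = 3.79e6
        h_max = 3e-7

        h_c = np.geomspace(h_max * 1e-6, h_max, 40000)
        a = coeffs[0] + coeffs[1] * h_c
        n_loc = 1.0 / np.gradient(np.log(a), np.log(h_c))
        h_or = depth_scaling_kappa(n_loc) * h_c
        F_or = np.concatenate(
            [[0.0], np.cumsum(0.5 * (2 * e_star * a[1:] + 2 * e_star * a[:-1]) * np.diff(h_or))]
        )  # F_or[0] ~ 0 at the first (near-zero) depth node

        curve = sneddon_elastic_curve(tip, e_star, h_max, n_points=300)
        h, F = curve.loading()
        sel = h > 0.02 * h_max
        F_expect = np.interp(h[sel], h_or, F_or)
        np.testing.assert_allclose(F[sel], F_expect, rtol=1e-3)

    def test_too_few_points_rejected(self):
        tip = IndenterTruth(kind="paraboloid", R=50e-9)
        with pytest.raises(ParameterError):
            sneddon_elastic_curve(tip, 3.79e6, 1e-7, n_points=2)

    def test_decreasing_profile_rejected(self):
        tip = IndenterTruth(kind="polynomial", coeffs=np.array([1e-8, -0.5]))
        with pytest.raises(GeometryError):
            sneddon_elastic_curve(tip, 3.79e6, 1e-7, n_points=100)


class TestElastoplasticCurve:
    def test_initial_unloading_stiffness_example(self):
        # a = 100 nm at peak with E = 1 GPa, nu = 0.4:
        # S0 = 2 a E / (1 - nu^2) = 238.1 N/m
        E, nu, a = 1e9, 0.4, 1e-7
        f_max = 2e-6
        H = f_max / (np.pi * a**2)  # forces the peak contact radius to 100 nm
        truth = MaterialTruth(behaviour="elastoplastic", E=E, nu=nu, H=H)
        tip = IndenterTruth(kind="polynomial", coeffs=np.array([0.0, 0.3]))
        state = elastoplastic_state(truth, tip, f_max)
        assert state["a"] == pytest.approx(1e-7, rel=1e-12)
        assert state["S0"] == pytest.approx(238.095, rel=1e-4)

    def test_contact_radius_from_hardness_example(self):
        # F = pi a^2 H: 2 uN at H = 177 MPa -> a = 60 nm
        truth = MaterialTruth(behaviour="elastoplastic", E=2e9, nu=0.4, H=176.8388e6)
        state = elastoplastic_state(truth, DEFAULT_TIP_TRUTH, 2e-6)
        assert state["a"] == pytest.approx(60e-9, rel=1e-4)

    def test_hysteresis_and_residual_depth(self, cone_tip, cell_truth):
        curve = elastoplastic_curve(cell_truth, cone_tip, f_max=2e-6)
        m_app = curve.seg_mask("approach")
        m_ret = curve.seg_mask("retract")
        # unloading force is below loading force at matched heights
        z_common = np.linspace(curve.height[m_app].max() * 0.3, curve.height[m_app].max() * 0.9, 20)
        F_load = np.interp(z_common, curve.height[m_app], curve.signal[m_app])
        F_unl = np.interp(z_common, curve.height[m_ret][::-1], curve.signal[m_ret][::-1])
        assert np.all(F_unl <= F_load + 1e-15)
        state = elastoplastic_state(cell_truth, cone_tip, 2e-6)
        assert state["h_f"] > 0

    def test_nearly_elastic_limit_small_residual(self, cone_tip):
        soft = MaterialTruth(behaviour="elastoplastic", E=1e9, nu=0.4, H=150e6)
        hard = MaterialTruth(behaviour="elastoplastic", E=1e9, nu=0.4, H=600e6)
        s_soft = elastoplastic_state(soft, cone_tip, 2e-6)
        s_hard = elastoplastic_state(hard, cone_tip, 2e-6)
        # plasticity index h_f / h_max shrinks as H approaches E
        assert s_hard["h_f"] / s_hard["h_max"] < s_soft["h_f"] / s_soft["h_max"]

    def test_nonphysical_hardness_rejected(self, cone_tip):
        truth = MaterialTruth(behaviour="elastoplastic", E=1e8, nu=0.4, H=2e8)
        with pytest.raises(ParameterError):
            elastoplastic_curve(truth, cone_tip, f_max=2e-6)

    def test_noise_requires_rng(self, cone_tip, cell_truth):
        with pytest.raises(ParameterError):
            elastoplastic_curve(cell_truth, cone_tip, f_max=2e-6, noise_sd=1e-9)


class TestRelaxationCurve:
    def test_initial_force_example(self, visco_truth):
        # C0 + C1 + C2 = 198 MPa at a = 60 nm -> F(0) = 2.24 uN
        t, F = relaxation_curve(visco_truth, 60e-9, dwell=4.0, dt=0.004)
        assert F[0] == pytest.approx(np.pi * (60e-9) ** 2 * 198e6, rel=1e-12)
        assert F[0] == pytest.approx(2.24e-6, rel=5e-3)

    def test_constant_when_no_prony_terms(self):
        truth = MaterialTruth(behaviour="viscoplastic", E=1e9, C0=150e6, C1=0, C2=0,
                              tau1=0.1, tau2=2.0)
        t, F = relaxation_curve(truth, 60e-9, dwell=4.0, dt=0.004)
        assert np.all(F == F[0])

    def test_end_of_hold_matches_closed_form(self, visco_truth):
        t, F = relaxation_curve(visco_truth, 60e-9, dwell=4.0, dt=0.001)
        expect = np.pi * (60e-9) ** 2 * (
            visco_truth.C0
            + visco_truth.C1 * np.exp(-4.0 / visco_truth.tau1)
            + visco_truth.C2 * np.exp(-4.0 / visco_truth.tau2)
        )
        assert F[-1] == pytest.approx(expect, rel=1e-9)

    def test_monotone_non_increasing(self, visco_truth):
        _, F = relaxation_curve(visco_truth, 60e-9, dwell=4.0, dt=0.002)
        assert np.all(np.diff(F) <= 1e-20)

    def test_negative_coefficient_rejected(self):
        with pytest.raises(ParameterError):
            MaterialTruth(behaviour="viscoplastic", E=1e9, C0=-1.0, C1=0, C2=0,
                          tau1=0.1, tau2=2.0)


class TestGenerateDataset:
    def test_deterministic_for_fixed_seed(self, tmp_path):
        kw = dict(participants=1, cells_per_participant=1, grid_shape=(2, 2),
                  include_reference=False)
        m1 = generate_dataset(tmp_path / "a", seed=1, **kw)
        m2 = generate_dataset(tmp_path / "b", seed=1, **kw)
        assert m1.read_text() == m2.read_text()
        f1 = sorted((tmp_path / "a" / "curves").glob("*.tsv"))[0]
        f2 = sorted((tmp_path / "b" / "curves").glob("*.tsv"))[0]
        assert f1.read_text() == f2.read_text()
        assert (tmp_path / "a" / "truth.csv").read_text() == (
            tmp_path / "b" / "truth.csv"
        ).read_text()

    def test_seed_changes_output(self, tmp_path):
        kw = dict(participants=1, cells_per_participant=1, grid_shape=(2, 2),
                  include_reference=False)
        m1 = generate_dataset(tmp_path / "a", seed=1, **kw)
        m2 = generate_dataset(tmp_path / "b", seed=2, **kw)
        t1 = (tmp_path / "a" / "truth.csv").read_text()
        t2 = (tmp_path / "b" / "truth.csv").read_text()
        assert t1 != t2

    def test_manifest_counts(self, tmp_path):
        import pandas as pd

        manifest = generate_dataset(
            tmp_path, seed=3, participants=2, cells_per_participant=3,
            grid_shape=(2, 2), include_reference=True, reference_curves=4,
        )
        df = pd.read_csv(manifest)
        assert len(df) == 2 * 3 * 4
        truth = pd.read_csv(tmp_path / "truth.csv")
        assert len(truth) == len(df)
        ref = pd.read_csv(tmp_path / "reference_manifest.csv")
        assert len(ref) == 4
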