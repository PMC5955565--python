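"""Modulation decomposition, cone-model inversion, and distortion handling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from actinorder.polarimetry import (
    DistortionCalibration,
    PolarizationStack,
    compensate_distortion,
    compute_modulation_coefficients,
    cone_modulation,
    cone_modulation_3d,
    harmonic_least_squares,
    invert_cone_model,
    invert_cone_psi,
)
from actinorder.synthetic import AcquisitionConfig, DEFAULT_ANGLES, forward_simulate

from conftest import constant_psi_stack


def _stack_from_signal(fn, angles=DEFAULT_ANGLES, shape=(2, 2)):
    pages = np.stack([np.full(shape, fn(a)) for a in angles])
    return PolarizationStack(data=pages, angles=angles)


class TestModulationCoefficients:
    @pytest.mark.parametrize(
        "signal, exp_a2, exp_b2",
        [
            (lambda a: 3.0, 0.0, 0.0),
            (lambda a: 1 + 0.5 * np.cos(2 * np.deg2rad(a)), 0.5, 0.0),
            (lambda a: 1 + 0.4 * np.sin(2 * np.deg2rad(a)), 0.0, 0.4),
        ],
    )
    def test_summation_formulas_on_uniform_grid(self, signal, exp_a2, exp_b2):
        coeffs = compute_modulation_coefficients(_stack_from_signal(signal))
        assert coeffs.a2 == pytest.approx(exp_a2, abs=1e-12)
        assert coeffs.b2 == pytest.approx(exp_b2, abs=1e-12)

    def test_unmodulated_total_intensity(self):
        coeffs = compute_modulation_coefficients(_stack_from_signal(lambda a: 3.0))
        assert coeffs.a0 == pytest.approx(30.0)

    def test_dark_pixels_flagged_invalid(self):
        pages = np.ones((10, 4, 4))
        pages[:, 0, 0] = 0.0
        coeffs = compute_modulation_coefficients(
            PolarizationStack(data=pages, angles=DEFAULT_ANGLES), intensity_floor=1.0
        )
        assert not coeffs.valid[0, 0]
        assert coeffs.a2[0, 0] == 0.0 and coeffs.b2[0, 0] == 0.0
        assert coeffs.valid[1, 1]

    def test_page_angle_mismatch_is_hard_error(self):
        with pytest.raises(ValueError, match="does not match"):
            PolarizationStack(data=np.ones((9, 4, 4)), angles=DEFAULT_ANGLES)

    def test_too_few_distinct_angles_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            PolarizationStack(data=np.ones((3, 2, 2)), angles=np.array([0.0, 180.0, 90.0]))

    def test_sums_agree_with_least_squares_oracle(self):
        rng = np.random.default_rng(42)
        pages = rng.uniform(0.5, 2.0, size=(10, 8, 8))
        stack = PolarizationStack(data=pages, angles=DEFAULT_ANGLES)
        coeffs = compute_modulation_coefficients(stack, intensity_floor=0.0)
        a0, a2, b2 = harmonic_least_squares(pages, DEFAULT_ANGLES)
        assert np.allclose(coeffs.a0, a0, atol=1e-10)
        assert np.allclose(coeffs.a2, a2, atol=1e-10)
        assert np.allclose(coeffs.b2, b2, atol=1e-10)

    def test_nonuniform_grid_recovers_truth_via_least_squares(self):
        angles = np.array([0.0, 20.0, 50.0, 80.0, 100.0, 140.0, 165.0])
        stack = constant_psi_stack(30.0, 120.0, angles=angles)
        order = invert_cone_model(compute_modulation_coefficients(stack))
        assert order.rho.flat[0] == pytest.approx(30.0, abs=1e-8)
        assert order.psi.flat[0] == pytest.approx(120.0, abs=1e-6)


class TestConeModulation:
    def test_closed_form_values(self):
        assert cone_modulation(180.0) == pytest.approx(0.0, abs=1e-15)
        assert cone_modulation(90.0) == pytest.approx(2.0 / np.pi)
        assert cone_modulation(1.0) > 0.9999

    def test_strictly_decreasing(self):
        psi = np.linspace(1.0, 180.0, 500)
        m = cone_modulation(psi)
        assert np.all(np.diff(m) < 0)

    @pytest.mark.parametrize("bad", [0.0, -5.0, 180.1])
    def test_domain_enforced(self, bad):
        with pytest.raises(ValueError):
            cone_modulation(bad)

    def test_3d_kernel_limits_and_monotonicity(self):
        psi = np.linspace(1.0, 180.0, 40)
        m = cone_modulation_3d(psi)
        assert np.all(np.diff(m) < 0)
        assert m[-1] == pytest.approx(0.0, abs=1e-5)
        assert m[0] > 0.999


class TestInversion:
    def test_isotropic_pixel_yields_full_aperture(self):
        stack = _stack_from_signal(lambda a: 7.0)
        order = invert_cone_model(compute_modulation_coefficients(stack))
        assert np.all(order.psi == 180.0)
        assert np.all(order.rho == 0.0)

    def test_pure_sine_modulation_means_45_degrees(self):
        stack = _stack_from_signal(lambda a: 1 + 0.5 * np.sin(2 * np.deg2rad(a)))
        order = invert_cone_model(compute_modulation_coefficients(stack))
        assert order.rho.flat[0] == pytest.approx(45.0, abs=1e-9)

    def test_bisection_recovers_psi_grid(self):
        psi0 = np.linspace(1.0, 179.0, 90)
        m = cone_modulation(psi0)
        rec = invert_cone_psi(m)
        assert np.max(np.abs(rec - psi0)) < 1e-4

    def test_psi_nonincreasing_in_modulation(self):
        m = np.linspace(0.0, 1.0, 200)
        psi = invert_cone_psi(m)
        assert np.all(np.diff(psi) <= 0)

    def test_overmodulation_clamped_and_flagged(self):
        pages = np.stack(
            [np.full((2, 2), 1 + 1.2 * np.cos(2 * np.deg2rad(a))) for a in DEFAULT_ANGLES]
        )
        pages = np.clip(pages, 0, None)
        order = invert_cone_model(
            compute_modulation_coefficients(PolarizationStack(data=pages, angles=DEFAULT_ANGLES))
        )
        assert np.all(order.clipped)
        assert np.all(order.psi > 0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        rho=st.floats(0.0, 179.0),
        psi=st.floats(5.0, 175.0),
        delta=st.floats(0.0, 179.0),
    )
    def test_rotation_equivariance(self, rho, psi, delta):
        """Rotating every dipole by delta shifts rho by delta mod 180, psi fixed."""
        base = invert_cone_model(
            compute_modulation_coefficients(constant_psi_stack(rho, psi, shape=(1, 1)))
        )
        rot = invert_cone_model(
            compute_modulation_coefficients(
                constant_psi_stack((rho + delta) % 180.0, psi, shape=(1, 1))
            )
        )
        drho = (rot.rho - base.rho - delta + 90.0) % 180.0 - 90.0
        assert abs(drho.flat[0]) < 1e-6
        assert rot.psi.flat[0] == pytest.approx(base.psi.flat[0], abs=1e-6)

    def test_intensity_scale_invariance(self):
        stack = constant_psi_stack(30.0, 130.0)
        scaled = PolarizationStack(data=stack.data * 37.5, angles=stack.angles)
        o1 = invert_cone_model(compute_modulation_coefficients(stack))
        o2 = invert_cone_model(compute_modulation_coefficients(scaled))
        assert np.allclose(o1.rho, o2.rho, atol=1e-9)
        assert np.allclose(o1.psi, o2.psi, atol=1e-9)


class TestDistortionCompensation:
    def test_identity_is_a_no_op(self):
        coeffs = compute_modulation_coefficients(constant_psi_stack(30.0, 120.0))
        out = compensate_distortion(coeffs, DistortionCalibration.identity(10))
        assert np.allclose(out.a2, coeffs.a2) and np.allclose(out.b2, coeffs.b2)

    def test_compensation_restores_ground_truth(self):
        from actinorder.synthetic import GroundTruthScene

        gains = 1 + 0.1 * np.cos(2 * np.deg2rad(DEFAULT_ANGLES))
        ellip = np.full(10, 0.95)
        cal = DistortionCalibration(gains, ellip)
        scene = GroundTruthScene(
            intensity=np.ones((4, 4)),
            rho_true=np.full((4, 4), 25.0),
            psi_true=np.full((4, 4), 130.0),
        )
        stack = forward_simulate(scene, AcquisitionConfig(distortion=cal))
        raw = compute_modulation_coefficients(stack)
        biased = invert_cone_model(raw)
        fixed = invert_cone_model(compensate_distortion(raw, cal))
        assert np.all(np.abs(fixed.psi - 130.0) < 1e-3)
        assert np.all(np.abs(fixed.rho - 25.0) < 1e-3)
        # uncompensated maps are measurably biased
        assert np.all(np.abs(biased.psi - 130.0) > 0.1)

    def test_wrong_calibration_leaves_bias(self):
        gains = 1 + 0.1 * np.cos(2 * np.deg2rad(DEFAULT_ANGLES))
        cal = DistortionCalibration(gains, np.ones(10))
        wrong = DistortionCalibration(np.ones(10), np.full(10, 0.9))
        coeffs = compute_modulation_coefficients(constant_psi_stack(25.0, 130.0))
        # apply wrong compensation to clean data
        out = invert_cone_model(compensate_distortion(coeffs, wrong))
        assert np.all(np.abs(out.psi - 130.0) > 0.01)
        del cal

    def test_nonpositive_gains_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            DistortionCalibration(np.array([1.0, 0.0, 1.0]), np.ones(3))
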