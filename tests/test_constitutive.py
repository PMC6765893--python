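"""Strain-energy function, invariant kinematics and stress."""

import numpy as np
import pytest

from conftest import random_tension_state
from fibreo.constitutive import (
    DeformationState,
    FibrilFrame,
    InvertedElementError,
    MaterialParams,
    cauchy_stress,
    energy_aniso,
    energy_fibril,
    energy_matrix,
    energy_total,
    energy_vol,
    first_elasticity,
    first_piola,
    kinematics,
)
from fibreo.orientations import N_ORIENTATIONS


class TestKinematics:
    def test_reference_state(self, frame):
        st = kinematics(np.eye(3), frame)
        assert abs(st.I1 - 3.0) < 1e-14
        assert abs(st.I3 - 1.0) < 1e-14
        assert abs(st.J - 1.0) < 1e-14
        np.testing.assert_allclose(st.I4, 1.0, atol=1e-14)
        np.testing.assert_allclose(st.I6, 1.0, atol=1e-14)
        assert abs(st.J**2 - st.I3) < 1e-10

    def test_stretch_along_first_orientation(self, frame):
        a = frame.a0[0]
        lam = 1.05
        F = np.eye(3) + (lam - 1.0) * np.outer(a, a)
        st = kinematics(F, frame)
        assert abs(st.I4[0] - lam**2) < 1e-12  # 1.1025

    def test_random_state_matches_matrix_algebra(self, frame):
        rng = np.random.default_rng(0)
        F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        st = kinematics(F, frame)
        C = F.T @ F
        assert abs(st.I1 - np.trace(C)) < 1e-12
        assert abs(st.I3 - np.linalg.det(C)) < 1e-12
        for i in range(N_ORIENTATIONS):
            assert abs(st.I4[i] - frame.a0[i] @ C @ frame.a0[i]) < 1e-12
            assert abs(st.I6[i] - frame.b0[i] @ C @ frame.b0[i]) < 1e-12

    def test_inverted_element_rejected(self, frame):
        with pytest.raises(InvertedElementError):
            kinematics(np.diag([-1.0, 1.0, 1.0]), frame)


class TestFrame:
    def test_unit_vectors_and_elevation(self, frame):
        np.testing.assert_allclose(np.linalg.norm(frame.a0, axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(frame.b0, axis=1), 1.0, atol=1e-12)
        assert np.all(np.abs(frame.a0[:, 2]) < 1e-12)  # in plane
        elev = np.rad2deg(np.arcsin(frame.b0[:, 2]))
        np.testing.assert_allclose(elev, 15.0, atol=1e-10)
        # mirrored sub-family sits below the plane at the same angle
        np.testing.assert_allclose(
            np.rad2deg(np.arcsin(frame.b0_mirror[:, 2])), -15.0, atol=1e-10
        )


class TestEnergyComponents:
    def test_vol_zero_iff_reference_volume(self):
        assert energy_vol(1.0, 1e-5) == 0.0
        assert abs(energy_vol(1.01, 1e-5) - 10.0) < 1e-9
        assert abs(energy_vol(0.99, 1e-5) - energy_vol(1.01, 1e-5)) < 1e-12

    def test_matrix_closed_form(self):
        assert energy_matrix(3.0, 1.0, 0.03) == 0.0
        lam = 1.2
        I1 = lam**2 + 2.0 / lam
        assert abs(energy_matrix(I1, 1.0, 0.5) - 0.5 * (I1 - 3.0)) < 1e-12

    def test_matrix_insensitive_to_pure_dilation(self, frame):
        st = kinematics(1.1 * np.eye(3), frame)
        assert abs(energy_matrix(st.I1, st.I3, 0.3)) < 1e-12

    def test_fibril_hand_value(self):
        # mu=1, gamma=2, x=1.21: 0.5*0.21 - ln(1.1) = 0.0096898...
        w = energy_fibril(1.21, 1.0, 1.0, 2.0)
        assert abs(w - (0.105 - np.log(1.1))) < 1e-12
        assert energy_fibril(1.0, 1.0, 1.0, 2.0) == 0.0

    def test_fibril_stationary_at_reference(self):
        # independent symbolic oracle for dW/dx at x = 1
        import sympy as sp

        x, mu, g = sp.symbols("x mu g", positive=True)
        W = mu / g * (x ** (g / 2) - 1) - mu * sp.log(sp.sqrt(x))
        dW = sp.diff(W, x)
        assert sp.simplify(dW.subs(x, 1)) == 0
        # and the implementation's numeric derivative
        h = 1e-7
        num = (energy_fibril(1 + h, 1.0, 0.02, 40.0) - energy_fibril(1 - h, 1.0, 0.02, 40.0)) / (2 * h)
        assert abs(num) < 1e-8

    def test_aniso_vanishes_in_compression(self, params, frame):
        F = np.diag([0.97, 0.98, 1.0])  # all I4 <= 1, all I6 <= 1
        st = kinematics(F, frame)
        assert np.all(st.I4 <= 1.0) and np.all(st.I6 <= 1.0)
        assert energy_aniso(st, np.ones(16), params) == 0.0

    def test_aniso_matches_bruteforce_orientation_loop(self, params, frame):
        st = kinematics(np.diag([1.04, 1.04, 0.93]), frame)
        K = np.random.default_rng(1).uniform(0.5, 1.5, 16)
        total = 0.0
        for i in range(16):
            for inv, mu, gamma in (
                (st.I4[i], params.mu1, params.gamma1),
                (st.I6[i], 0.5 * params.mu2, params.gamma2),
                (st.I6m[i], 0.5 * params.mu2, params.gamma2),
            ):
                if inv > 1.0:
                    x = st.I3 ** (-1 / 3) * inv
                    total += K[i] * ((mu / gamma) * (x ** (gamma / 2) - 1) - 0.5 * mu * np.log(x))
        expected = total / 16.0
        assert abs(energy_aniso(st, K, params) - expected) < 1e-14

    def test_total_is_sum_of_components(self, params, frame, fixture_K):
        rng = np.random.default_rng(5)
        F = np.eye(3) * 1.02 + 0.02 * rng.standard_normal((3, 3))
        st = kinematics(F, frame)
        total = energy_total(st, fixture_K.K, params)
        parts = (
            energy_vol(st.J, params.D)
            + energy_matrix(st.I1, st.I3, params.C10)
            + energy_aniso(st, fixture_K.K, params)
        )
        assert abs(total - parts) < 1e-14

    def test_zero_at_reference_for_any_distribution(self, params, frame):
        st = kinematics(np.eye(3), frame)
        for seed in range(3):
            K = np.random.default_rng(seed).uniform(0, 2, 16)
            assert abs(energy_total(st, K, params)) < 1e-15


class TestInvariance:
    def test_rigid_rotation_leaves_energy_unchanged(self, params, frame, fixture_K):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(11)
        F = np.eye(3) * 1.03 + 0.03 * rng.standard_normal((3, 3))
        W = energy_total(kinematics(F, frame), fixture_K.K, params)
        for _ in range(5):
            Q = Rotation.random(rng=rng).as_matrix()
            WQ = energy_total(kinematics(Q @ F, frame), fixture_K.K, params)
            assert abs(WQ - W) < 1e-10 * max(1.0, abs(W))

    def test_energy_monotone_in_each_density(self, params, frame):
        rng = np.random.default_rng(3)
        F = random_tension_state(rng, frame)
        K = rng.uniform(0.5, 1.5, 16)
        st = kinematics(F, frame)
        W0 = energy_total(st, K, params)
        for i in range(16):
            Kp = K.copy()
            Kp[i] += 0.1
            assert energy_total(st, Kp, params) >= W0 - 1e-15


class TestCauchyStress:
    def test_stress_free_reference(self, params, frame, fixture_K):
        sigma = cauchy_stress(np.eye(3), fixture_K.K, params, frame)
        assert np.abs(sigma).max() < 1e-8

    def test_hydrostatic_expansion_isotropic_K_gives_pressure(self, params, frame):
        sigma = cauchy_stress(1.02 * np.eye(3), np.ones(16), params, frame)
        off = sigma - np.diag(np.diag(sigma))
        assert np.abs(off).max() < 1e-10 * abs(sigma[0, 0])
        assert abs(sigma[0, 0] - sigma[1, 1]) < 1e-8 * abs(sigma[0, 0])
        assert abs(sigma[0, 0] - sigma[2, 2]) < 1e-8 * abs(sigma[0, 0])

    def test_matches_finite_difference_of_energy(self, params, frame, fixture_K):
        rng = np.random.default_rng(7)
        for _ in range(10):
            F = random_tension_state(rng, frame)
            sigma = cauchy_stress(F, fixture_K.K, params, frame)
            h = 1e-6
            P = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    Fp, Fm = F.copy(), F.copy()
                    Fp[i, j] += h
                    Fm[i, j] -= h
                    P[i, j] = (
                        energy_total(kinematics(Fp, frame), fixture_K.K, params)
                        - energy_total(kinematics(Fm, frame), fixture_K.K, params)
                    ) / (2 * h)
            sig_fd = P @ F.T / np.linalg.det(F)
            sig_fd = 0.5 * (sig_fd + sig_fd.T)
            err = np.linalg.norm(sigma - sig_fd) / np.linalg.norm(sig_fd)
            assert err < 1e-6

    def test_consistent_tangent_matches_fd_of_stress(self, params, frame, fixture_K):
        rng = np.random.default_rng(9)
        F = random_tension_state(rng, frame)
        for inc_vol in (False, True):
            A = first_elasticity(F, fixture_K.K, params, frame, include_volumetric=inc_vol)
            h = 1e-6
            Afd = np.zeros((3, 3, 3, 3))
            for k in range(3):
                for l in range(3):
                    Fp, Fm = F.copy(), F.copy()
                    Fp[k, l] += h
                    Fm[k, l] -= h
                    Afd[:, :, k, l] = (
                        first_piola(Fp, fixture_K.K, params, frame, include_volumetric=inc_vol)
                        - first_piola(Fm, fixture_K.K, params, frame, include_volumetric=inc_vol)
                    ) / (2 * h)
            assert np.linalg.norm(A - Afd) / np.linalg.norm(Afd) < 1e-6


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(D=0.0), dict(C10=-1.0), dict(mu1=-0.1), dict(gamma1=0.0), dict(gamma2=-2.0)],
    )
    def test_invalid_constants_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MaterialParams(**kwargs)
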