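"""Constitutive laws: worked values, consistency, and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from afcomp.materials import (
    DeformationState, Environment, FiberReinforced, MaterialParams, Mixture,
    NeoHookeanMatrix, donnan_pressure, fiber_energy, fiber_stress_1d,
    fixed_charge_density, holmes_mow_energy, lame_constants,
    material_from_dict, material_to_dict, neo_hookean_energy, permeability,
    power_linear_B, preset,
)
from conftest import random_states


def numeric_cauchy(material, F, h=1e-6):
    """Independent oracle: sigma = (1/J) dW/dF F^T by central differences."""
    P = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            Fp = F.copy(); Fp[i, j] += h
            Fm = F.copy(); Fm[i, j] -= h
            Wp = material.energy(DeformationState.from_F(Fp))
            Wm = material.energy(DeformationState.from_F(Fm))
            P[i, j] = (Wp - Wm) / (2 * h)
    return P @ F.T / np.linalg.det(F)


def isotropic_tangent(E, nu):
    """Small-strain elasticity tensor C_ijkl of an isotropic solid."""
    lam, mu = lame_constants(E, nu)
    I = np.eye(3)
    C = np.zeros((3, 3, 3, 3))
    for i in range(3):
        for j in range(3):
            for k in range(3):
                for l in range(3):
                    C[i, j, k, l] = (lam * I[i, j] * I[k, l]
                                     + mu * (I[i, k] * I[j, l]
                                             + I[i, l] * I[j, k]))
    return C


def fd_hessian_energy(energy_fn, h=1e-4):
    """d2W/dF2 at the identity by central differences (as a 9x9)."""
    H = np.zeros((9, 9))
    for a in range(9):
        for b in range(9):
            def W(da, db):
                F = np.eye(3)
                F[a // 3, a % 3] += da
                F[b // 3, b % 3] += db
                return energy_fn(DeformationState.from_F(F))
            H[a, b] = (W(h, h) - W(h, -h) - W(-h, h) + W(-h, -h)) / (4 * h * h)
    return H


class TestEnergiesAtIdentity:
    def test_zero_energy_and_stress(self, matrix_params, bundle_params, env):
        st_ = DeformationState.from_F(np.eye(3))
        assert neo_hookean_energy(st_, matrix_params) == 0.0
        assert holmes_mow_energy(st_, bundle_params) == 0.0
        for mat in (NeoHookeanMatrix(matrix_params),
                    FiberReinforced(bundle_params)):
            assert np.allclose(mat.cauchy_stress(st_), 0.0, atol=1e-14)

    def test_invalid_deformation_rejected(self, matrix_params):
        with pytest.raises(ValueError):
            DeformationState.from_F(-np.eye(3))


class TestNeoHookean:
    def test_hand_evaluated_value(self, matrix_params):
        # W(diag(1.1,1.1,1.1)) evaluated term by term with Lame constants
        lam, mu = lame_constants(0.22, 0.3)
        F = np.diag([1.1, 1.1, 1.1])
        I1 = 3 * 1.1**2
        lnJ = np.log(1.1**3)
        expected = 0.5 * mu * (I1 - 3) - mu * lnJ + 0.5 * lam * lnJ**2
        got = neo_hookean_energy(DeformationState.from_F(F), matrix_params)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_small_strain_limit_matches_isotropic_elasticity(self, matrix_params):
        C = isotropic_tangent(matrix_params.E_matrix, matrix_params.nu_matrix)
        eps = 1e-4
        rng = np.random.default_rng(3)
        H = rng.standard_normal((3, 3))
        E = 0.5 * (H + H.T) * eps
        W_exact = 0.5 * np.einsum("ij,ijkl,kl->", E, C, E)
        F = np.eye(3) + eps * H
        W = neo_hookean_energy(DeformationState.from_F(F), matrix_params)
        # rotations contribute only at O(eps^3)
        assert W == pytest.approx(W_exact, rel=5e-3)


class TestHolmesMow:
    def test_c_coefficient_hand_value(self):
        p = preset("SEP-fiber-bundle", beta=1.0)
        from afcomp.materials import _hm_coeffs
        assert _hm_coeffs(p)[2] == pytest.approx(0.22 * 0.7 / (2 * 1 * 1.3 * 0.4),
                                                 rel=1e-12)

    def test_incompressible_parameters_rejected(self):
        with pytest.raises(ValueError):
            MaterialParams(nu_matrix=0.5)

    @pytest.mark.parametrize("beta", [0.5, 1.0, 3.3])
    def test_small_strain_tangent_independent_of_beta(self, beta):
        p = preset("SEP-fiber-bundle", beta=beta, fiber_active=False)
        H = fd_hessian_energy(lambda s: holmes_mow_energy(s, p))
        C = isotropic_tangent(p.E_matrix, p.nu_matrix)
        # D2W/DF2 at identity equals C_ijkl for any stiffening coefficient
        assert np.allclose(H, C.reshape(9, 9), atol=2e-4)


class TestFiber:
    def test_slack_in_compression(self, bundle_params):
        assert fiber_energy(0.95, bundle_params) == 0.0
        assert fiber_stress_1d(0.95, bundle_params) == 0.0

    def test_quadratic_coefficient_B_hand_value(self, bundle_params):
        B = power_linear_B(bundle_params)
        expected = (580 / 2) * ((1.07**2 - 1) / (2 * 4.95) + 1.07**2)
        assert B == pytest.approx(expected, rel=1e-12)
        assert B == pytest.approx(336.3, abs=0.05)

    def test_energy_continuous_at_transition_both_conventions(self, bundle_params):
        l0 = bundle_params.lambda0
        for conv in ("continuous", "literal"):
            below = fiber_energy(l0 - 1e-11, bundle_params, conv)
            above = fiber_energy(l0 + 1e-11, bundle_params, conv)
            # tolerance: steepest branch slope (~E_lin + 2 B lambda0) x step
            assert abs(above - below) < 3e3 * 2e-11 + 1e-12

    def test_stress_continuous_at_transition_default_convention(self, bundle_params):
        l0 = bundle_params.lambda0
        below = fiber_stress_1d(l0 - 1e-11, bundle_params)
        above = fiber_stress_1d(l0 + 1e-11, bundle_params)
        assert above == pytest.approx(below, rel=1e-8)
        # stress is also continuous (zero) at lambda = 1
        assert fiber_stress_1d(1.0 + 1e-9, bundle_params) == pytest.approx(
            0.0, abs=1e-6)

    def test_linear_branch_tangent_is_E_lin(self, bundle_params):
        lam = np.array([1.10, 1.15])
        t = fiber_stress_1d(lam, bundle_params)
        slope = (t[1] - t[0]) / 0.05
        assert slope == pytest.approx(bundle_params.E_lin, rel=1e-9)

    def test_gamma_at_most_one_rejected(self):
        with pytest.raises(ValueError):
            MaterialParams(gamma=1.0)

    @given(lam=st.floats(min_value=0.2, max_value=2.5))
    @settings(max_examples=60, deadline=None)
    def test_energy_nonnegative_and_monotone_regions(self, lam):
        p = preset("SEP-fiber-bundle")
        psi = fiber_energy(lam, p)
        assert psi >= 0.0
        if lam < 1.0:
            assert psi == 0.0


class TestStressEnergyConsistency:
    def test_analytic_stress_matches_numeric_gradient(self, rng, env):
        mats = [
            NeoHookeanMatrix(preset("SEP-matrix")),
            FiberReinforced(preset("SEP-fiber-bundle")),
            FiberReinforced(preset("HOM"), family_weights=(0.13, 0.13)),
            Mixture([(0.74, NeoHookeanMatrix(preset("SEP-matrix"))),
                     (0.26, FiberReinforced(preset("SEP-fiber-bundle")))]),
        ]
        states = random_states(rng, n=100)
        worst = 0.0
        for k, F in enumerate(states):
            m = mats[k % len(mats)]
            st_ = DeformationState.from_F(F)
            sig = m.cauchy_stress(st_)
            ref = numeric_cauchy(m, F)
            scale = max(np.abs(ref).max(), 1e-6)
            worst = max(worst, np.abs(sig - ref).max() / scale)
        assert worst < 1e-5

    def test_fiber_inactive_in_compression_along_fiber(self, bundle_params):
        m_with = FiberReinforced(bundle_params.with_fiber_dirs([(1, 0, 0)]))
        from dataclasses import replace
        m_without = FiberReinforced(
            replace(bundle_params, fiber_active=False).with_fiber_dirs([]))
        F = np.diag([0.93, 1.0, 1.0])
        st_ = DeformationState.from_F(F)
        assert np.allclose(m_with.cauchy_stress(st_),
                           m_without.cauchy_stress(st_))


class TestSwellingAndPermeability:
    def test_permeability_reference_value(self, matrix_params):
        assert permeability(1.0, matrix_params) == pytest.approx(0.0064,
                                                                 rel=1e-12)

    def test_permeability_hand_value(self):
        p = MaterialParams(k0=0.0064, phi0=0.3, alpha_perm=2.0, M_perm=4.8)
        k = permeability(1.2, p)
        assert k == pytest.approx(0.0064 * (0.9 / 0.7) ** 2 * np.exp(2.4 * 0.44),
                                  rel=1e-12)

    def test_permeability_vanishes_at_pore_closure(self, matrix_params):
        p = matrix_params
        assert permeability(p.phi0 + 1e-9, p) < 1e-12
        with pytest.raises(ValueError):
            permeability(p.phi0, p)

    def test_donnan_hand_value(self, env):
        p = preset("SEP-matrix")  # cF0 = -100 mmol/L
        pi = donnan_pressure(1.0, p, env)
        cF = -100.0
        expected = 0.927 * 8.314e-6 * 298.0 * (np.sqrt(cF**2 + 4 * 150**2)
                                               - 300.0)
        assert pi == pytest.approx(expected, rel=1e-12)
        assert pi == pytest.approx(0.0373, abs=5e-4)

    def test_uncharged_material_does_not_swell(self, env, bundle_params):
        assert donnan_pressure(1.1, bundle_params, env) == 0.0

    def test_donnan_strictly_decreasing_in_J(self, env):
        p = preset("SEP-matrix")
        Js = np.linspace(0.9, 1.5, 30)
        pis = donnan_pressure(Js, p, env)
        assert np.all(np.diff(pis) < 0)

    def test_fixed_charge_density_kinematics(self):
        p = preset("SEP-matrix")
        assert fixed_charge_density(1.0, p) == pytest.approx(-100.0)
        # swelling dilutes the charge
        assert abs(fixed_charge_density(1.3, p)) < 100.0
        from dataclasses import replace
        frozen = replace(p, cF_evolving=False)
        assert fixed_charge_density(1.3, frozen) == pytest.approx(-100.0)


class TestSerialization:
    @pytest.mark.parametrize("name", ["SEP-matrix", "SEP-fiber-bundle", "HOM"])
    def test_preset_round_trip(self, name):
        p = preset(name)
        q = material_from_dict(material_to_dict(p))
        assert p == q

    def test_presets_store_E_lin_in_MPa(self):
        assert preset("SEP-fiber-bundle").E_lin == 580.0
        assert preset("HOM").E_lin == 530.0

    def test_invalid_fiber_direction_rejected(self):
        with pytest.raises(ValueError):
            MaterialParams(fiber_dirs=((1.0, 1.0, 0.0),))
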