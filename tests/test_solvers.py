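"""Material-point, free-swelling, laminate, and voxel-FE solvers."""

import numpy as np
import pytest

from afcomp.materials import (DeformationState, Environment, FiberReinforced,
                              Mixture, NeoHookeanMatrix, preset)
from afcomp.microstructure import LamellaSpec, SpecimenSpec, build_voxel_model
from afcomp.protocols import ply_material
from afcomp.solvers import (BoundaryCondition, ControlSpec, LaminateControl,
                            fe_solve, free_swelling, laminate_solve,
                            material_point_solve, solve_affine_patch,
                            uniaxial_control)
from afcomp.solvers.fe import _FESystem


@pytest.fixture(scope="module")
def env():
    return Environment()


class TestMaterialPoint:
    def test_identity_control_needs_no_correction(self):
        mat = NeoHookeanMatrix(preset("SEP-matrix", cF0=0.0))
        kin = {(i, j): 1.0 if i == j else 0.0
               for i in range(3) for j in range(3)}
        path = material_point_solve(mat, ControlSpec(kinematic=kin, stress={}),
                                    increments=2)
        assert all(p.iterations == 0 for p in path)
        assert np.allclose(path[-1].state.F, np.eye(3))

    def test_uniaxial_poisson_ratio_recovered(self):
        mat = NeoHookeanMatrix(preset("SEP-matrix", cF0=0.0))
        path = material_point_solve(mat, uniaxial_control(1.0001),
                                    increments=1)
        F = path[-1].state.F
        nu_eff = (1.0 - F[1, 1]) / (F[0, 0] - 1.0)
        assert nu_eff == pytest.approx(0.3, abs=1e-4)
        assert abs(path[-1].stress[1, 1]) < 1e-8

    def test_control_validation(self):
        with pytest.raises(ValueError):
            ControlSpec(kinematic={}, stress={})
        with pytest.raises(ValueError):
            ControlSpec(kinematic={(0, 0): 1.0}, stress={(0, 0): 0.0})


class TestFreeSwelling:
    def test_uncharged_material_stays_put(self, env):
        mat = NeoHookeanMatrix(preset("SEP-matrix", cF0=0.0))
        lam_s, state = free_swelling(mat, env)
        assert lam_s == pytest.approx(1.0, abs=1e-10)

    def test_matrix_swells_stress_free(self, env):
        mat = NeoHookeanMatrix(preset("SEP-matrix"))
        lam_s, state = free_swelling(mat, env)
        assert lam_s > 1.0
        sig = mat.cauchy_stress(state, env=env, swelling=True)
        assert np.abs(sig).max() < 1e-8

    def test_swelling_monotone_in_charge(self, env):
        lams = []
        for cf in (0.0, -50.0, -100.0):
            mat = NeoHookeanMatrix(preset("SEP-matrix", cF0=cf))
            lams.append(free_swelling(mat, env)[0])
        assert lams[0] < lams[1] < lams[2]


class TestLaminate:
    def _sep_plies(self, n, env=None):
        spec = SpecimenSpec(n_lamellae=n)
        lam = LamellaSpec()
        from afcomp.microstructure import build_ply_stack
        stack = build_ply_stack(spec, lam)
        return [(p.thickness, ply_material(p.fiber_dirs, lam, "SEP"))
                for p in stack.plies]

    def test_single_ply_reduces_to_material_point(self, env):
        plies = self._sep_plies(1)
        ctrl = LaminateControl(kinematic={(0, 0): 0.05, (0, 1): 0.0,
                                          (1, 0): 0.0},
                               stress={(1, 1): 0.0})
        res = laminate_solve(plies, ctrl, increments=5, env=env,
                             swelling=False)
        # material-point oracle: same mixture, uniaxial-like mixed control
        mat = plies[0][1]
        kin = {(0, 0): 1.05, (1, 0): 0.0, (0, 1): 0.0, (2, 0): 0.0,
               (2, 1): 0.0}
        st = {(1, 1): 0.0, (2, 2): 0.0, (0, 2): 0.0, (1, 2): 0.0}
        path = material_point_solve(mat, ControlSpec(kinematic=kin, stress=st),
                                    increments=5, env=env, swelling=False)
        P_lam = res.nominal[-1, 0]
        F = path[-1].state.F
        P_mp = (np.linalg.det(F) * path[-1].stress @ np.linalg.inv(F).T)[0, 0]
        assert P_lam == pytest.approx(P_mp, rel=1e-6)

    def test_balanced_stack_has_no_net_inplane_shear(self, env):
        plies = self._sep_plies(2)
        ctrl = LaminateControl(kinematic={(0, 0): 0.08, (0, 1): 0.0,
                                          (1, 0): 0.0},
                               stress={(1, 1): 0.0})
        res = laminate_solve(plies, ctrl, increments=4, env=env,
                             swelling=False)
        assert abs(res.bulk_stress[-1][0, 1]) < 1e-8

    def test_equibiaxial_symmetric_response(self, env):
        plies = self._sep_plies(2)
        ctrl = LaminateControl(kinematic={(0, 0): 0.06, (1, 1): 0.06,
                                          (0, 1): 0.0, (1, 0): 0.0},
                               stress={})
        res = laminate_solve(plies, ctrl, increments=4, env=env, swelling=True)
        # circumferential direction is stiffer than axial for +-30 plies
        assert res.nominal[-1, 0] > res.nominal[-1, 1] > 0


class TestVoxelFE:
    def test_patch_test_matches_affine_deformation(self):
        lam = LamellaSpec(matrix=preset("SEP-matrix", cF0=0.0),
                          bundle_radius=0.0)
        vm = build_voxel_model(SpecimenSpec(length=0.6, width=0.4,
                                            n_lamellae=2), lam, 0.2)
        F = np.array([[1.08, 0.02, 0.0], [0.01, 0.96, 0.03],
                      [0.0, 0.0, 1.02]])
        sys_, u = solve_affine_patch(vm, F)
        ue = u.reshape(-1, 3)[sys_.mesh.conn]
        Fgp = np.eye(3) + np.einsum("eai,paj->epij", ue, sys_.mesh.dN)
        assert np.abs(Fgp - F).max() < 1e-10

    def test_kernel_matches_reference_implementation(self):
        rng = np.random.default_rng(7)
        for fam in ("SEP", "HOM"):
            vm = build_voxel_model(
                SpecimenSpec(length=1.0, width=0.6, n_lamellae=2,
                             model_family=fam), LamellaSpec(), 0.1)
            fast = _FESystem(vm)
            ref = _FESystem(vm)
            ref._kernel_args = None
            u = 0.004 * rng.standard_normal(fast.ndof)
            fk = fast.residual(u, 0.8)
            fn = ref.residual(u, 0.8)
            scale = max(np.abs(fn).max(), 1e-12)
            assert np.abs(fk - fn).max() / scale < 1e-10

    def test_single_element_uniaxial_matches_closed_form(self):
        lam = LamellaSpec(matrix=preset("SEP-matrix", cF0=0.0),
                          bundle_radius=0.0)
        vm = build_voxel_model(SpecimenSpec(length=0.2, width=0.2,
                                            n_lamellae=1), lam, 0.2)
        res = fe_solve(vm, BoundaryCondition("gripped", clamp="guided"),
                       strain=0.10, increments=5, swelling=False)
        # closed-form uniaxial neo-Hookean nominal stress at 10% stretch
        mat = NeoHookeanMatrix(preset("SEP-matrix", cF0=0.0))
        path = material_point_solve(mat, uniaxial_control(1.10), increments=5)
        F = path[-1].state.F
        P = (np.linalg.det(F) * path[-1].stress @ np.linalg.inv(F).T)[0, 0]
        assert res.nominal_stress[-1] == pytest.approx(P, rel=1e-6)

    def test_fe_patch_equals_material_point_under_homogeneous_bc(self):
        """Grip-free affine boundary: every element carries the same stress."""
        lam = LamellaSpec(matrix=preset("SEP-matrix", cF0=0.0),
                          bundle_radius=0.0)
        vm = build_voxel_model(SpecimenSpec(length=0.8, width=0.6,
                                            n_lamellae=3), lam, 0.2)
        F = np.diag([1.07, 0.97, 0.99])
        sys_, u = solve_affine_patch(vm, F)
        ue = u.reshape(-1, 3)[sys_.mesh.conn]
        Fgp = np.eye(3) + np.einsum("eai,paj->epij", ue, sys_.mesh.dN)
        sig = sys_.field.cauchy(Fgp, swell=0.0)
        mat = NeoHookeanMatrix(preset("SEP-matrix", cF0=0.0))
        ref = mat.cauchy_stress(DeformationState.from_F(F))
        assert np.abs(sig - ref).max() / np.abs(ref).max() < 1e-4

    def test_energy_consistency_reaction_work_vs_stored_energy(self):
        lam = LamellaSpec(matrix=preset("SEP-matrix", cF0=0.0))
        vm = build_voxel_model(SpecimenSpec(length=1.6, width=0.8,
                                            n_lamellae=2), lam, 0.2)
        res = fe_solve(vm, BoundaryCondition("gripped"), strain=0.06,
                       increments=12, swelling=False)
        sys_ = _FESystem(vm)
        W_end = sys_.total_energy(res.u)
        # reaction work along the grip displacement path (trapezoid)
        disp = res.strain * res.swollen_length
        work = np.trapezoid(res.reaction, disp)
        assert work == pytest.approx(W_end, rel=0.01)

    def test_gripped_stiffer_than_guided(self):
        vm = build_voxel_model(SpecimenSpec(length=2.0, width=1.0,
                                            n_lamellae=2), LamellaSpec(), 0.2)
        full = fe_solve(vm, BoundaryCondition("gripped", "full"),
                        strain=0.08, increments=8)
        guided = fe_solve(vm, BoundaryCondition("gripped", "guided"),
                          strain=0.08, increments=8)
        assert full.nominal_stress[-1] >= guided.nominal_stress[-1]

    def test_invalid_bc_rejected(self):
        with pytest.raises(ValueError):
            BoundaryCondition("clamped")
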