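"""Homogeneous-deformation equilibrium under mixed stretch/stress control.

A material point is driven through a strain program in which every component
of the deformation gradient is either prescribed kinematically or adjusted so
that the corresponding Cauchy-stress component reaches a prescribed value
(usually zero, e.g. the lateral faces of a uniaxial test).  The free-swelling
pre-step solves for the stress-free swollen configuration under Donnan
pressure; the mechanical program is then measured from that state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..materials import DeformationState, Environment, Material
from ._newton import NonConvergenceError, newton_solve

__all__ = ["ControlSpec", "PathPoint", "material_point_solve", "free_swelling",
           "free_swelling_state", "uniaxial_control", "NonConvergenceError"]

_IDX = [(i, j) for i in range(3) for j in range(3)]


@dataclass(frozen=True)
class ControlSpec:
    """Mixed control: each F component is stretch- or stress-prescribed.

    ``kinematic`` maps (i, j) to the final value of F_ij (ramped linearly
    from the identity); ``stress`` maps (i, j) to the target Cauchy stress
    sigma_ij (held fixed along the path).  Every one of the nine components
    must be assigned exactly once, and at least one kinematic component is
    required to pin the deformation.
    """

    kinematic: dict = field(default_factory=dict)
    stress: dict = field(default_factory=dict)

    def __post_init__(self):
        keys = set(self.kinematic) | set(self.stress)
        if set(self.kinematic) & set(self.stress):
            raise ValueError("a component cannot be both stretch- and stress-controlled")
        if keys != set(_IDX):
            raise ValueError("all 9 F components must be assigned a control")
        if not self.kinematic:
            raise ValueError("at least one kinematic component is required")


def uniaxial_control(stretch: float, axis: int = 0,
                     shear_free: bool = False) -> ControlSpec:
    """Uniaxial stress control: prescribed stretch on ``axis``, other normal
    stresses zero.

    With ``shear_free`` the upper-triangular F components relax the shear
    stresses (the lower triangle is pinned to remove the duplicate rows a
    symmetric stress tensor would create); otherwise all shears are
    kinematically zero.
    """
    kin = {(axis, axis): stretch}
    st = {}
    for i, j in _IDX:
        if (i, j) == (axis, axis):
            continue
        if i == j:
            st[(i, j)] = 0.0
        elif shear_free and i < j:
            st[(i, j)] = 0.0
        else:
            kin[(i, j)] = 0.0
    return ControlSpec(kinematic=kin, stress=st)


@dataclass
class PathPoint:
    t: float
    state: DeformationState
    stress: np.ndarray
    iterations: int


def _solve_increment(material, F_kin, stress_slots, stress_targets, x0,
                     env, swelling, tol):
    slots = list(stress_slots)

    def residual(x):
        F = F_kin.copy()
        for k, (i, j) in enumerate(slots):
            F[i, j] = x[k]
        state = DeformationState.from_F(F)
        sig = material.cauchy_stress(state, env=env, swelling=swelling)
        return np.array([sig[i, j] - stress_targets[k]
                         for k, (i, j) in enumerate(slots)])

    x, it = newton_solve(residual, x0, tol=tol)
    F = F_kin.copy()
    for k, (i, j) in enumerate(slots):
        F[i, j] = x[k]
    state = DeformationState.from_F(F)
    sig = material.cauchy_stress(state, env=env, swelling=swelling)
    return state, sig, it, x


def material_point_solve(material: Material, control: ControlSpec,
                         increments: int = 20, env: Environment | None = None,
                         swelling: bool = False, F_start: np.ndarray | None = None,
                         tol: float = 1e-8):
    """Drive a material point along the control path; returns list[PathPoint].

    ``F_start`` (default identity) is the configuration the kinematic ramp
    starts from, e.g. a swollen state; the prescribed-stress residual is
    reduced below ``tol`` (MPa) at every increment.
    """
    F0 = np.eye(3) if F_start is None else np.asarray(F_start, dtype=float)
    slots = sorted(control.stress)
    targets = [control.stress[ij] for ij in slots]
    x = np.array([F0[i, j] for i, j in slots], dtype=float)
    path = []
    for n in range(increments + 1):
        t = n / increments if increments > 0 else 1.0
        F_kin = F0.copy()
        for (i, j), val in control.kinematic.items():
            base = F0[i, j]
            F_kin[i, j] = base + t * (val - base)
        try:
            state, sig, it, x = _solve_increment(
                material, F_kin, slots, targets, x, env, swelling, tol)
        except NonConvergenceError as exc:
            raise NonConvergenceError(
                f"increment {n}/{increments} failed: {exc}",
                residual_norm=exc.residual_norm, last_x=exc.last_x) from exc
        path.append(PathPoint(t=t, state=state, stress=sig, iterations=it))
    return path


def free_swelling_state(material: Material, env: Environment,
                        tol: float = 1e-8) -> DeformationState:
    """Stress-free swollen configuration: solve sigma(F) = 0 with symmetric F.

    The osmotic (Donnan) pressure is ramped in a few sub-steps for
    robustness.  Returns the swollen DeformationState (F = I when the
    material carries no fixed charge).
    """
    sym = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]

    def make_F(x):
        F = np.zeros((3, 3))
        for k, (i, j) in enumerate(sym):
            F[i, j] = x[k]
            F[j, i] = x[k]
        return F

    x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
    for ramp in (0.25, 0.5, 0.75, 1.0):
        env_r = Environment(c_ext=env.c_ext, T=env.T * 1.0, R=env.R * ramp)

        def residual(x):
            state = DeformationState.from_F(make_F(x))
            sig = material.cauchy_stress(state, env=env_r, swelling=True)
            return np.array([sig[i, j] for i, j in sym])

        x, _ = newton_solve(residual, x, tol=tol)
    return DeformationState.from_F(make_F(x))


def free_swelling(material: Material, env: Environment, tol: float = 1e-8):
    """Free-swelling stretch of a material in the bath.

    Returns ``(lambda_s, state)`` where ``lambda_s`` is the mean principal
    stretch of the stress-free swollen configuration (exactly the isotropic
    swelling stretch for isotropic constituents) and ``state`` the swollen
    reference from which subsequent engineering strain is measured.
    """
    state = free_swelling_state(material, env, tol=tol)
    lam_s = float(np.cbrt(state.J))
    return lam_s, state
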