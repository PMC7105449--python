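"""Finite-strain angle-ply laminate solver.

The multi-lamellar specimen is treated as a stack of plies that share the
in-plane deformation (grip-to-grip kinematic compatibility) while each ply
relaxes its own through-thickness column of the deformation gradient so that
the out-of-plane Cauchy-stress components vanish (thin free-standing
laminate).  The bulk in-plane stress is the thickness-weighted ply average.

A free-swelling pre-step (all stress targets zero, swelling on) produces the
swollen reference; the mechanical program prescribes in-plane engineering
strain from that reference and reports nominal stress per loading direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..materials import DeformationState, Environment, Material
from ._newton import NonConvergenceError, newton_solve

__all__ = ["LaminateControl", "LaminateResult", "laminate_solve",
           "uniaxial_stack_control"]

_INPLANE = [(0, 0), (1, 1), (0, 1), (1, 0)]
_OOP = [(0, 2), (1, 2), (2, 2)]


@dataclass(frozen=True)
class LaminateControl:
    """In-plane mixed control for the stack.

    ``kinematic``: final engineering strain for prescribed in-plane
    components of the shared deformation gradient, keyed by (i, j) with
    i, j in {0, 1} (values are stretches for the diagonal, shears
    otherwise, measured from the swollen reference).
    ``stress``: target thickness-averaged Cauchy stress for the remaining
    in-plane components.
    """

    kinematic: dict
    stress: dict

    def __post_init__(self):
        keys = set(self.kinematic) | set(self.stress)
        if keys != set(_INPLANE) or set(self.kinematic) & set(self.stress):
            raise ValueError("in-plane components (0,0),(1,1),(0,1),(1,0) must "
                             "each have exactly one control")


def uniaxial_stack_control(strain: float, axis: int = 0,
                           lateral_free: bool = True,
                           shear_free: bool = False) -> LaminateControl:
    """Uniaxial in-plane program: engineering strain on ``axis`` (0=x, 1=y)."""
    # kinematic diagonal entries are engineering strains from the swollen state
    kin, st = {}, {}
    for ij in _INPLANE:
        if ij == (axis, axis):
            kin[ij] = strain
        elif ij in ((0, 0), (1, 1)):
            (st if lateral_free else kin)[ij] = 0.0
        else:
            (st if shear_free else kin)[ij] = 0.0
    return LaminateControl(kinematic=kin, stress=st)


@dataclass
class LaminateResult:
    t: np.ndarray                # load factors
    F_bar: list                  # shared in-plane F (3x3, oop columns zeroed)
    ply_states: list             # per increment: list of DeformationState
    bulk_stress: np.ndarray      # (n_inc, 3, 3) thickness-avg Cauchy
    nominal: np.ndarray          # (n_inc, 2) nominal stress (x, y) from swollen ref
    strain: np.ndarray           # (n_inc, 2) engineering strain (x, y)
    swollen_F: list              # per-ply swollen F


def _ply_F(Fbar_entries, oop):
    F = np.array([[Fbar_entries[0], Fbar_entries[2], oop[0]],
                  [Fbar_entries[3], Fbar_entries[1], oop[1]],
                  [0.0, 0.0, oop[2]]])
    return F


def _assemble_residual(x, mats, weights, inplane_vals, stress_slots,
                       stress_targets, env, swelling):
    """x = [per-ply (F13,F23,F33)..., in-plane unknowns]."""
    n = len(mats)
    oop = x[: 3 * n].reshape(n, 3)
    free = x[3 * n:]
    vals = dict(inplane_vals)
    for k, ij in enumerate(stress_slots):
        vals[ij] = free[k]
    entries = [vals[(0, 0)], vals[(1, 1)], vals[(0, 1)], vals[(1, 0)]]
    res_oop = np.empty((n, 3))
    bulk = np.zeros((3, 3))
    sigs = []
    states = []
    for p, m in enumerate(mats):
        F = _ply_F(entries, oop[p])
        state = DeformationState.from_F(F)
        sig = m.cauchy_stress(state, env=env, swelling=swelling)
        res_oop[p] = [sig[0, 2], sig[1, 2], sig[2, 2]]
        bulk += weights[p] * sig
        sigs.append(sig)
        states.append(state)
    res_bulk = np.array([bulk[ij] - stress_targets[k]
                         for k, ij in enumerate(stress_slots)])
    return np.concatenate([res_oop.ravel(), res_bulk]), states, bulk


def laminate_solve(plies, loading: LaminateControl, increments: int = 20,
                   env: Environment | None = None, swelling: bool = True,
                   tol: float = 1e-8) -> LaminateResult:
    """Equilibrium of a ply stack under mixed in-plane control.

    ``plies`` is a sequence of (thickness, Material).  With ``swelling``
    enabled the stack is first brought to its stress-free swollen state
    (all in-plane bulk stresses and ply out-of-plane stresses zero) and the
    kinematic program is applied relative to it.
    """
    mats = [m for _, m in plies]
    th = np.array([t for t, _ in plies], dtype=float)
    weights = th / th.sum()
    n = len(mats)
    if env is None:
        env = Environment()

    def solve(x0, inplane_vals, stress_slots, stress_targets, swell):
        def fun(x):
            r, _, _ = _assemble_residual(x, mats, weights, inplane_vals,
                                         stress_slots, stress_targets, env, swell)
            return r
        x, it = newton_solve(fun, x0, tol=tol)
        r, states, bulk = _assemble_residual(x, mats, weights, inplane_vals,
                                             stress_slots, stress_targets,
                                             env, swell)
        return x, states, bulk, it

    # --- swelling pre-step: everything stress-free -------------------------
    x = np.concatenate([np.tile([0.0, 0.0, 1.0], n), []])
    if swelling:
        slots = [(0, 0), (1, 1), (0, 1)]
        x = np.concatenate([np.tile([0.0, 0.0, 1.0], n), [1.0, 1.0, 0.0]])
        x, states, _, _ = solve(x, {(1, 0): 0.0}, slots, [0.0, 0.0, 0.0], True)
        lam_x, lam_y, shear = x[3 * n], x[3 * n + 1], x[3 * n + 2]
        swollen_entries = {(0, 0): lam_x, (1, 1): lam_y, (0, 1): shear, (1, 0): 0.0}
        swollen_oop = x[: 3 * n].copy()
        swollen_F = [s.F.copy() for s in states]
    else:
        swollen_entries = {(0, 0): 1.0, (1, 1): 1.0, (0, 1): 0.0, (1, 0): 0.0}
        swollen_oop = np.tile([0.0, 0.0, 1.0], n)
        swollen_F = [np.eye(3) for _ in range(n)]

    lam_sx = swollen_entries[(0, 0)]
    lam_sy = swollen_entries[(1, 1)]

    # --- mechanical program ------------------------------------------------
    stress_slots = sorted(loading.stress)
    stress_targets = [loading.stress[ij] for ij in stress_slots]
    x = np.concatenate([swollen_oop,
                        [swollen_entries[ij] for ij in stress_slots]])

    ts, Fbars, all_states, bulks, noms, strains = [], [], [], [], [], []
    for inc in range(increments + 1):
        t = inc / increments if increments else 1.0
        inplane_vals = {}
        for ij, target in loading.kinematic.items():
            base = swollen_entries[ij]
            if ij in ((0, 0), (1, 1)):
                # target is engineering strain from the swollen state
                inplane_vals[ij] = base * (1.0 + t * target)
            else:
                inplane_vals[ij] = base + t * target
        try:
            x, states, bulk, _ = solve(x, inplane_vals, stress_slots,
                                       stress_targets, swelling)
        except NonConvergenceError as exc:
            raise NonConvergenceError(
                f"laminate increment {inc}/{increments} failed: {exc}",
                residual_norm=exc.residual_norm) from exc
        vals = dict(inplane_vals)
        for k, ij in enumerate(stress_slots):
            vals[ij] = x[3 * n + k]
        # nominal stress from the swollen reference, per loading direction
        eps_x = vals[(0, 0)] / lam_sx - 1.0
        eps_y = vals[(1, 1)] / lam_sy - 1.0
        nom = np.zeros(2)
        for p, s in enumerate(states):
            F_rel = s.F @ np.linalg.inv(swollen_F[p])
            Jr = np.linalg.det(F_rel)
            sig = mats[p].cauchy_stress(s, env=env, swelling=swelling)
            P = Jr * sig @ np.linalg.inv(F_rel).T
            nom += weights[p] * np.array([P[0, 0], P[1, 1]])
        ts.append(t)
        Fbars.append(_ply_F([vals[(0, 0)], vals[(1, 1)], vals[(0, 1)],
                             vals[(1, 0)]], [0, 0, 1]))
        all_states.append(states)
        bulks.append(bulk)
        noms.append(nom)
        strains.append([eps_x, eps_y])
    return LaminateResult(t=np.array(ts), F_bar=Fbars, ply_states=all_states,
                          bulk_stress=np.array(bulks), nominal=np.array(noms),
                          strain=np.array(strains), swollen_F=swollen_F)
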