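"""Virtual mechanical experiments, modulus extraction, and calibration.

The testing protocols mirror standard annulus fibrosus tissue testing:
free swelling in 0.15 M saline, then uniaxial tension (20% engineering
strain), biaxial tension (strain ratios 1:1 or 1:0, stopped at 15%), or
simple shear (10%).  Moduli are slopes of the nominal stress--strain curve:
a toe modulus over the initial region, a linear-region modulus over the
terminal region, and low/medium/high-stress tangent moduli at fixed
fractions of the peak stress (used by the sub-tissue calibration loop).

Calibration follows the multiscale framework: parameters are fit on
single-lamella uniaxial data (along-fiber and transverse protocols are
available) until the simulated region moduli are within 10% of the
experimental targets; validation then happens at the multi-lamellar scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .materials import (Environment, FiberReinforced, Mixture,
                        MaterialParams, NeoHookeanMatrix, preset)
from .microstructure import (LamellaSpec, SpecimenSpec, build_ply_stack,
                             build_voxel_model, fiber_volume_fraction)
from .solvers.fe import BoundaryCondition, fe_solve
from .solvers.laminate import LaminateControl, laminate_solve
from .solvers.material_point import (ControlSpec, free_swelling_state,
                                     material_point_solve)
from .materials import DeformationState

__all__ = [
    "LoadCase", "ModulusReport", "CalibrationTarget", "CalibrationResult",
    "run_experiment", "extract_moduli", "calibrate", "ply_material",
    "single_lamella_model", "single_lamella_region_moduli",
    "DEFAULT_STRAIN_TARGETS",
]

DEFAULT_STRAIN_TARGETS = {"uniaxial": 0.20, "biaxial": 0.15, "shear": 0.10}


@dataclass(frozen=True)
class LoadCase:
    """Loading modality + boundary condition + strain program."""

    modality: str = "uniaxial"
    direction: str = "circumferential"
    strain_target: float | None = None
    biaxial_ratio: str = "1:1"
    bc: BoundaryCondition = field(default_factory=BoundaryCondition)

    def __post_init__(self):
        if self.modality not in DEFAULT_STRAIN_TARGETS:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.direction not in ("circumferential", "axial"):
            raise ValueError("direction must be 'circumferential' or 'axial'")
        if self.biaxial_ratio not in ("1:1", "1:0"):
            raise ValueError("biaxial_ratio must be '1:1' or '1:0'")
        if self.strain_target is not None and self.strain_target < 0:
            raise ValueError("strain target must be non-negative")

    @property
    def strain(self) -> float:
        if self.strain_target is None:
            return DEFAULT_STRAIN_TARGETS[self.modality]
        return self.strain_target


@dataclass
class ModulusReport:
    """Slopes extracted from one stress--strain curve (MPa).

    ``linearity`` is NL (nonlinear) when the linear-region slope exceeds
    ``nl_threshold`` times the toe slope, else PL (pseudo-linear).
    """

    toe_modulus: float
    linear_modulus: float
    E_low: float
    E_med: float
    E_high: float
    linearity: str
    toe_bounds: tuple
    linear_bounds: tuple
    stress_fractions: tuple = (0.1, 0.5, 0.9)

    @property
    def apparent_modulus(self) -> float:
        return self.linear_modulus

    @property
    def shear_modulus(self) -> float:
        return self.linear_modulus

    def to_dict(self) -> dict:
        return {
            "toe_modulus": self.toe_modulus,
            "linear_modulus": self.linear_modulus,
            "E_low": self.E_low, "E_med": self.E_med, "E_high": self.E_high,
            "linearity": self.linearity,
            "toe_bounds": list(self.toe_bounds),
            "linear_bounds": list(self.linear_bounds),
        }


def _ls_slope(x, y):
    A = np.vstack([x, np.ones_like(x)]).T
    m, _ = np.linalg.lstsq(A, y, rcond=None)[0]
    return float(m)


def extract_moduli(strain, stress, toe_fraction: float = 0.10,
                   linear_fraction: float = 0.25,
                   stress_fractions=(0.1, 0.5, 0.9),
                   nl_threshold: float = 3.0) -> ModulusReport:
    """Extract toe/linear/region moduli from a monotone stress--strain curve.

    Toe modulus: least-squares slope over the first ``toe_fraction`` of the
    strain range; linear modulus: slope over the last ``linear_fraction``;
    E_low/E_med/E_high: tangent slopes where the stress reaches the given
    fractions of the peak stress.
    """
    strain = np.asarray(strain, dtype=float)
    stress = np.asarray(stress, dtype=float)
    if strain.ndim != 1 or strain.size != stress.size:
        raise ValueError("strain and stress must be equal-length 1-D arrays")
    if np.any(np.diff(strain) <= 0):
        raise ValueError("strain grid must be strictly increasing")
    rng = strain[-1] - strain[0]
    toe_hi = strain[0] + toe_fraction * rng
    lin_lo = strain[-1] - linear_fraction * rng
    toe_mask = strain <= toe_hi + 1e-12
    lin_mask = strain >= lin_lo - 1e-12
    if toe_mask.sum() < 3 or lin_mask.sum() < 3:
        raise ValueError("fewer than 3 points in a modulus region; "
                         "increase the number of increments")
    toe = _ls_slope(strain[toe_mask], stress[toe_mask])
    lin = _ls_slope(strain[lin_mask], stress[lin_mask])
    tangent = np.gradient(stress, strain)
    peak = stress.max()
    regions = []
    for frac in stress_fractions:
        target = frac * peak
        k = int(np.searchsorted(stress, target))
        k = min(max(k, 1), strain.size - 1)
        # interpolate the tangent between bracketing points
        s0, s1 = stress[k - 1], stress[k]
        w = 0.0 if s1 == s0 else (target - s0) / (s1 - s0)
        regions.append(float((1 - w) * tangent[k - 1] + w * tangent[k]))
    label = "NL" if lin > nl_threshold * max(toe, 1e-12) else "PL"
    return ModulusReport(toe_modulus=toe, linear_modulus=lin,
                         E_low=regions[0], E_med=regions[1], E_high=regions[2],
                         linearity=label,
                         toe_bounds=(float(strain[0]), float(toe_hi)),
                         linear_bounds=(float(lin_lo), float(strain[-1])),
                         stress_fractions=tuple(stress_fractions))


# ---------------------------------------------------------------------------
# materials for plies and single lamellae
# ---------------------------------------------------------------------------


def ply_material(fiber_dirs, lamella: LamellaSpec, model_family: str,
                 convention: str = "continuous"):
    """Constitutive description of one lamella at a material point.

    SEP: volume-weighted mixture of neo-Hookean matrix and the fiber-bundle
    constituent (Holmes--Mow ground + one family).  HOM: Holmes--Mow ground
    with the fiber families down-weighted by the bundle volume fraction.
    """
    vf = fiber_volume_fraction(lamella)
    if model_family == "SEP":
        bundle = lamella.bundle.with_fiber_dirs(fiber_dirs)
        return Mixture([
            (1.0 - vf, NeoHookeanMatrix(lamella.matrix)),
            (vf, FiberReinforced(bundle, convention=convention)),
        ])
    hom = lamella.bundle.with_fiber_dirs(fiber_dirs)
    n = len(fiber_dirs)
    return FiberReinforced(hom, family_weights=(vf / n,) * n,
                           convention=convention)


def single_lamella_model(params_matrix: MaterialParams | None = None,
                         params_bundle: MaterialParams | None = None,
                         model_family: str = "SEP",
                         direction: str = "fiber",
                         lamella: LamellaSpec | None = None):
    """Material-point description of a single lamella loaded along x.

    ``direction='fiber'`` aligns the fiber family with the loading axis;
    ``'transverse'`` puts it perpendicular (in-plane).
    """
    if lamella is None:
        lamella = LamellaSpec()
    if params_matrix is not None or params_bundle is not None:
        lamella = replace(lamella,
                          matrix=params_matrix or lamella.matrix,
                          bundle=params_bundle or lamella.bundle)
    a0 = (1.0, 0.0, 0.0) if direction == "fiber" else (0.0, 1.0, 0.0)
    return ply_material((a0,), lamella, model_family)


def _nominal_from_path(path, F_ref):
    """Engineering strain (x) and nominal stress (x, y) measured from F_ref."""
    Fr_inv = np.linalg.inv(F_ref)
    out = []
    for pt in path:
        F_rel = pt.state.F @ Fr_inv
        Jr = np.linalg.det(F_rel)
        P = Jr * pt.stress @ np.linalg.inv(F_rel).T
        out.append((F_rel[0, 0] - 1.0, F_rel[1, 1] - 1.0, P[0, 0], P[1, 1],
                    P[0, 2]))
    return np.array(out)


def single_lamella_region_moduli(material, strain: float = 0.05,
                                 increments: int = 20,
                                 env: Environment | None = None,
                                 swelling: bool = False,
                                 stress_fractions=(0.1, 0.5, 0.9)):
    """Uniaxial region moduli (E_low, E_med, E_high) of a single lamella.

    The sub-tissue calibration protocol loads the lamella along x to
    ``strain`` engineering strain (default 5%, the sub-failure range of
    single-lamella tests; the toe--linear transition is traversed inside
    it).  The two-step swelling-then-load protocol belongs to the
    multi-lamellar validation experiments; calibration defaults to the
    unswollen state.
    """
    env = env or Environment()
    if swelling:
        F_s = free_swelling_state(material, env).F
    else:
        F_s = np.eye(3)
    kin = {(0, 0): F_s[0, 0] * (1.0 + strain)}
    st = {}
    for i in range(3):
        for j in range(3):
            if (i, j) == (0, 0):
                continue
            if i == j:
                st[(i, j)] = 0.0
            else:
                kin[(i, j)] = F_s[i, j]
    control = ControlSpec(kinematic=kin, stress=st)
    path = material_point_solve(material, control, increments=increments,
                                env=env, swelling=swelling, F_start=F_s)
    data = _nominal_from_path(path, F_s)
    rep = extract_moduli(data[:, 0], data[:, 2],
                         stress_fractions=stress_fractions)
    return rep


# ---------------------------------------------------------------------------
# run_experiment
# ---------------------------------------------------------------------------


def _laminate_curves(spec, lamella, loadcase, increments, env, swelling,
                     convention):
    stack = build_ply_stack(spec, lamella)
    plies = [(p.thickness,
              ply_material(p.fiber_dirs, lamella, spec.model_family,
                           convention))
             for p in stack.plies]
    if loadcase.modality == "uniaxial":
        kin = {(0, 0): loadcase.strain, (0, 1): 0.0, (1, 0): 0.0}
        st = {(1, 1): 0.0}
    elif loadcase.modality == "biaxial":
        ey = loadcase.strain if loadcase.biaxial_ratio == "1:1" else 0.0
        kin = {(0, 0): loadcase.strain, (1, 1): ey, (0, 1): 0.0, (1, 0): 0.0}
        st = {}
    else:
        raise ValueError("laminate path supports uniaxial and biaxial")
    res = laminate_solve(plies, LaminateControl(kinematic=kin, stress=st),
                         increments=increments, env=env, swelling=swelling)
    df = pd.DataFrame({
        "strain_x": res.strain[:, 0], "strain_y": res.strain[:, 1],
        "stress_x": res.nominal[:, 0], "stress_y": res.nominal[:, 1],
    })
    return df


def _shear_curve(spec, lamella, loadcase, increments, env, swelling,
                 convention):
    """Simple shear of the plate-clamped stack, iso-strain across plies.

    The top plate translates along x with the gradient through the
    thickness (z); each ply sees F = (I + gamma e_x (x) e_z) F_swollen.
    """
    stack = build_ply_stack(spec, lamella)
    mats = [ply_material(p.fiber_dirs, lamella, spec.model_family, convention)
            for p in stack.plies]
    th = np.array([p.thickness for p in stack.plies])
    wts = th / th.sum()
    env = env or Environment()
    rows = []
    F_sw = []
    for m in mats:
        F_sw.append(free_swelling_state(m, env).F if swelling else np.eye(3))
    for g in np.linspace(0.0, loadcase.strain, increments + 1):
        shear = np.eye(3)
        shear[0, 2] = g
        tau = 0.0
        for m, Fs, w in zip(mats, F_sw, wts):
            F = shear @ Fs
            state = DeformationState.from_F(F)
            sig = m.cauchy_stress(state, env=env, swelling=swelling)
            F_rel = shear
            P = np.linalg.det(F_rel) * sig @ np.linalg.inv(F_rel).T
            tau += w * P[0, 2]
        rows.append((g, tau))
    arr = np.array(rows)
    return pd.DataFrame({"strain_x": arr[:, 0], "stress_x": arr[:, 1]})


def run_experiment(spec: SpecimenSpec, lamella: LamellaSpec,
                   loadcase: LoadCase, solver_path: str = "laminate",
                   resolution: float = 0.2, increments: int = 20,
                   env: Environment | None = None, swelling: bool = True,
                   convention: str = "continuous"):
    """Run a virtual experiment; returns a stress--strain DataFrame.

    Columns: ``strain_x``/``stress_x`` (loading direction; nominal stress in
    MPa measured from the post-swelling state) and ``strain_y``/``stress_y``
    for biaxial runs.  ``solver_path`` selects the angle-ply laminate
    ('laminate') or the voxel finite element model ('fe').
    """
    env = env or Environment()
    if loadcase.strain == 0.0:
        return pd.DataFrame({"strain_x": [0.0], "stress_x": [0.0]})
    if solver_path == "laminate":
        if loadcase.modality == "shear":
            return _shear_curve(spec, lamella, loadcase, increments, env,
                                swelling, convention)
        return _laminate_curves(spec, lamella, loadcase, increments, env,
                                swelling, convention)
    if solver_path != "fe":
        raise ValueError("solver_path must be 'laminate' or 'fe'")
    if loadcase.modality == "biaxial":
        raise NotImplementedError(
            "biaxial tests use the laminate path (grip-driven biaxial voxel "
            "models are out of scope)")
    model = build_voxel_model(spec, lamella, resolution)
    bc = loadcase.bc
    if loadcase.modality == "shear" and bc.kind != "parallel_plate":
        bc = BoundaryCondition("parallel_plate", bc.clamp)
    res = fe_solve(model, bc, strain=loadcase.strain, increments=increments,
                   env=env, swelling=swelling, convention=convention)
    return pd.DataFrame({"strain_x": res.strain,
                         "stress_x": res.nominal_stress})


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationTarget:
    """Experimental single-lamella region moduli (MPa) and tolerance."""

    E_low: float = 5.96
    E_med: float = 32.5
    E_high: float = 77.6
    sd_low: float = 3.05
    sd_med: float = 12.1
    sd_high: float = 20.0
    tolerance: float = 0.10

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")

    @property
    def values(self):
        return np.array([self.E_low, self.E_med, self.E_high])


@dataclass
class CalibrationResult:
    params: MaterialParams
    moduli: np.ndarray
    relative_errors: np.ndarray
    accepted: bool
    n_evaluations: int

    def to_dict(self):
        return {"moduli": self.moduli.tolist(),
                "relative_errors": self.relative_errors.tolist(),
                "accepted": bool(self.accepted),
                "n_evaluations": int(self.n_evaluations)}


_DEFAULT_BOUNDS = {"E_matrix": (0.02, 2.0), "E_lin": (100.0, 2000.0),
                   "gamma": (2.0, 12.0), "lambda0": (1.02, 1.2)}


def calibrate(target: CalibrationTarget,
              start: MaterialParams | None = None,
              model_family: str = "SEP",
              free_params=("E_matrix", "E_lin", "gamma", "lambda0"),
              bounds: dict | None = None,
              strain: float = 0.05, increments: int = 20,
              swelling: bool = False,
              env: Environment | None = None,
              lamella: LamellaSpec | None = None) -> CalibrationResult:
    """Bounded least squares on log-scaled parameters against region moduli.

    The objective is the relative error of the along-fiber single-lamella
    region moduli (E_low, E_med, E_high); acceptance is the within-tolerance
    predicate on all three.  Deterministic for a fixed starting point.
    """
    env = env or Environment()
    if start is None:
        start = preset("SEP-fiber-bundle") if model_family == "SEP" \
            else preset("HOM")
    bounds = {**_DEFAULT_BOUNDS, **(bounds or {})}
    lamella = lamella or LamellaSpec()
    n_eval = 0

    def build(params_vec):
        kw = {}
        for name, v in zip(free_params, params_vec):
            kw[name] = float(np.exp(v))
        bundle = replace(start, **{k: v for k, v in kw.items()
                                   if k != "E_matrix"})
        matrix = replace(lamella.matrix,
                         E_matrix=kw.get("E_matrix", lamella.matrix.E_matrix))
        if "E_matrix" in kw:
            bundle = replace(bundle, E_matrix=kw["E_matrix"])
        return matrix, bundle

    def simulate(params_vec):
        nonlocal n_eval
        n_eval += 1
        matrix, bundle = build(params_vec)
        mat = single_lamella_model(matrix, bundle, model_family=model_family,
                                   direction="fiber", lamella=lamella)
        rep = single_lamella_region_moduli(mat, strain=strain,
                                           increments=increments, env=env,
                                           swelling=swelling)
        return np.array([rep.E_low, rep.E_med, rep.E_high])

    def residuals(params_vec):
        sim = simulate(params_vec)
        return (sim - target.values) / target.values

    x0 = np.log([getattr(start, n) if n != "E_matrix"
                 else lamella.matrix.E_matrix for n in free_params])
    lo = np.log([bounds[n][0] for n in free_params])
    hi = np.log([bounds[n][1] for n in free_params])
    x0 = np.clip(x0, lo, hi)
    r0 = residuals(x0)
    if np.all(np.abs(r0) <= target.tolerance):
        matrix, bundle = build(x0)
        sim = r0 * target.values + target.values
        return CalibrationResult(params=bundle, moduli=sim,
                                 relative_errors=r0, accepted=True,
                                 n_evaluations=n_eval)
    sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                        diff_step=0.005, x_scale="jac", xtol=1e-10,
                        ftol=1e-10, max_nfev=250)
    r = residuals(sol.x)
    matrix, bundle = build(sol.x)
    sim = r * target.values + target.values
    return CalibrationResult(params=bundle, moduli=sim, relative_errors=r,
                             accepted=bool(np.all(np.abs(r) <= target.tolerance)),
                             n_evaluations=n_eval)
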