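"""Constitutive laws for annulus fibrosus constituents.

The annulus fibrosus (AF) is modelled as a fiber-reinforced composite of an
extrafibrillar matrix and collagen fiber bundles.  This module provides the
closed-form strain-energy densities and Cauchy stresses for

* a compressible neo-Hookean solid (extrafibrillar matrix),
* a compressible Holmes--Mow solid (ground substance of fiber bundles and of
  the homogenized tissue),
* a tension-only power-linear fiber family (toe region with power-law
  stiffening up to the transition stretch ``lambda0``, then a linear region
  with tangent modulus ``E_lin``),

together with Donnan osmotic swelling pressure (triphasic equilibrium) and
the strain-dependent Holmes--Mow hydraulic permeability.

Units are fixed to mm / N / MPa / mmol/L / s throughout.  All point-wise
functions are vectorized over leading array dimensions so the finite element
solver can evaluate them at every quadrature point in one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GAS_CONSTANT_MPA",
    "MaterialParams",
    "DeformationState",
    "Environment",
    "Material",
    "NeoHookeanMatrix",
    "FiberReinforced",
    "Mixture",
    "neo_hookean_energy",
    "holmes_mow_energy",
    "fiber_energy",
    "fiber_stress_1d",
    "power_linear_B",
    "cauchy_stress",
    "permeability",
    "donnan_pressure",
    "fixed_charge_density",
    "lame_constants",
    "material_from_dict",
    "material_to_dict",
    "preset",
    "PRESET_NAMES",
]

#: Gas constant in MPa per (mmol/L * K): 8.314 J/(mol K) = 8.314e-6 MPa m^3/(mol K),
#: and 1 mmol/L = 1 mol/m^3.
GAS_CONSTANT_MPA = 8.314e-6


class InvalidDeformationError(ValueError):
    """Raised for deformation gradients with non-positive determinant."""


class PoreClosureError(ValueError):
    """Raised when the volume ratio drops to the solid fraction (pores closed)."""


# ---------------------------------------------------------------------------
# parameter container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MaterialParams:
    """All constitutive, swelling, and transport constants for one constituent.

    Parameters
    ----------
    E_matrix, nu_matrix:
        Young's modulus (MPa) and Poisson's ratio of the isotropic ground
        substance (neo-Hookean or Holmes--Mow).
    beta:
        Exponential stiffening coefficient of the Holmes--Mow description.
    E_lin:
        Fiber modulus in the linear region, MPa (0.58 GPa is stored as 580).
    gamma:
        Power-law exponent of the fiber toe region (> 1).
    lambda0:
        Transition stretch between fiber toe and linear regions (> 1).
    cF0:
        Reference fixed charge density, mmol/L (<= 0; 0 disables swelling).
    phi_osm:
        Osmotic (activity) coefficient applied symmetrically to the internal
        and external phases.
    k0, phi0, alpha_perm, M_perm:
        Reference hydraulic permeability (mm^4/(N s)), solid volume fraction,
        and the power-law / exponential coefficients of the strain-dependent
        permeability.
    D0_Na, D0_Cl, DAF_Na, DAF_Cl:
        Free and in-tissue ion diffusivities (mm^2/s).  Stored for
        completeness; unused at swelling equilibrium.
    fiber_dirs:
        Reference unit vectors of the fiber families (0, 1, or 2 families).
    fiber_active:
        Master switch for the fiber contribution.
    cF_evolving:
        If True (default) the fixed charge density follows solid-volume
        kinematics, cF(J) = cF0 (1 - phi0) / (J - phi0); if False it is held
        at cF0.
    """

    E_matrix: float = 0.22
    nu_matrix: float = 0.3
    beta: float = 1.0
    E_lin: float = 580.0
    gamma: float = 5.95
    lambda0: float = 1.07
    cF0: float = 0.0
    phi_osm: float = 0.927
    k0: float = 0.0064
    phi0: float = 0.3
    alpha_perm: float = 2.0
    M_perm: float = 4.8
    D0_Na: float = 0.00116
    D0_Cl: float = 0.00161
    DAF_Na: float = 0.00044
    DAF_Cl: float = 0.00069
    fiber_dirs: tuple = ()
    fiber_active: bool = True
    cF_evolving: bool = True

    def __post_init__(self):
        if self.E_matrix <= 0:
            raise ValueError("E_matrix must be positive")
        if not -1.0 < self.nu_matrix < 0.5:
            raise ValueError("nu_matrix must lie in (-1, 0.5)")
        if self.gamma <= 1.0:
            raise ValueError("gamma must exceed 1 (denominator gamma - 1)")
        if self.lambda0 <= 1.0:
            raise ValueError("lambda0 must exceed 1")
        if not 0.0 < self.phi0 < 1.0:
            raise ValueError("phi0 must lie in (0, 1)")
        if self.k0 <= 0:
            raise ValueError("k0 must be positive")
        if self.cF0 > 0:
            raise ValueError("cF0 must be <= 0 (proteoglycans carry negative charge)")
        dirs = []
        for a in self.fiber_dirs:
            a = np.asarray(a, dtype=float)
            n = np.linalg.norm(a)
            if not np.isclose(n, 1.0, atol=1e-8):
                raise ValueError("fiber_dirs must be unit vectors")
            dirs.append(tuple(float(v) for v in a))
        object.__setattr__(self, "fiber_dirs", tuple(dirs))

    def with_fiber_dirs(self, dirs: Sequence[Sequence[float]]) -> "MaterialParams":
        return replace(self, fiber_dirs=tuple(tuple(d) for d in dirs))


@dataclass(frozen=True)
class Environment:
    """External bath: salt concentration (mmol/L), temperature (K), gas constant."""

    c_ext: float = 150.0
    T: float = 298.0
    R: float = GAS_CONSTANT_MPA

    def __post_init__(self):
        if self.c_ext < 0:
            raise ValueError("bath concentration must be non-negative")
        if self.T <= 0:
            raise ValueError("temperature must be positive")


# ---------------------------------------------------------------------------
# deformation state
# ---------------------------------------------------------------------------


@dataclass
class DeformationState:
    """Deformation gradient and derived invariants at a material point.

    Arrays may carry leading batch dimensions; ``F`` has shape ``(..., 3, 3)``.
    """

    F: np.ndarray
    J: np.ndarray
    C: np.ndarray
    I1: np.ndarray
    I2: np.ndarray

    @classmethod
    def from_F(cls, F) -> "DeformationState":
        F = np.asarray(F, dtype=float)
        J = np.linalg.det(F)
        if np.any(J <= 0):
            raise InvalidDeformationError("det(F) must be positive")
        C = np.einsum("...ji,...jk->...ik", F, F)
        I1 = np.trace(C, axis1=-2, axis2=-1)
        CC = np.einsum("...ij,...jk->...ik", C, C)
        I2 = 0.5 * (I1**2 - np.trace(CC, axis1=-2, axis2=-1))
        return cls(F=F, J=J, C=C, I1=I1, I2=I2)

    def fiber_stretch(self, a0) -> np.ndarray:
        """Stretch of a fiber with reference direction ``a0``: |F a0|."""
        a0 = np.asarray(a0, dtype=float)
        fa = np.einsum("...ij,j->...i", self.F, a0)
        return np.sqrt(np.einsum("...i,...i->...", fa, fa))


def lame_constants(E: float, nu: float) -> tuple[float, float]:
    """Lamé constants (lam, mu) from Young's modulus and Poisson's ratio."""
    mu = E / (2.0 * (1.0 + nu))
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return lam, mu


# ---------------------------------------------------------------------------
# strain-energy densities
# ---------------------------------------------------------------------------


def neo_hookean_energy(state: DeformationState, p: MaterialParams):
    """Compressible neo-Hookean strain energy density (MPa).

    W = mu/2 (I1 - 3) - mu ln J + lam/2 (ln J)^2, with Lamé constants from
    (E_matrix, nu_matrix).  W(identity) = 0 and the small-strain tangent is
    the isotropic elasticity tensor of (E, nu).
    """
    lam, mu = lame_constants(p.E_matrix, p.nu_matrix)
    lnJ = np.log(state.J)
    return 0.5 * mu * (state.I1 - 3.0) - mu * lnJ + 0.5 * lam * lnJ**2


def _hm_coeffs(p: MaterialParams):
    lam, mu = lame_constants(p.E_matrix, p.nu_matrix)
    if np.isclose(p.nu_matrix, 0.5):
        raise ValueError("Holmes-Mow requires nu != 0.5")
    c = p.E_matrix * (1.0 - p.nu_matrix) / (
        2.0 * p.beta * (1.0 + p.nu_matrix) * (1.0 - 2.0 * p.nu_matrix)
    )  # = (lam + 2 mu) / (2 beta)
    q0 = p.beta / (lam + 2.0 * mu)
    return lam, mu, c, q0


def holmes_mow_energy(state: DeformationState, p: MaterialParams):
    """Holmes--Mow strain energy density W = c/2 (e^Q - 1) (MPa).

    Q = beta/(lam+2mu) [ (2mu-lam)(I1-3) + lam (I2-3) - (lam+2mu) ln(J^2) ].
    Reduces to the (E, nu) isotropic tangent at the identity for any beta.
    """
    lam, mu, c, q0 = _hm_coeffs(p)
    lnJ2 = 2.0 * np.log(state.J)
    Q = q0 * (
        (2.0 * mu - lam) * (state.I1 - 3.0)
        + lam * (state.I2 - 3.0)
        - (lam + 2.0 * mu) * lnJ2
    )
    return 0.5 * c * (np.exp(Q) - 1.0)


def _fiber_xi(p: MaterialParams) -> float:
    return (
        p.E_lin
        / (4.0 * p.gamma * (p.gamma - 1.0))
        * (p.lambda0**2 - 1.0) ** (2.0 - p.gamma)
    )


def power_linear_B(p: MaterialParams) -> float:
    """Linear-region quadratic coefficient B of the literal branch algebra.

    B = E_lin/2 [ (lambda0^2 - 1) / (2 (gamma - 1)) + lambda0^2 ].
    """
    return 0.5 * p.E_lin * (
        (p.lambda0**2 - 1.0) / (2.0 * (p.gamma - 1.0)) + p.lambda0**2
    )


def fiber_energy(lambda_n, p: MaterialParams, convention: str = "continuous"):
    """Tension-only power-linear fiber strain energy density (MPa).

    Zero for ``lambda_n < 1``; power-law toe up to the transition stretch
    ``lambda0``; linear region beyond.  The default ``"continuous"``
    convention writes the toe in powers of (lambda_n^2 - 1) with the
    coefficient xi = E_lin / (4 gamma (gamma-1)) (lambda0^2-1)^(2-gamma) and
    continues with tangent exactly E_lin, so both the energy and the fiber
    stress are continuous at lambda0.  ``"literal"`` evaluates the literal
    branch algebra ((lambda_n - 1)^gamma powers and the quadratic
    coefficient of :func:`power_linear_B`),
    which is energy- but not stress-continuous.
    """
    lam = np.asarray(lambda_n, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("fiber stretch must be positive")
    xi = _fiber_xi(p)
    g, l0, E = p.gamma, p.lambda0, p.E_lin
    if convention == "continuous":
        toe = xi * np.clip(lam**2 - 1.0, 0.0, None) ** g
        psi0 = xi * (l0**2 - 1.0) ** g
        t0 = 2.0 * g * xi * l0 * (l0**2 - 1.0) ** (g - 1.0)
        lin = psi0 + t0 * (lam - l0) + 0.5 * E * (lam - l0) ** 2
    elif convention == "literal":
        B = power_linear_B(p)
        toe = xi * np.clip(lam - 1.0, 0.0, None) ** g
        lin = E * (lam - l0) + B * (lam**2 - l0**2) + xi * (lam - 1.0) ** g
    else:  # pragma: no cover - guarded interface
        raise ValueError(f"unknown fiber convention {convention!r}")
    return np.where(lam < 1.0, 0.0, np.where(lam <= l0, toe, lin))


def fiber_stress_1d(lambda_n, p: MaterialParams, convention: str = "continuous"):
    """d(psi)/d(lambda_n): nominal fiber stress along the fiber (MPa)."""
    lam = np.asarray(lambda_n, dtype=float)
    xi = _fiber_xi(p)
    g, l0, E = p.gamma, p.lambda0, p.E_lin
    if convention == "continuous":
        toe = 2.0 * g * xi * lam * np.clip(lam**2 - 1.0, 0.0, None) ** (g - 1.0)
        t0 = 2.0 * g * xi * l0 * (l0**2 - 1.0) ** (g - 1.0)
        lin = t0 + E * (lam - l0)
    elif convention == "literal":
        B = power_linear_B(p)
        toe = g * xi * np.clip(lam - 1.0, 0.0, None) ** (g - 1.0)
        lin = E + 2.0 * B * lam + g * xi * (lam - 1.0) ** (g - 1.0)
    else:  # pragma: no cover
        raise ValueError(f"unknown fiber convention {convention!r}")
    return np.where(lam < 1.0, 0.0, np.where(lam <= l0, toe, lin))


# ---------------------------------------------------------------------------
# swelling and permeability
# ---------------------------------------------------------------------------


def fixed_charge_density(J, p: MaterialParams):
    """Current fixed charge density cF(J), mmol/L (non-positive).

    Solid-volume conservation dilutes the charge with swelling:
    cF(J) = cF0 (1 - phi0) / (J - phi0).  With ``cF_evolving=False`` the
    reference value is held.
    """
    J = np.asarray(J, dtype=float)
    if np.any(J <= p.phi0):
        raise PoreClosureError("J must exceed the solid volume fraction phi0")
    if not p.cF_evolving:
        return np.broadcast_to(np.asarray(p.cF0, dtype=float), J.shape).copy()
    return p.cF0 * (1.0 - p.phi0) / (J - p.phi0)


def donnan_pressure(J, p: MaterialParams, env: Environment):
    """Ideal Donnan osmotic pressure difference (MPa).

    delta_pi = phi_osm R T ( sqrt(cF(J)^2 + 4 c_ext^2) - 2 c_ext ), the
    triphasic swelling pressure at equilibrium with the osmotic coefficient
    applied symmetrically to the internal and external phases.  Zero when
    cF0 = 0 (fibers do not swell) and strictly decreasing in J.
    """
    if env.c_ext < 0:
        raise ValueError("bath concentration must be non-negative")
    cF = fixed_charge_density(J, p)
    return (
        p.phi_osm
        * env.R
        * env.T
        * (np.sqrt(cF**2 + 4.0 * env.c_ext**2) - 2.0 * env.c_ext)
    )


def permeability(J, p: MaterialParams):
    """Strain-dependent Holmes--Mow hydraulic permeability k(J), mm^4/(N s).

    k(J) = k0 ((J - phi0)/(1 - phi0))^alpha exp( M (J^2 - 1) / 2 ).
    k(1) = k0 exactly; k -> 0 as J -> phi0 (pore closure).
    """
    J = np.asarray(J, dtype=float)
    if np.any(J <= p.phi0):
        raise PoreClosureError("J must exceed phi0 (pores closed)")
    return (
        p.k0
        * ((J - p.phi0) / (1.0 - p.phi0)) ** p.alpha_perm
        * np.exp(0.5 * p.M_perm * (J**2 - 1.0))
    )


# ---------------------------------------------------------------------------
# Cauchy stresses
# ---------------------------------------------------------------------------


def _iso_stress(state: DeformationState, W1, W2, WJ):
    """Cauchy stress of an isotropic energy from dW/dI1, dW/dI2, dW/dJ."""
    F = state.F
    B = np.einsum("...ij,...kj->...ik", F, F)
    BB = np.einsum("...ij,...jk->...ik", B, B)
    I = np.broadcast_to(np.eye(3), B.shape)
    J = state.J[..., None, None]
    I1 = state.I1[..., None, None]
    W1 = np.asarray(W1)[..., None, None]
    W2 = np.asarray(W2)[..., None, None]
    WJ = np.asarray(WJ)[..., None, None]
    return (2.0 / J) * (W1 * B + W2 * (I1 * B - BB)) + WJ * I


def _neo_hookean_stress(state: DeformationState, p: MaterialParams):
    lam, mu = lame_constants(p.E_matrix, p.nu_matrix)
    J = state.J[..., None, None]
    B = np.einsum("...ij,...kj->...ik", state.F, state.F)
    I = np.broadcast_to(np.eye(3), B.shape)
    return (mu / J) * (B - I) + (lam * np.log(J) / J) * I


def _holmes_mow_stress(state: DeformationState, p: MaterialParams):
    lam, mu, c, q0 = _hm_coeffs(p)
    lnJ2 = 2.0 * np.log(state.J)
    Q = q0 * (
        (2.0 * mu - lam) * (state.I1 - 3.0)
        + lam * (state.I2 - 3.0)
        - (lam + 2.0 * mu) * lnJ2
    )
    eQ = np.exp(Q)
    # c * q0 = 1/2
    W1 = 0.25 * eQ * (2.0 * mu - lam)
    W2 = 0.25 * eQ * lam
    WJ = -0.5 * eQ * (lam + 2.0 * mu) / state.J
    return _iso_stress(state, W1, W2, WJ)


def _fiber_family_stress(state: DeformationState, a0, p: MaterialParams,
                         convention: str = "continuous"):
    a0 = np.asarray(a0, dtype=float)
    fa = np.einsum("...ij,j->...i", state.F, a0)
    lam_n = np.sqrt(np.einsum("...i,...i->...", fa, fa))
    t = fiber_stress_1d(lam_n, p, convention)
    # sigma = (psi'(lam) lam / J) a x a  with a = F a0 / lam
    coef = t / (lam_n * state.J)
    return coef[..., None, None] * np.einsum("...i,...j->...ij", fa, fa)


# ---------------------------------------------------------------------------
# material objects
# ---------------------------------------------------------------------------


class Material:
    """Base class: a constituent (or mixture) with energy and Cauchy stress.

    ``swelling=True`` subtracts the Donnan pressure times identity from the
    elastic stress (and adds the corresponding osmotic work is *not* part of
    the stored elastic energy; the osmotic term enters equilibrium through
    the stress only, as in triphasic equilibrium).
    """

    params: MaterialParams

    def energy(self, state: DeformationState):
        raise NotImplementedError

    def elastic_stress(self, state: DeformationState):
        raise NotImplementedError

    def cauchy_stress(self, state: DeformationState, env: Environment | None = None,
                      swelling: bool = False):
        sig = self.elastic_stress(state)
        if swelling:
            if env is None:
                raise ValueError("swelling requires an Environment")
            sig = sig - self.osmotic_pressure(state.J, env)[..., None, None] * np.broadcast_to(
                np.eye(3), sig.shape
            )
        return sig

    def osmotic_pressure(self, J, env: Environment):
        p = self.params
        if p.cF0 == 0.0:
            return np.zeros(np.shape(J))
        return donnan_pressure(J, p, env)


class NeoHookeanMatrix(Material):
    """Extrafibrillar matrix: compressible neo-Hookean, swelling-capable."""

    def __init__(self, params: MaterialParams):
        self.params = params

    def energy(self, state):
        return neo_hookean_energy(state, self.params)

    def elastic_stress(self, state):
        return _neo_hookean_stress(state, self.params)


class FiberReinforced(Material):
    """Holmes--Mow ground substance reinforced by tension-only fiber families.

    ``family_weights`` scales each family's energy density (used by the
    homogenized description to split the fiber content between the two
    symmetric families).
    """

    def __init__(self, params: MaterialParams, family_weights=None,
                 convention: str = "continuous", ground: str = "holmes-mow"):
        self.params = params
        n = len(params.fiber_dirs)
        if family_weights is None:
            family_weights = (1.0,) * n
        if len(family_weights) != n:
            raise ValueError("one weight per fiber family")
        self.family_weights = tuple(float(w) for w in family_weights)
        self.convention = convention
        if ground not in ("holmes-mow", "neo-hookean"):
            raise ValueError("ground must be 'holmes-mow' or 'neo-hookean'")
        self.ground = ground

    def energy(self, state):
        p = self.params
        if self.ground == "holmes-mow":
            W = holmes_mow_energy(state, p)
        else:
            W = neo_hookean_energy(state, p)
        if p.fiber_active:
            for w, a0 in zip(self.family_weights, p.fiber_dirs):
                W = W + w * fiber_energy(state.fiber_stretch(a0), p, self.convention)
        return W

    def elastic_stress(self, state):
        p = self.params
        if self.ground == "holmes-mow":
            sig = _holmes_mow_stress(state, p)
        else:
            sig = _neo_hookean_stress(state, p)
        if p.fiber_active:
            for w, a0 in zip(self.family_weights, p.fiber_dirs):
                sig = sig + w * _fiber_family_stress(state, a0, p, self.convention)
        return sig


class Mixture(Material):
    """Volume-weighted mixture of constituents (Voigt, shared deformation).

    Used for the homogenized tissue description and for laminate plies of
    the separate-volume model; the osmotic stress is the volume-weighted sum
    of constituent Donnan pressures.
    """

    def __init__(self, parts: Sequence[tuple[float, Material]]):
        if not parts:
            raise ValueError("mixture needs at least one constituent")
        self.parts = [(float(w), m) for w, m in parts]
        # representative params: first constituent (for permeability queries)
        self.params = self.parts[0][1].params

    def energy(self, state):
        return sum(w * m.energy(state) for w, m in self.parts)

    def elastic_stress(self, state):
        return sum(w * m.elastic_stress(state) for w, m in self.parts)

    def osmotic_pressure(self, J, env):
        return sum(w * m.osmotic_pressure(J, env) for w, m in self.parts)


def cauchy_stress(material: Material, state: DeformationState,
                  env: Environment | None = None, swelling: bool = False):
    """Cauchy stress (3x3 symmetric, MPa) of a material at a deformation state."""
    return material.cauchy_stress(state, env=env, swelling=swelling)


# ---------------------------------------------------------------------------
# presets and serialization
# ---------------------------------------------------------------------------


def _fiber_direction(angle_deg: float) -> tuple[float, float, float]:
    """Unit fiber direction at ``angle_deg`` to the transverse (circ.) axis.

    Axes: x = circumferential, y = axial, z = radial (lamella normal).
    """
    a = np.deg2rad(angle_deg)
    return (float(np.cos(a)), float(np.sin(a)), 0.0)


#: Calibrated parameter sets.  E_lin is stored in MPa (tables print GPa).
_PRESETS: dict[str, dict] = {
    "SEP-matrix": dict(
        E_matrix=0.22, nu_matrix=0.3, cF0=-100.0, fiber_dirs=(), fiber_active=False,
    ),
    "SEP-fiber-bundle": dict(
        E_matrix=0.22, nu_matrix=0.3, beta=1.0, E_lin=580.0, gamma=5.95,
        lambda0=1.07, cF0=0.0, fiber_dirs=(_fiber_direction(30.0),),
    ),
    "HOM": dict(
        E_matrix=0.22, nu_matrix=0.3, beta=1.0, E_lin=530.0, gamma=6.0,
        lambda0=1.09, cF0=-100.0,
        fiber_dirs=(_fiber_direction(30.0), _fiber_direction(-30.0)),
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str, **overrides) -> MaterialParams:
    """Named parameter presets: "SEP-matrix", "SEP-fiber-bundle", "HOM"."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    kw = dict(_PRESETS[name])
    kw.update(overrides)
    return MaterialParams(**kw)


def material_to_dict(p: MaterialParams) -> dict:
    d = {k: getattr(p, k) for k in p.__dataclass_fields__}
    d["fiber_dirs"] = [list(a) for a in p.fiber_dirs]
    return d


def material_from_dict(d: dict) -> MaterialParams:
    kw = dict(d)
    kw["fiber_dirs"] = tuple(tuple(a) for a in kw.get("fiber_dirs", ()))
    return MaterialParams(**kw)
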