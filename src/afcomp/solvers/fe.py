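"""Total-Lagrangian finite-strain solver on voxel hexahedral meshes.

Each voxel of a :class:`~afcomp.microstructure.VoxelModel` is a trilinear
hexahedral element.  An F-bar (centroid-dilatation) treatment controls
volumetric locking.  Swelling enters as a constituent-wise osmotic stress
(Donnan pressure in charge-carrying constituents), equilibrated in a
pre-step before the mechanical load program; engineering strain and nominal
stress are measured from the swollen configuration.

The separate-volume (SEP) description uses the per-voxel bundle volume
weights of the microstructure map (each voxel blends matrix and bundle
material in the exact proportion it contains); the homogenized (HOM)
description carries the blended fiber-plus-matrix material everywhere.

The tangent stiffness is obtained by central finite differencing of the
element residual, so fibers, F-bar, and osmotic terms are all captured by
one code path; residuals use the closed-form Cauchy stresses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ..materials import (DeformationState, Environment, MaterialParams,
                         donnan_pressure, fiber_energy, fiber_stress_1d,
                         holmes_mow_energy, neo_hookean_energy,
                         _holmes_mow_stress, _neo_hookean_stress)
from ..microstructure import VoxelModel, fiber_volume_fraction
from ._newton import NonConvergenceError

log = logging.getLogger("afcomp.fe")

__all__ = ["BoundaryCondition", "FEResult", "fe_solve", "VoxelMesh",
           "build_mesh", "VoxelStressField", "solve_affine_patch"]

_CORNERS = np.array([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
                     (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)])
_XI = 2.0 * _CORNERS - 1.0


@dataclass(frozen=True)
class BoundaryCondition:
    """Grip description for the load program.

    kind:
        ``gripped`` / ``vertebrae_attached`` — end faces (x = 0, x = L) are
        bonded to the grips/platens; ``parallel_plate`` — the z faces are
        bonded to shear plates.
    clamp:
        ``full`` (all displacement components of the gripped faces held) or
        ``guided`` (only the loading component prescribed).
    """

    kind: str = "gripped"
    clamp: str = "full"

    def __post_init__(self):
        if self.kind not in ("gripped", "vertebrae_attached", "parallel_plate"):
            raise ValueError(f"unknown boundary condition kind {self.kind!r}")
        if self.clamp not in ("full", "guided"):
            raise ValueError("clamp must be 'full' or 'guided'")


@dataclass
class VoxelMesh:
    nodes: np.ndarray     # (N, 3)
    conn: np.ndarray      # (n_e, 8)
    h: tuple              # (hx, hy, hz) voxel edges, mm
    shape: tuple
    dN: np.ndarray        # (8 gp, 8 nodes, 3) reference shape gradients
    dN0: np.ndarray       # (8 nodes, 3) centroid gradients
    w_gp: float           # gauss-point volume


def _shape_gradients(h):
    hx, hy, hz = h
    g = 1.0 / np.sqrt(3.0)
    gps = _XI * g
    scale = np.array([2.0 / hx, 2.0 / hy, 2.0 / hz])
    def grads(xi):
        d = np.empty((8, 3))
        for a in range(8):
            xa = _XI[a]
            d[a, 0] = 0.125 * xa[0] * (1 + xi[1] * xa[1]) * (1 + xi[2] * xa[2])
            d[a, 1] = 0.125 * xa[1] * (1 + xi[0] * xa[0]) * (1 + xi[2] * xa[2])
            d[a, 2] = 0.125 * xa[2] * (1 + xi[0] * xa[0]) * (1 + xi[1] * xa[1])
        return d * scale
    dN = np.stack([grads(x) for x in gps])
    dN0 = grads(np.zeros(3))
    return dN, dN0, hx * hy * hz / 8.0


def build_mesh(model: VoxelModel) -> VoxelMesh:
    nx, ny, nz = model.shape
    h = model.h
    ix, iy, iz = np.meshgrid(np.arange(nx + 1), np.arange(ny + 1),
                             np.arange(nz + 1), indexing="ij")
    nodes = np.stack([h[0] * ix.ravel(), h[1] * iy.ravel(),
                      h[2] * iz.ravel()], axis=1).astype(float)

    def nid(ax, ay, az):
        return (ax * (ny + 1) + ay) * (nz + 1) + az

    ex, ey, ez = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    ex, ey, ez = ex.ravel(), ey.ravel(), ez.ravel()
    conn = np.stack([nid(ex + cx, ey + cy, ez + cz) for cx, cy, cz in _CORNERS],
                    axis=1)
    dN, dN0, w_gp = _shape_gradients(h)
    return VoxelMesh(nodes=nodes, conn=conn, h=h, shape=model.shape,
                     dN=dN, dN0=dN0, w_gp=w_gp)


class VoxelStressField:
    """Batched Cauchy stress / energy density over all elements of a model."""

    def __init__(self, model: VoxelModel, env: Environment | None = None,
                 convention: str = "continuous"):
        self.model = model
        self.env = env or Environment()
        self.convention = convention
        self.matrix = model.lamella.matrix
        self.bundle = model.lamella.bundle
        nx, ny, nz = model.shape
        lam_of_e = np.tile(model.lamella_of_layer, nx * ny)
        # per-element fiber directions (n_e, n_fam, 3)
        self.dirs = model.fiber_dirs[lam_of_e]
        if model.spec.model_family == "SEP":
            self.w = model.bundle_weight.reshape(-1)
            self.fam_w = np.ones(self.dirs.shape[1])
        else:
            vf = fiber_volume_fraction(model.lamella)
            self.w = np.zeros(nx * ny * nz)
            self.fam_w = np.full(self.dirs.shape[1], vf / self.dirs.shape[1])
        self._idx_matrix = np.where(self.w == 0.0)[0]
        self._idx_bundle = np.where(self.w > 0.0)[0]

    def _fiber_sigma(self, F, J, p: MaterialParams, dirs):
        sig = np.zeros_like(F)
        for k in range(dirs.shape[1]):
            a0 = dirs[:, k, :]
            fa = np.einsum("epij,ej->epi", F, a0)
            lam = np.sqrt(np.einsum("epi,epi->ep", fa, fa))
            t = fiber_stress_1d(lam, p, self.convention)
            coef = self.fam_w[k] * t / (lam * J)
            sig += coef[..., None, None] * np.einsum("epi,epj->epij", fa, fa)
        return sig

    def _matrix_sigma(self, F, J, swell):
        """Neo-Hookean matrix + osmotic stress, minimal evaluations."""
        from ..materials import lame_constants
        lam, mu = lame_constants(self.matrix.E_matrix, self.matrix.nu_matrix)
        B = np.einsum("epij,epkj->epik", F, F)
        I3 = np.eye(3)
        Jn = J[..., None, None]
        sig = (mu / Jn) * (B - I3) + (lam * np.log(Jn) / Jn) * I3
        if swell and self.matrix.cF0 != 0.0:
            pi = donnan_pressure(J, self.matrix, self.env)
            sig = sig - (swell * pi)[..., None, None] * I3
        return sig

    def cauchy(self, F, swell: float = 1.0):
        """F: (n_e, n_gp, 3, 3) -> Cauchy stress, same shape.

        Pure-matrix voxels take a lean neo-Hookean path; only voxels with
        nonzero bundle weight evaluate the Holmes--Mow + fiber description.
        """
        fam = self.model.spec.model_family
        if fam == "HOM":
            state = DeformationState.from_F(F)
            sig = _holmes_mow_stress(state, self.bundle)
            sig = sig + self._fiber_sigma(F, state.J, self.bundle, self.dirs)
            if swell and self.bundle.cF0 != 0.0:
                pi = donnan_pressure(state.J, self.bundle, self.env)
                sig = sig - (swell * pi)[..., None, None] * np.eye(3)
            return sig
        J = np.linalg.det(F)
        if np.any(J <= 0):
            raise FloatingPointError("non-positive J in stress evaluation")
        sig = np.empty_like(F)
        im, ib = self._idx_matrix, self._idx_bundle
        if im.size:
            sig[im] = self._matrix_sigma(F[im], J[im], swell)
        if ib.size:
            Fb = F[ib]
            state = DeformationState.from_F(Fb)
            sb = _holmes_mow_stress(state, self.bundle)
            sb = sb + self._fiber_sigma(Fb, state.J, self.bundle,
                                        self.dirs[ib])
            sm = self._matrix_sigma(Fb, state.J, swell)
            w = self.w[ib][:, None, None, None]
            out = (1.0 - w) * sm + w * sb
            if swell and self.bundle.cF0 != 0.0:
                pi = donnan_pressure(state.J, self.bundle, self.env)
                out = out - (swell * self.w[ib][:, None] * pi)[..., None, None] \
                    * np.eye(3)
            sig[ib] = out
        return sig

    def energy(self, F):
        """Elastic strain-energy density (MPa), same leading shape as F."""
        state = DeformationState.from_F(F)
        fam = self.model.spec.model_family
        psi_fib = np.zeros(state.J.shape)
        for k in range(self.dirs.shape[1]):
            a0 = self.dirs[:, k, :]
            fa = np.einsum("epij,ej->epi", F, a0)
            lam = np.sqrt(np.einsum("epi,epi->ep", fa, fa))
            psi_fib += self.fam_w[k] * fiber_energy(lam, self.bundle, self.convention)
        if fam == "SEP":
            W = ((1.0 - self.w[:, None]) * neo_hookean_energy(state, self.matrix)
                 + self.w[:, None] * (holmes_mow_energy(state, self.bundle) + psi_fib))
        else:
            W = holmes_mow_energy(state, self.bundle) + psi_fib
        return W


@dataclass
class FEResult:
    strain: np.ndarray
    nominal_stress: np.ndarray
    reaction: np.ndarray
    u: np.ndarray
    u_swollen: np.ndarray
    swollen_length: float
    swollen_area: float
    iterations: list
    meta: dict = field(default_factory=dict)


class _FESystem:
    def __init__(self, model: VoxelModel, env: Environment | None = None,
                 convention: str = "continuous", fbar: bool = False):
        self.model = model
        self.mesh = build_mesh(model)
        self.field = VoxelStressField(model, env, convention)
        self.fbar = bool(fbar)
        conn = self.mesh.conn
        n_e = conn.shape[0]
        self.n_nodes = self.mesh.nodes.shape[0]
        self.ndof = 3 * self.n_nodes
        edof = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(n_e, 24)
        self.edof = edof
        self.Krows = np.repeat(edof, 24, axis=1).ravel()
        self.Kcols = np.tile(edof, (1, 24)).ravel()
        self._kernel_args = self._build_kernel_args()

    def _build_kernel_args(self):
        """Constants for the numba fast path; None -> numpy reference path."""
        from ..materials import lame_constants, _hm_coeffs, _fiber_xi
        fld = self.field
        if fld.convention != "continuous":
            return None
        model = self.model
        is_hom = model.spec.model_family == "HOM"
        bundle = fld.bundle
        matrix = fld.matrix
        if (not is_hom) and bundle.cF0 != 0.0:
            return None          # kernel assumes the matrix carries the charge
        charged = bundle if is_hom else matrix
        lam_m, mu_m = lame_constants(matrix.E_matrix, matrix.nu_matrix)
        lam_b, mu_b, cHM, q0 = _hm_coeffs(bundle)
        xi = _fiber_xi(bundle)
        t0_fib = (2.0 * bundle.gamma * xi * bundle.lambda0
                  * (bundle.lambda0**2 - 1.0) ** (bundle.gamma - 1.0))
        env = fld.env
        return (
            np.ascontiguousarray(fld.w, dtype=float),
            np.ascontiguousarray(fld.dirs, dtype=float),
            np.ascontiguousarray(fld.fam_w, dtype=float),
            bool(is_hom),
            float(lam_m), float(mu_m), float(lam_b), float(mu_b),
            float(cHM), float(q0),
            float(xi), float(bundle.gamma), float(bundle.lambda0),
            float(bundle.E_lin), float(t0_fib),
            float(charged.cF0), float(charged.phi0),
            float(charged.phi_osm * env.R * env.T), float(env.c_ext),
            bool(charged.cF_evolving),
        )

    def element_residual(self, ue, swell):
        """ue: (n_e, 8, 3) element displacements -> (n_e, 8, 3) forces."""
        return self._element_residual_batch(ue[:, None], swell)[:, 0]

    def _element_residual_batch(self, ue, swell):
        """Dispatch to the numba kernel when it covers the material setup."""
        if self._kernel_args is not None:
            from ._kernels import element_residual_kernel
            ue = np.ascontiguousarray(ue, dtype=float)
            forces = np.zeros_like(ue)
            err = element_residual_kernel(
                ue, self.mesh.dN, self.mesh.dN0, self.mesh.w_gp,
                *self._kernel_args, self.fbar, float(swell), forces)
            if err:
                raise FloatingPointError("element inversion or pore closure")
            return forces
        return self._element_residual_batch_numpy(ue, swell)

    def _element_residual_batch_numpy(self, ue, swell):
        """ue: (n_e, K, 8, 3) -> (n_e, K, 8, 3); K parallel configurations."""
        mesh = self.mesh
        n_e, K = ue.shape[:2]
        with np.errstate(over="raise", invalid="raise", divide="raise"):
            F = np.eye(3) + np.einsum("ekai,paj->ekpij", ue, mesh.dN)
            J = np.linalg.det(F)
            if np.any(J <= 0):
                raise FloatingPointError("element inversion")
            if self.fbar:
                F0 = np.eye(3) + np.einsum("ekai,aj->ekij", ue, mesh.dN0)
                J0 = np.linalg.det(F0)
                if np.any(J0 <= 0):
                    raise FloatingPointError("element inversion")
                Fb = ((J0[..., None] / J) ** (1.0 / 3.0))[..., None, None] * F
                Jb = np.broadcast_to(J0[..., None], J.shape)
            else:
                Fb = F
                Jb = J
            sig = self.field.cauchy(Fb.reshape(n_e, K * 8, 3, 3), swell=swell)
            sig = sig.reshape(n_e, K, 8, 3, 3)
            Fb_inv = np.linalg.inv(Fb)
            P = Jb[..., None, None] * np.einsum("ekpij,ekplj->ekpil",
                                                sig, Fb_inv)
            return mesh.w_gp * np.einsum("ekpij,paj->ekai", P, mesh.dN)

    def residual(self, u, swell):
        ue = u.reshape(-1, 3)[self.mesh.conn]
        fe = self.element_residual(ue, swell)
        f = np.zeros(self.ndof)
        np.add.at(f, self.edof.ravel(), fe.reshape(len(fe), 24).ravel())
        return f

    def stiffness(self, u, swell, h_fd=2e-6):
        """Element-level central-difference tangent, assembled sparse.

        The 48 perturbed configurations are evaluated in chunked batches so
        the constitutive evaluation stays fully vectorized without holding
        all perturbations in memory at once.
        """
        ue0 = u.reshape(-1, 3)[self.mesh.conn]
        n_e = ue0.shape[0]
        pert = np.zeros((48, 8, 3))
        for k in range(24):
            a, i = divmod(k, 3)
            pert[2 * k, a, i] = h_fd
            pert[2 * k + 1, a, i] = -h_fd
        chunk = max(2, min(48, int(4.0e5 // max(n_e, 1)) * 2))
        fvals = np.empty((n_e, 48, 24))
        for s in range(0, 48, chunk):
            batch = ue0[:, None, :, :] + pert[None, s:s + chunk]
            fvals[:, s:s + chunk] = self._element_residual_batch(
                batch, swell).reshape(n_e, -1, 24)
        cols = (fvals[:, 0::2] - fvals[:, 1::2]).transpose(0, 2, 1) / (2 * h_fd)
        K = sp.coo_matrix((cols.ravel(), (self.Krows, self.Kcols)),
                          shape=(self.ndof, self.ndof)).tocsr()
        return K

    def total_energy(self, u):
        ue = u.reshape(-1, 3)[self.mesh.conn]
        F = np.eye(3) + np.einsum("eai,paj->epij", ue, self.mesh.dN)
        W = self.field.energy(F)
        return float(self.mesh.w_gp * W.sum())

    def _factorize(self, u, swell, free):
        K = self.stiffness(u, swell)
        Kff = K[free][:, free].tocsc()
        return spla.splu(Kff)

    def solve_equilibrium(self, u, fixed_dofs, fixed_vals, swell,
                          tol_rel=1e-6, max_iter=60):
        """Newton with a reusable stiffness factorization.

        The tangent is refactorized whenever the residual contraction rate
        degrades; the line search enforces a monotone residual norm and an
        outer increment-halving loop handles genuinely hard steps.
        """
        u = u.copy()
        u[fixed_dofs] = fixed_vals
        free = np.ones(self.ndof, dtype=bool)
        free[fixed_dofs] = False
        factor = None
        fresh = False
        nrm_prev = None
        for it in range(max_iter):
            try:
                f = self.residual(u, swell)
            except (FloatingPointError, ValueError) as exc:
                raise NonConvergenceError(f"invalid state: {exc}") from exc
            ref = max(float(np.linalg.norm(f)), 1e-9)
            nrm = float(np.linalg.norm(f[free])) if free.any() else 0.0
            if nrm < tol_rel * ref or nrm < 1e-12:
                return u, it, f
            # refactorize when contraction degrades, and always close to the
            # tolerance so the final steps converge quadratically
            stale_rate = nrm_prev is not None and nrm > 0.2 * nrm_prev
            endgame = nrm < 30.0 * tol_rel * ref
            if factor is None or stale_rate or endgame:
                factor = self._factorize(u, swell, free)
                fresh = True
            du = factor.solve(-f[free])
            if not np.all(np.isfinite(du)):
                raise NonConvergenceError("singular stiffness", residual_norm=nrm)
            alpha, accepted = 1.0, False
            for _ in range(14):
                u_try = u.copy()
                u_try[free] += alpha * du
                try:
                    f_try = self.residual(u_try, swell)
                except (FloatingPointError, ValueError):
                    alpha *= 0.5
                    continue
                if (np.all(np.isfinite(f_try))
                        and np.linalg.norm(f_try[free]) < nrm):
                    u, accepted = u_try, True
                    break
                alpha *= 0.5
            log.debug("newton it=%d nrm=%.3e ref=%.3e fresh=%s alpha=%s",
                      it, nrm, ref, fresh, alpha if accepted else None)
            if not accepted:
                if fresh:
                    raise NonConvergenceError("line search failed",
                                              residual_norm=nrm)
                factor = None      # retry with a fresh tangent
                nrm_prev = None
                continue
            nrm_prev = nrm
            fresh = False
        f = self.residual(u, swell)
        nrm = float(np.linalg.norm(f[free]))
        ref = max(float(np.linalg.norm(f)), 1e-9)
        if nrm < tol_rel * ref:
            return u, max_iter, f
        raise NonConvergenceError(
            f"FE Newton stalled (residual {nrm:.3e}, ref {ref:.3e})",
            residual_norm=nrm)


def _face_nodes(mesh: VoxelMesh, axis: int, side: int):
    coord = mesh.nodes[:, axis]
    target = coord.max() if side else 0.0
    return np.where(np.isclose(coord, target))[0]


def _rigid_body_constraints(mesh: VoxelMesh):
    """3-2-1 constraints pinning rigid modes, leaving swelling stress-free."""
    nx, ny, nz = mesh.shape
    def nid(ax, ay, az):
        return (ax * (ny + 1) + ay) * (nz + 1) + az
    dofs = [3 * nid(0, 0, 0) + 0, 3 * nid(0, 0, 0) + 1, 3 * nid(0, 0, 0) + 2,
            3 * nid(nx, 0, 0) + 1, 3 * nid(nx, 0, 0) + 2,
            3 * nid(0, ny, 0) + 2]
    return np.array(dofs)


def fe_solve(model: VoxelModel, bc: BoundaryCondition, strain: float,
             increments: int = 20, env: Environment | None = None,
             swelling: bool = True, convention: str = "continuous",
             tol_rel: float = 1e-6, max_iter: int = 60,
             swell_steps: int = 3, max_halvings: int = 6,
             fbar: bool = False) -> FEResult:
    """Quasi-static grip-driven loading of a voxel specimen.

    Free swelling is equilibrated first (osmotic pressure ramped in
    ``swell_steps`` sub-steps under rigid-body constraints only); the grips
    then hold the swollen faces and the load program applies ``strain``
    engineering strain (tensile for gripped/vertebrae-attached along x,
    simple shear displacement of the top plate for parallel-plate) measured
    from the swollen configuration.  Nominal stress is the grip reaction
    divided by the swollen cross-section.
    """
    sys_ = _FESystem(model, env, convention, fbar=fbar)
    mesh = sys_.mesh
    u = np.zeros(sys_.ndof)
    iters = []

    swell_on = swelling and (model.lamella.matrix.cF0 != 0.0
                             or model.lamella.bundle.cF0 != 0.0)
    if swell_on:
        rb = _rigid_body_constraints(mesh)
        for s in range(1, swell_steps + 1):
            u, it, _ = sys_.solve_equilibrium(
                u, rb, np.zeros(len(rb)), swell=s / swell_steps,
                tol_rel=tol_rel, max_iter=max_iter)
            iters.append(("swell", s / swell_steps, it))
            log.info("swell step %.2f it=%d", s / swell_steps, it)
    u_swollen = u.copy()
    swell = 1.0 if swell_on else 0.0

    x_s = mesh.nodes + u.reshape(-1, 3)
    if bc.kind in ("gripped", "vertebrae_attached"):
        load_axis, grip_axis = 0, 0
    else:
        load_axis, grip_axis = 0, 2
    lo = _face_nodes(mesh, grip_axis, 0)
    hi = _face_nodes(mesh, grip_axis, 1)
    span = float(x_s[hi, grip_axis].mean() - x_s[lo, grip_axis].mean())
    vol_s = float(np.sum(np.linalg.det(
        np.eye(3) + np.einsum("eai,aj->eij", u.reshape(-1, 3)[mesh.conn],
                              mesh.dN0)))) * (mesh.h[0] * mesh.h[1] * mesh.h[2])
    area_s = vol_s / span

    comps_full = (0, 1, 2)
    if bc.kind == "parallel_plate":
        move_comp = 0          # top plate translated tangentially (x)
    else:
        move_comp = load_axis
    if bc.clamp == "full":
        lo_comps = hi_comps = comps_full
    else:
        lo_comps = hi_comps = (move_comp,)

    fixed = []
    for n in lo:
        for c in lo_comps:
            fixed.append(3 * n + c)
    for n in hi:
        for c in hi_comps:
            fixed.append(3 * n + c)
    if bc.clamp == "guided":
        # guided grips leave transverse rigid modes free; pin them minimally
        nx, ny, nz = mesh.shape
        def nid(ax, ay, az):
            return (ax * (ny + 1) + ay) * (nz + 1) + az
        fixed.extend([3 * nid(0, 0, 0) + 1, 3 * nid(0, 0, 0) + 2,
                      3 * nid(0, ny, 0) + 2])
    fixed = np.array(sorted(set(fixed)))
    base_vals = u[fixed].copy()
    move_mask = np.isin(fixed, 3 * hi + move_comp)

    delta_total = strain * span
    strains = [0.0]
    reactions = [0.0]

    def reaction_at(u_now):
        f = sys_.residual(u_now, swell)
        return float(f[3 * hi + move_comp].sum())

    t = 0.0
    dt = 1.0 / increments
    halved = 0
    u_prev, t_prev = None, None
    while t < 1.0 - 1e-12:
        t_try = min(1.0, t + dt)
        vals = base_vals.copy()
        vals[move_mask] += t_try * delta_total
        u_guess = u
        if u_prev is not None and t > t_prev:
            # linear extrapolation predictor from the last two states
            u_guess = u + (u - u_prev) * ((t_try - t) / (t - t_prev))
        try:
            u_new, it, _ = sys_.solve_equilibrium(
                u_guess, fixed, vals, swell, tol_rel=tol_rel,
                max_iter=max_iter)
        except NonConvergenceError:
            try:
                u_new, it, _ = sys_.solve_equilibrium(
                    u, fixed, vals, swell, tol_rel=tol_rel,
                    max_iter=max_iter)
            except NonConvergenceError:
                if halved >= max_halvings:
                    raise
                dt *= 0.5
                halved += 1
                continue
        u_prev, t_prev = u, t
        u = u_new
        t = t_try
        iters.append(("load", t, it))
        log.info("load t=%.4f (strain %.4f) it=%d", t, t * strain, it)
        strains.append(t * strain)
        reactions.append(reaction_at(u))

    strains = np.asarray(strains)
    reactions = np.asarray(reactions)
    return FEResult(strain=strains, nominal_stress=reactions / area_s,
                    reaction=reactions, u=u, u_swollen=u_swollen,
                    swollen_length=span, swollen_area=area_s, iterations=iters,
                    meta=dict(bc=bc.kind, clamp=bc.clamp, strain=strain,
                              increments=increments, tol_rel=tol_rel,
                              resolution=model.h, shape=model.shape,
                              family=model.spec.model_family))


def solve_affine_patch(model: VoxelModel, F_target, env=None,
                       tol_rel=1e-6, fbar: bool = False,
                       convention: str = "continuous"):
    """Dirichlet patch problem: boundary nodes carry u = (F - I) X exactly.

    Returns (system, u).  For a homogeneous model the interior solution is
    the uniform deformation ``F_target`` (patch test).
    """
    sys_ = _FESystem(model, env, convention, fbar=fbar)
    mesh = sys_.mesh
    F = np.asarray(F_target, dtype=float)
    nx, ny, nz = mesh.shape
    X = mesh.nodes
    on_boundary = (np.isclose(X[:, 0], 0) | np.isclose(X[:, 0], X[:, 0].max())
                   | np.isclose(X[:, 1], 0) | np.isclose(X[:, 1], X[:, 1].max())
                   | np.isclose(X[:, 2], 0) | np.isclose(X[:, 2], X[:, 2].max()))
    nodes_b = np.where(on_boundary)[0]
    ub = (X[nodes_b] @ (F - np.eye(3)).T)
    fixed = (3 * nodes_b[:, None] + np.arange(3)[None, :]).ravel()
    vals = ub.ravel()
    u0 = X @ (F - np.eye(3)).T * 0.0
    u, it, _ = sys_.solve_equilibrium(u0.ravel(), fixed, vals, swell=0.0,
                                      tol_rel=tol_rel)
    return sys_, u
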