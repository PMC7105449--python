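"""Numba kernel for the voxel-FE element residual (hot path).

Implements the same constitutive stack as :mod:`afcomp.materials`
(neo-Hookean matrix, Holmes--Mow ground, tension-only power-linear fibers in
the stress-continuous convention, Donnan osmotic pressure) with explicit
3x3 arithmetic; the vectorized numpy path in ``fe.py`` is the reference the
kernel is tested against.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["element_residual_kernel"]


@njit(cache=False, fastmath=False)
def _det3(a):
    return (a[0, 0] * (a[1, 1] * a[2, 2] - a[1, 2] * a[2, 1])
            - a[0, 1] * (a[1, 0] * a[2, 2] - a[1, 2] * a[2, 0])
            + a[0, 2] * (a[1, 0] * a[2, 1] - a[1, 1] * a[2, 0]))


@njit(cache=False, fastmath=False)
def _inv3(a, out):
    d = _det3(a)
    out[0, 0] = (a[1, 1] * a[2, 2] - a[1, 2] * a[2, 1]) / d
    out[0, 1] = (a[0, 2] * a[2, 1] - a[0, 1] * a[2, 2]) / d
    out[0, 2] = (a[0, 1] * a[1, 2] - a[0, 2] * a[1, 1]) / d
    out[1, 0] = (a[1, 2] * a[2, 0] - a[1, 0] * a[2, 2]) / d
    out[1, 1] = (a[0, 0] * a[2, 2] - a[0, 2] * a[2, 0]) / d
    out[1, 2] = (a[0, 2] * a[1, 0] - a[0, 0] * a[1, 2]) / d
    out[2, 0] = (a[1, 0] * a[2, 1] - a[1, 1] * a[2, 0]) / d
    out[2, 1] = (a[0, 1] * a[2, 0] - a[0, 0] * a[2, 1]) / d
    out[2, 2] = (a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]) / d
    return d


@njit(cache=False, fastmath=False)
def element_residual_kernel(ue, dN, dN0, w_gp, w, dirs, fam_w, is_hom,
                            lam_m, mu_m, lam_b, mu_b, cHM, q0,
                            xi, gamma, lam0, E_lin, t0_fib,
                            cF0, phi0, piRT, c_ext, cF_evolving, use_fbar,
                            swell, forces):
    """Internal nodal forces for K parallel configurations per element.

    ue: (n_e, K, 8, 3); dN: (8 gp, 8 nodes, 3); forces: (n_e, K, 8, 3).
    Returns 0 on success, 1 on element inversion / pore closure.
    """
    n_e, K = ue.shape[0], ue.shape[1]
    n_fam = dirs.shape[1]
    F = np.empty((3, 3))
    F0 = np.empty((3, 3))
    Fb = np.empty((3, 3))
    Fbi = np.empty((3, 3))
    B = np.empty((3, 3))
    sig = np.empty((3, 3))
    P = np.empty((3, 3))
    v = np.empty(3)
    for e in range(n_e):
        we = w[e]
        for k in range(K):
            # centroid deformation gradient -> J0 (F-bar dilatation source)
            J0 = 1.0
            if use_fbar:
                for i in range(3):
                    for j in range(3):
                        s = 1.0 if i == j else 0.0
                        for a in range(8):
                            s += ue[e, k, a, i] * dN0[a, j]
                        F0[i, j] = s
                J0 = _det3(F0)
                if J0 <= 0.0:
                    return 1
            for p in range(8):
                for i in range(3):
                    for j in range(3):
                        s = 1.0 if i == j else 0.0
                        for a in range(8):
                            s += ue[e, k, a, i] * dN[p, a, j]
                        F[i, j] = s
                J = _det3(F)
                if J <= 0.0:
                    return 1
                if use_fbar:
                    scale = (J0 / J) ** (1.0 / 3.0)
                    Jb = J0
                else:
                    scale = 1.0
                    Jb = J
                for i in range(3):
                    for j in range(3):
                        Fb[i, j] = scale * F[i, j]
                lnJ = np.log(Jb)
                # B = Fb Fb^T and invariants
                I1 = 0.0
                for i in range(3):
                    for j in range(3):
                        s = 0.0
                        for m in range(3):
                            s += Fb[i, m] * Fb[j, m]
                        B[i, j] = s
                    I1 += B[i, i]
                trB2 = 0.0
                for i in range(3):
                    for j in range(3):
                        trB2 += B[i, j] * B[j, i]
                I2 = 0.5 * (I1 * I1 - trB2)

                for i in range(3):
                    for j in range(3):
                        sig[i, j] = 0.0

                if is_hom or we > 0.0:
                    # Holmes-Mow ground substance (bundle parameters)
                    Q = q0 * ((2.0 * mu_b - lam_b) * (I1 - 3.0)
                              + lam_b * (I2 - 3.0)
                              - (lam_b + 2.0 * mu_b) * 2.0 * lnJ)
                    eQ = np.exp(Q)
                    W1 = 0.25 * eQ * (2.0 * mu_b - lam_b)
                    W2 = 0.25 * eQ * lam_b
                    WJ = -0.5 * eQ * (lam_b + 2.0 * mu_b) / Jb
                    wb = 1.0 if is_hom else we
                    for i in range(3):
                        for j in range(3):
                            bb2 = 0.0
                            for m in range(3):
                                bb2 += B[i, m] * B[m, j]
                            sig[i, j] += wb * ((2.0 / Jb)
                                               * (W1 * B[i, j]
                                                  + W2 * (I1 * B[i, j] - bb2)))
                        sig[i, i] += wb * WJ
                    # fiber families
                    for fidx in range(n_fam):
                        lam_n2 = 0.0
                        for i in range(3):
                            s = 0.0
                            for j in range(3):
                                s += Fb[i, j] * dirs[e, fidx, j]
                            v[i] = s
                            lam_n2 += s * s
                        lam_n = np.sqrt(lam_n2)
                        if lam_n > 1.0:
                            if lam_n <= lam0:
                                t = (2.0 * gamma * xi * lam_n
                                     * (lam_n2 - 1.0) ** (gamma - 1.0))
                            else:
                                t = t0_fib + E_lin * (lam_n - lam0)
                            coef = wb * fam_w[fidx] * t / (lam_n * Jb)
                            for i in range(3):
                                for j in range(3):
                                    sig[i, j] += coef * v[i] * v[j]

                if not is_hom and we < 1.0:
                    # neo-Hookean matrix
                    wm = 1.0 - we
                    for i in range(3):
                        for j in range(3):
                            sig[i, j] += wm * (mu_m / Jb) * B[i, j]
                        sig[i, i] += wm * ((lam_m * lnJ - mu_m) / Jb)

                # Donnan osmotic pressure (charged constituent weight)
                if swell > 0.0 and cF0 != 0.0:
                    w_chg = 1.0 if is_hom else (1.0 - we)
                    if w_chg > 0.0:
                        if Jb <= phi0:
                            return 1
                        if cF_evolving:
                            cF = cF0 * (1.0 - phi0) / (Jb - phi0)
                        else:
                            cF = cF0
                        pi = piRT * (np.sqrt(cF * cF + 4.0 * c_ext * c_ext)
                                     - 2.0 * c_ext)
                        for i in range(3):
                            sig[i, i] -= swell * w_chg * pi

                _inv3(Fb, Fbi)
                for i in range(3):
                    for j in range(3):
                        s = 0.0
                        for m in range(3):
                            s += sig[i, m] * Fbi[j, m]
                        P[i, j] = Jb * s
                for a in range(8):
                    for i in range(3):
                        s = 0.0
                        for j in range(3):
                            s += P[i, j] * dN[p, a, j]
                        forces[e, k, a, i] += w_gp * s
    return 0
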