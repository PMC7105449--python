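"""Small dense Newton solver with finite-difference Jacobian."""

from __future__ import annotations

import numpy as np


class NonConvergenceError(RuntimeError):
    def __init__(self, msg, residual_norm=None, last_x=None):
        super().__init__(msg)
        self.residual_norm = residual_norm
        self.last_x = last_x


def fd_jacobian(fun, x, f0=None, h=1e-7):
    x = np.asarray(x, dtype=float)
    if f0 is None:
        f0 = np.asarray(fun(x), dtype=float)
    J = np.empty((f0.size, x.size))
    for k in range(x.size):
        step = h * max(1.0, abs(x[k]))
        xp = x.copy()
        xp[k] += step
        J[:, k] = (np.asarray(fun(xp)) - f0) / step
    return J, f0


def newton_solve(fun, x0, tol=1e-8, max_iter=50, damping=True):
    """Solve fun(x) = 0; returns (x, iterations).  Raises NonConvergenceError."""
    x = np.asarray(x0, dtype=float).copy()
    f = np.asarray(fun(x), dtype=float)
    if x.size == 0:
        return x, 0
    for it in range(max_iter):
        nrm = np.linalg.norm(f, ord=np.inf)
        if nrm < tol:
            return x, it
        J, _ = fd_jacobian(fun, x, f0=f)
        try:
            dx = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError as exc:
            raise NonConvergenceError(f"singular Jacobian: {exc}",
                                      residual_norm=nrm, last_x=x) from exc
        if damping:
            alpha = 1.0
            for _ in range(12):
                try:
                    f_new = np.asarray(fun(x + alpha * dx), dtype=float)
                except (ValueError, FloatingPointError):
                    alpha *= 0.5
                    continue
                if np.all(np.isfinite(f_new)) and (
                    np.linalg.norm(f_new, ord=np.inf) < nrm or alpha < 1.0 - 1e-12
                ):
                    break
                alpha *= 0.5
            else:
                raise NonConvergenceError("line search failed",
                                          residual_norm=nrm, last_x=x)
            x = x + alpha * dx
            f = f_new
        else:
            x = x + dx
            f = np.asarray(fun(x), dtype=float)
    nrm = float(np.linalg.norm(f, ord=np.inf))
    if nrm < tol:
        return x, max_iter
    raise NonConvergenceError(
        f"Newton did not converge in {max_iter} iterations (residual {nrm:.3e})",
        residual_norm=nrm, last_x=x)
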