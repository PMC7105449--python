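"""Specimen-geometry study: length x width sweep, regression, importance.

Uniaxial circumferential tension of multi-lamellar SEP specimens is
simulated over a grid of specimen lengths and widths; the linear-region
modulus of each geometry feeds a log-transformed multivariate regression

    log10(modulus) = b0 + b1 log10(length) + b2 (1/width) + b3 AR

with the aspect ratio AR = length/width entering as the interaction of
length and 1/width.  Statistically insignificant terms (p > 0.05) are
removed and the model refit.  Relative importance of the regressors is the
LMG decomposition: the average over all regressor orderings of the
sequential R^2 increments, normalized to 100%.

The sweep runs on the finite element path (gripped-type end constraint):
geometry effects are boundary-layer phenomena a laminate model cannot
express.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .materials import Environment
from .microstructure import LamellaSpec, SpecimenSpec, build_voxel_model
from .protocols import LoadCase, extract_moduli, run_experiment
from .solvers.fe import BoundaryCondition

__all__ = ["SweepResult", "RegressionResult", "run_sweep",
           "fit_geometry_regression", "relative_importance"]

log = logging.getLogger("afcomp.geometry")


@dataclass
class SweepResult:
    table: pd.DataFrame          # length, width, aspect_ratio, modulus_MPa
    failures: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)


def run_sweep(lengths, widths, lamella: LamellaSpec | None = None,
              n_lamellae: int = 3, resolution: float = 0.2,
              strain: float = 0.20, increments: int = 20,
              clamp: str = "full", env: Environment | None = None,
              solver_path: str = "fe") -> SweepResult:
    """One gripped circumferential uniaxial modulus per (length, width).

    Individual solve failures are recorded and the sweep continues.
    """
    if solver_path != "fe":
        raise ValueError("the geometry sweep requires the FE path "
                         "(end effects drive the geometry dependence)")
    lamella = lamella or LamellaSpec()
    env = env or Environment()
    rows, failures = [], []
    for L, W in itertools.product(lengths, widths):
        spec = SpecimenSpec(length=float(L), width=float(W),
                            n_lamellae=n_lamellae,
                            orientation="circumferential", model_family="SEP")
        lc = LoadCase(modality="uniaxial", direction="circumferential",
                      strain_target=strain,
                      bc=BoundaryCondition("gripped", clamp))
        try:
            curve = run_experiment(spec, lamella, lc, solver_path="fe",
                                   resolution=resolution,
                                   increments=increments, env=env)
            rep = extract_moduli(curve["strain_x"].to_numpy(),
                                 curve["stress_x"].to_numpy())
            rows.append((float(L), float(W), float(L) / float(W),
                         rep.linear_modulus))
            log.info("sweep L=%g W=%g -> E=%.3f MPa", L, W, rep.linear_modulus)
        except Exception as exc:   # noqa: BLE001 - per-row fault isolation
            failures.append({"length": float(L), "width": float(W),
                             "error": str(exc)})
            log.warning("sweep L=%g W=%g failed: %s", L, W, exc)
    table = pd.DataFrame(rows, columns=["length", "width", "aspect_ratio",
                                        "modulus_MPa"])
    return SweepResult(table=table, failures=failures,
                       meta=dict(resolution=resolution, strain=strain,
                                 increments=increments, clamp=clamp,
                                 n_lamellae=n_lamellae))


_REGRESSORS = ("log_length", "inv_width", "aspect_ratio")


def _design(table: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame({
        "log_length": np.log10(table["length"]),
        "inv_width": 1.0 / table["width"],
        "aspect_ratio": table["aspect_ratio"],
    })
    return X


@dataclass
class RegressionResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    retained: tuple
    r_squared: float
    response_transform: str
    importance: dict | None = None
    model: object = None

    def to_dict(self) -> dict:
        return {
            "params": {k: float(v) for k, v in self.params.items()},
            "std_errors": {k: float(v) for k, v in self.bse.items()},
            "pvalues": {k: float(v) for k, v in self.pvalues.items()},
            "retained": list(self.retained),
            "r_squared": float(self.r_squared),
            "response_transform": self.response_transform,
            "importance_percent": self.importance,
        }


def fit_geometry_regression(sweep: SweepResult | pd.DataFrame,
                            alpha: float = 0.05) -> RegressionResult:
    """OLS of log10(modulus) on {log10(length), 1/width, AR} with backward
    elimination at ``alpha``; raises on rank-deficient designs."""
    table = sweep.table if isinstance(sweep, SweepResult) else sweep
    if len(table) < 5:
        raise ValueError("need at least number-of-terms + 2 rows")
    y = np.log10(table["modulus_MPa"].to_numpy())
    X = _design(table)
    retained = list(_REGRESSORS)
    while True:
        Xc = sm.add_constant(X[retained], has_constant="add")
        if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
            raise ValueError("rank-deficient design (degenerate sweep grid)")
        fit = sm.OLS(y, Xc).fit()
        pv = fit.pvalues.drop("const").fillna(1.0)
        worst = pv.idxmax()
        if len(retained) > 1 and pv.max() > alpha:
            retained.remove(worst)
            continue
        if len(retained) == 1 and pv.max() > alpha:
            retained = []
            fit = sm.OLS(y, pd.DataFrame(
                {"const": np.ones(len(table))}, index=table.index)).fit()
        break
    return RegressionResult(params=fit.params, bse=fit.bse,
                            pvalues=fit.pvalues, retained=tuple(retained),
                            r_squared=float(fit.rsquared),
                            response_transform="log10", model=fit)


def relative_importance(fit: RegressionResult,
                        sweep: SweepResult | pd.DataFrame) -> dict:
    """LMG shares (%) of the retained regressors, summing to 100.

    For every ordering of the regressors, R^2 increments are attributed to
    each regressor as it enters; the share is the mean increment over all
    orderings, normalized by the full-model R^2.
    """
    table = sweep.table if isinstance(sweep, SweepResult) else sweep
    names = list(fit.retained)
    if len(names) < 1 or fit.r_squared <= 0:
        raise ValueError("need a fitted model with positive R^2")
    y = np.log10(table["modulus_MPa"].to_numpy())
    X = _design(table)

    def r2(subset):
        if not subset:
            return 0.0
        Xc = sm.add_constant(X[list(subset)], has_constant="add")
        return float(sm.OLS(y, Xc).fit().rsquared)

    cache = {}

    def r2c(subset):
        key = tuple(sorted(subset))
        if key not in cache:
            cache[key] = r2(key)
        return cache[key]

    shares = {n: 0.0 for n in names}
    orders = list(itertools.permutations(names))
    for order in orders:
        seen = []
        for n in order:
            before = r2c(seen)
            seen.append(n)
            shares[n] += r2c(seen) - before
    total = sum(shares.values())
    return {n: 100.0 * v / total for n, v in shares.items()}
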