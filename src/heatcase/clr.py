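"""Conditional logistic regression for matched case-crossover strata.

Each stratum holds one case day and its matched control days.  Conditioning
on one event per stratum cancels the stratum intercepts, leaving the
conditional likelihood

    l(theta) = sum_c [ x_case' theta - log sum_r exp(x_r' theta) ]

which is smooth, concave and low-dimensional; it is maximized by damped
Newton-Raphson with analytic gradient and Hessian.  Strata whose covariate
rows are constant contribute a theta-free term and are dropped (counted).
Degrees of freedom for the spline bases are chosen by minimum AIC over a
grid, mirroring standard practice for distributed-lag models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dlnm import CrossBasisSpec, build_cross_basis

logger = logging.getLogger(__name__)

__all__ = ["DesignData", "FitResult", "conditional_loglik", "fit_clr",
           "aic_grid_select"]


class DesignData:
    """Stratified design matrices, grouped by stratum size for vectorization.

    Built from a list of ``(case_row_index, X)`` pairs, one per stratum,
    where ``X`` has one row per day in the stratum.  Non-informative strata
    (every column constant within the stratum) are dropped and counted.
    """

    def __init__(self, strata: list[tuple[int, np.ndarray]]):
        if not strata:
            raise ValueError("no strata supplied")
        widths = {np.asarray(x).shape[1] for _, x in strata}
        if len(widths) != 1:
            raise ValueError(f"inconsistent column counts across strata: {widths}")
        self.n_params = widths.pop()
        groups: dict[int, tuple[list[int], list[np.ndarray]]] = {}
        self.n_dropped = 0
        for case_idx, x in strata:
            x = np.asarray(x, dtype=float)
            if x.shape[0] < 2:
                raise ValueError("stratum with fewer than 2 rows")
            if not (0 <= case_idx < x.shape[0]):
                raise ValueError(f"case index {case_idx} out of range")
            if np.ptp(x, axis=0).max(initial=0.0) == 0.0:
                self.n_dropped += 1
                continue
            cases, mats = groups.setdefault(x.shape[0], ([], []))
            cases.append(case_idx)
            mats.append(x)
        # size -> (case positions (m,), design stack (m, size, p))
        self.groups: dict[int, tuple[np.ndarray, np.ndarray]] = {
            s: (np.asarray(c), np.stack(m)) for s, (c, m) in groups.items()
        }
        self.n_strata = sum(len(c) for c, _ in self.groups.values())
        if self.n_dropped:
            logger.info("dropped %d non-informative strata", self.n_dropped)

    @classmethod
    def from_design_blocks(cls, stratum_ids, is_case, design: np.ndarray
                           ) -> "DesignData":
        """Assemble from long-format rows (stratum id, case flag, design row)."""
        sid = np.asarray(stratum_ids)
        case = np.asarray(is_case).astype(bool)
        design = np.asarray(design, dtype=float)
        order = np.argsort(sid, kind="stable")
        sid, case, design = sid[order], case[order], design[order]
        _, starts = np.unique(sid, return_index=True)
        strata = []
        bounds = np.append(starts, sid.size)
        for a, b in zip(bounds[:-1], bounds[1:]):
            c = np.flatnonzero(case[a:b])
            if c.size != 1:
                raise ValueError("each stratum must contain exactly one case row")
            strata.append((int(c[0]), design[a:b]))
        return cls(strata)


def conditional_loglik(theta, data: DesignData):
    """Stratified conditional log-likelihood with analytic gradient/Hessian.

    Returns ``(loglik, gradient, hessian)``; log-sum-exp is stabilized by
    subtracting the per-stratum row maximum.
    """
    theta = np.asarray(theta, dtype=float).ravel()
    if theta.size != data.n_params:
        raise ValueError(f"theta length {theta.size} != {data.n_params} columns")
    if not np.isfinite(theta).all():
        raise ValueError("non-finite theta")
    ll = 0.0
    grad = np.zeros(data.n_params)
    hess = np.zeros((data.n_params, data.n_params))
    for size, (case_pos, x3) in data.groups.items():
        eta = x3 @ theta                                  # (m, size)
        emax = eta.max(axis=1, keepdims=True)
        w = np.exp(eta - emax)
        z = w.sum(axis=1)
        lse = emax[:, 0] + np.log(z)
        m = np.arange(case_pos.size)
        ll += float(eta[m, case_pos].sum() - lse.sum())
        p = w / z[:, None]                                # (m, size)
        mu = np.einsum("ms,msp->mp", p, x3)               # (m, p)
        grad += x3[m, case_pos].sum(axis=0) - mu.sum(axis=0)
        e2 = np.einsum("ms,msp,msq->pq", p, x3, x3)
        hess -= e2 - mu.T @ mu
    return ll, grad, hess


@dataclass
class FitResult:
    """Maximum conditional likelihood fit.

    ``covariance`` is the inverse observed information at the optimum;
    ``aic = -2 loglik + 2 k`` with ``k`` the coefficient count.
    """

    coefficients: np.ndarray | None
    covariance: np.ndarray | None
    log_likelihood: float
    aic: float
    n_strata: int
    converged: bool
    iterations: int
    n_dropped: int = 0
    message: str = ""

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


def fit_clr(data: DesignData, tol: float = 1e-8, max_iter: int = 50) -> FitResult:
    """Damped Newton-Raphson maximization of the conditional likelihood.

    Convergence when the max-norm of the gradient falls below ``tol``.
    Non-convergence and separation (diverging coefficients) are flagged on
    the result rather than raised.
    """
    if data.n_strata == 0:
        return FitResult(None, None, 0.0, 0.0, 0, False, 0,
                         n_dropped=data.n_dropped,
                         message="no informative strata; coefficients undefined")
    p = data.n_params
    theta = np.zeros(p)
    ll, grad, hess = conditional_loglik(theta, data)
    converged, msg, it = False, "", 0
    for it in range(1, max_iter + 1):
        if np.abs(grad).max() < tol:
            converged = True
            it -= 1
            break
        try:
            step = np.linalg.solve(-hess + 1e-12 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            msg = "singular information matrix"
            break
        # step-halving to guarantee ascent
        alpha = 1.0
        for _ in range(30):
            cand = theta + alpha * step
            ll_new, grad_new, hess_new = conditional_loglik(cand, data)
            if ll_new >= ll - 1e-12:
                break
            alpha /= 2.0
        theta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.linalg.norm(theta) > 1e3:
            msg = "possible separation: coefficients diverging"
            break
    else:
        msg = f"no convergence in {max_iter} iterations"
    if not converged and not msg:
        if np.abs(grad).max() < tol:
            converged = True
        else:
            msg = f"no convergence in {max_iter} iterations"
    try:
        cov = np.linalg.inv(-hess)
        cov = (cov + cov.T) / 2.0
    except np.linalg.LinAlgError:
        cov, converged = None, False
        msg = msg or "information matrix not invertible at optimum"
    aic = -2.0 * ll + 2.0 * p
    return FitResult(theta, cov, ll, aic, data.n_strata, converged, it,
                     n_dropped=data.n_dropped, message=msg)


def _stack_design(strata, specs: list[CrossBasisSpec]) -> DesignData:
    """Cross-basis design for a StrataSet: temperature block, then RH block."""
    blocks = []
    lagged = [strata.lag_temperature, strata.lag_rh]
    for spec, lag in zip(specs, lagged):
        blocks.append(build_cross_basis(lag, spec).values)
    design = np.hstack(blocks)
    return DesignData.from_design_blocks(strata.row_stratum, strata.row_is_case,
                                         design)


def fit_strata(strata, temp_spec: CrossBasisSpec,
               rh_spec: CrossBasisSpec | None = None, **kw) -> FitResult:
    """Fit the conditional-logistic DLNM for one stratum set.

    The design is the temperature cross-basis, optionally followed by a
    relative-humidity cross-basis of the same structure.
    """
    specs = [temp_spec] + ([rh_spec] if rh_spec is not None else [])
    if rh_spec is None:
        block = build_cross_basis(strata.lag_temperature, temp_spec).values
        data = DesignData.from_design_blocks(strata.row_stratum,
                                             strata.row_is_case, block)
    else:
        data = _stack_design(strata, specs)
    return fit_clr(data, **kw)


def aic_grid_select(strata, var_df_grid=(3, 4), lag_df_grid=(2, 3, 4, 5),
                    max_lag: int = 6, include_rh: bool = True,
                    reference_value: float | None = None):
    """Fit every (df_var, df_lag) combination and select by minimum AIC.

    All fits share the same strata.  Non-converged fits are recorded in the
    table but excluded from the argmin.  AIC ties closer than 1e-6 resolve
    to the smaller total df (parsimony).

    Returns ``(best_var_df, best_lag_df, table)`` where ``table`` is a
    DataFrame with one row per combination.
    """
    if not len(var_df_grid) or not len(lag_df_grid):
        raise ValueError("df grids must be non-empty")
    rows = []
    fits = {}
    for var_df in var_df_grid:
        for lag_df in lag_df_grid:
            t_spec = CrossBasisSpec.from_exposure(
                strata.lag_temperature, var_df, max_lag, lag_df,
                reference_value)
            rh_spec = (CrossBasisSpec.from_exposure(
                strata.lag_rh, var_df, max_lag, lag_df) if include_rh else None)
            fit = fit_strata(strata, t_spec, rh_spec)
            fits[(var_df, lag_df)] = fit
            rows.append({"var_df": var_df, "lag_df": lag_df,
                         "n_params": var_df * lag_df * (2 if include_rh else 1),
                         "log_likelihood": fit.log_likelihood,
                         "aic": fit.aic, "converged": fit.converged})
            if not fit.converged:
                logger.warning("fit (var_df=%d, lag_df=%d) did not converge: %s",
                               var_df, lag_df, fit.message)
    table = pd.DataFrame(rows)
    ok = table[table["converged"]]
    if ok.empty:
        raise RuntimeError("no converged fits in the AIC grid")
    best_aic = ok["aic"].min()
    near = ok[ok["aic"] <= best_aic + 1e-6].copy()
    near["total_df"] = near["var_df"] + near["lag_df"]
    pick = near.sort_values(["total_df", "var_df", "lag_df"]).iloc[0]
    return int(pick["var_df"]), int(pick["lag_df"]), table
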