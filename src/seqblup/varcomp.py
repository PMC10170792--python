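"""REML estimation of genomic variance components and heritability.

Fits y ~ N(X beta, sum_k sigma2_k G_k + sigma2_e I) by average-
information (AI) REML with expectation-maximization fallback steps, for
one or two genomic components plus a residual.  The restricted
log-likelihood is exposed separately so independent oracles (e.g. grid
search) can share the objective definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .errors import ConfigurationError, DataError
from .grm import GRM

__all__ = ["VarianceEstimate", "restricted_loglik", "reml_fit", "h2_profile"]

_EM_ITERS = 3  # leading EM iterations before AI steps are attempted


@dataclass
class VarianceEstimate:
    """REML solution: variances, SEs, heritabilities, convergence record."""

    components: dict  # e.g. {"g1": .., "g2": .., "e": ..}
    standard_errors: dict
    h2: dict  # per-component fractions + "total"
    h2_se: dict
    loglik: float
    n_iterations: int
    converged: bool
    boundary: list = field(default_factory=list)  # components pinned at floor

    @property
    def total_h2(self) -> float:
        return self.h2["total"]


def _component_matrices(grms) -> list[np.ndarray]:
    out = []
    for g in grms:
        out.append(np.asarray(g.values if isinstance(g, GRM) else g, dtype=float))
    return out


def restricted_loglik(y, X, grms, variances) -> float:
    """Restricted log-likelihood (additive constant dropped).

    ``variances`` holds one entry per genomic component followed by the
    residual variance.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    Gs = _component_matrices(grms)
    variances = np.asarray(variances, dtype=float)
    if variances.size != len(Gs) + 1:
        raise ConfigurationError("need one variance per component plus residual")
    if (variances < 0).any() or variances.sum() <= 0:
        raise ConfigurationError("variances must be >= 0 with positive sum")
    n = y.size
    V = variances[-1] * np.eye(n)
    for s, G in zip(variances[:-1], Gs):
        V += s * G
    try:
        cho = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise DataError("covariance matrix V is singular") from exc
    logdet_v = 2.0 * np.sum(np.log(np.diag(cho[0])))
    Vi_X = cho_solve(cho, X)
    XtViX = X.T @ Vi_X
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise DataError("X' V^-1 X is not positive definite")
    Vi_y = cho_solve(cho, y)
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    ypy = float(y @ Vi_y - (X.T @ Vi_y) @ beta)
    return -0.5 * (logdet_v + logdet_x + ypy)


def _projection(V, X, y):
    """Return (P y, P, loglik pieces) for the current V."""
    cho = cho_factor(V, lower=True)
    Vinv = cho_solve(cho, np.eye(V.shape[0]))
    Vi_X = Vinv @ X
    XtViX = X.T @ Vi_X
    XtViX_inv = np.linalg.inv(XtViX)
    P = Vinv - Vi_X @ XtViX_inv @ Vi_X.T
    Py = P @ y
    logdet_v = 2.0 * np.sum(np.log(np.diag(cho[0])))
    sign, logdet_x = np.linalg.slogdet(XtViX)
    ll = -0.5 * (logdet_v + logdet_x + float(y @ Py))
    return Py, P, ll


def reml_fit(
    y,
    grms,
    covariates=None,
    max_iter: int = 100,
    tol_param: float = 1e-6,
    tol_loglik: float = 1e-8,
) -> VarianceEstimate:
    """AI-REML with EM fallback for 1-2 genomic components + residual.

    ``y`` must be aligned with the GRM sample order.  Fixed effects
    default to an intercept (phenotypes are expected to be pre-corrected
    upstream).  Negative variance proposals are truncated to a small
    positive floor; components stuck at the floor are reported as
    boundary estimates.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    Gs = _component_matrices(grms)
    for G in Gs:
        if G.shape != (n, n):
            raise DataError(f"GRM shape {G.shape} does not match n={n}")
    X = (
        np.ones((n, 1))
        if covariates is None
        else np.atleast_2d(np.asarray(covariates, dtype=float))
    )
    if X.shape[0] != n:
        X = X.T
    k = len(Gs)
    if n < k + X.shape[1] + 1:
        raise DataError("too few observations for the requested model")

    var_y = float(y.var(ddof=1)) if n > 1 else 1.0
    if var_y <= 0:
        raise DataError("phenotype has zero variance")
    floor = 1e-8 * var_y
    theta = np.full(k + 1, var_y / (k + 1))
    comps = Gs + [np.eye(n)]

    def build_v(th):
        V = th[-1] * np.eye(n)
        for s, G in zip(th[:-1], Gs):
            V += s * G
        return V

    Py, P, ll = _projection(build_v(theta), X, y)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        GPy = [G @ Py for G in comps]
        trPG = np.array([np.einsum("ij,ji->", P, G) for G in comps])
        yPGPy = np.array([float(Py @ g) for g in GPy])
        grad = -0.5 * (trPG - yPGPy)

        proj_new = None
        if it > _EM_ITERS:
            PGPy = [P @ g for g in GPy]
            AI = 0.5 * np.array(
                [[float(GPy[a] @ PGPy[b]) for b in range(k + 1)] for a in range(k + 1)]
            )
            try:
                step = np.linalg.solve(AI, grad)
                cand = np.maximum(theta + step, floor)
                proj = _projection(build_v(cand), X, y)
                if np.isfinite(proj[2]) and proj[2] >= ll - 1e-10:
                    theta_new, proj_new = cand, proj
            except np.linalg.LinAlgError:
                pass
        if proj_new is None:  # EM step (monotone, always safe)
            theta_new = np.maximum(
                theta + theta**2 / n * (yPGPy - trPG), floor
            )
            proj_new = _projection(build_v(theta_new), X, y)
        ll_new = proj_new[2]
        if not np.isfinite(ll_new):
            raise DataError(
                f"non-finite restricted likelihood at iteration {it}; "
                f"theta={theta_new}"
            )
        rel = np.max(np.abs(theta_new - theta) / np.maximum(theta, floor))
        dll = abs(ll_new - ll)
        theta = theta_new
        Py, P, ll = proj_new
        if rel < tol_param and dll < tol_loglik:
            converged = True
            break

    # AI matrix at the optimum for standard errors
    GPy = [G @ Py for G in comps]
    PGPy = [P @ g for g in GPy]
    AI = 0.5 * np.array(
        [[float(GPy[a] @ PGPy[b]) for b in range(k + 1)] for a in range(k + 1)]
    )
    try:
        cov = np.linalg.pinv(AI)
        ses = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        cov = np.full((k + 1, k + 1), np.nan)
        ses = np.full(k + 1, np.nan)

    names = [f"g{i + 1}" for i in range(k)] + ["e"]
    total = float(theta.sum())
    h2 = {names[i]: float(theta[i] / total) for i in range(k)}
    h2["total"] = float(theta[:k].sum() / total)
    # delta-method SEs for the variance ratios
    h2_se = {}
    for key, num_idx in list({names[i]: [i] for i in range(k)}.items()) + [
        ("total", list(range(k)))
    ]:
        grad_h = np.empty(k + 1)
        num = theta[num_idx].sum()
        for j in range(k + 1):
            grad_h[j] = ((j in num_idx) * total - num) / total**2
        var_h = float(grad_h @ cov @ grad_h)
        h2_se[key] = float(np.sqrt(max(var_h, 0.0)))

    boundary = [names[i] for i in range(k + 1) if theta[i] <= floor * (1 + 1e-6)]
    return VarianceEstimate(
        components=dict(zip(names, map(float, theta))),
        standard_errors=dict(zip(names, map(float, ses))),
        h2=h2,
        h2_se=h2_se,
        loglik=float(ll),
        n_iterations=it,
        converged=converged,
        boundary=boundary,
    )


def h2_profile(y, grms_by_panel: dict) -> pd.DataFrame:
    """reml_fit per panel label; percent change vs the first panel.

    Panels are processed in mapping order (callers order labels by
    density).  A failing fit flags its row instead of dropping it.
    """
    rows = []
    base_h2 = None
    for label, grm in grms_by_panel.items():
        try:
            est = reml_fit(y, [grm])
            h2, se, err = est.total_h2, est.h2_se["total"], ""
        except Exception as exc:  # keep the row, flag the failure
            h2, se, err = np.nan, np.nan, str(exc)
        if base_h2 is None and np.isfinite(h2):
            base_h2 = h2
        pct = (
            100.0 * (h2 - base_h2) / base_h2
            if base_h2 and np.isfinite(h2)
            else np.nan
        )
        rows.append(
            {
                "panel": label,
                "h2": h2,
                "se": se,
                "pct_change_vs_base": round(pct, 2) if np.isfinite(pct) else pct,
                "error": err,
            }
        )
    return pd.DataFrame(rows)
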