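"""Weighted generalized estimating equations, identity link.

Solves ``sum_i X_i' V_i^{-1} W_i (y_i - X_i beta) = 0`` by Fisher
scoring with an AR(1) or independence working correlation, a weighted
lag-1 moment estimator for the correlation parameter, and the robust
sandwich covariance with per-cluster weighted scores.  Clusters are
grouped by size so the per-iteration algebra is fully vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["GeeFit", "fit_weighted_gee", "wald_ci"]


@dataclass
class GeeFit:
    beta: np.ndarray
    names: list[str]
    robust_cov: np.ndarray
    ar1_alpha: float
    scale: float
    n_clusters: int
    converged: bool
    n_iter: int

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def robust_se(self, name: str) -> float:
        k = self.names.index(name)
        return float(np.sqrt(self.robust_cov[k, k]))

    def summary(self) -> "np.ndarray":
        import pandas as pd

        se = np.sqrt(np.diag(self.robust_cov))
        return pd.DataFrame(
            {"estimate": self.beta, "robust_se": se}, index=self.names
        )


def _ar1_inverse(alpha: float, size: int) -> np.ndarray:
    """Closed-form inverse of the AR(1) correlation matrix."""
    if size == 1 or alpha == 0.0:
        return np.eye(size)
    inv = np.zeros((size, size))
    c = 1.0 / (1.0 - alpha * alpha)
    diag = np.full(size, (1.0 + alpha * alpha) * c)
    diag[0] = diag[-1] = c
    np.fill_diagonal(inv, diag)
    off = -alpha * c
    idx = np.arange(size - 1)
    inv[idx, idx + 1] = off
    inv[idx + 1, idx] = off
    return inv


def _group_by_size(clusters: np.ndarray):
    """Yield (indices (g, s),) row-index blocks for clusters of equal size."""
    uniq, starts, counts = np.unique(clusters, return_index=True, return_counts=True)
    order = np.argsort(starts)
    starts, counts = starts[order], counts[order]
    groups: dict[int, list[np.ndarray]] = {}
    for st, ct in zip(starts, counts):
        groups.setdefault(int(ct), []).append(np.arange(st, st + ct))
    return {s: np.array(rows) for s, rows in groups.items()}


def fit_weighted_gee(
    y: np.ndarray,
    X: np.ndarray,
    clusters: np.ndarray,
    weights: np.ndarray | None = None,
    corr: str = "ar1",
    names: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> GeeFit:
    """Fit the weighted GEE on long-format arrays.

    Rows must be sorted by cluster with within-cluster time order; the
    AR(1) lag runs over consecutive retained rows within a cluster.
    Weights enter both the estimating equation and the sandwich meat;
    rescaling all weights by a positive constant leaves the fit
    unchanged.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    clusters = np.asarray(clusters)
    m, p = X.shape
    if corr not in ("ar1", "independence"):
        raise ValueError(f"unknown correlation structure {corr!r}")
    if weights is None:
        weights = np.ones(m)
    weights = np.asarray(weights, dtype=float)
    if names is None:
        names = [f"b{k}" for k in range(p)]
    # enforce contiguous cluster blocks (stable, preserves time order)
    order = np.argsort(clusters, kind="stable")
    y, X, clusters, weights = y[order], X[order], clusters[order], weights[order]
    n_clusters = len(np.unique(clusters))
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters")

    size_groups = _group_by_size(clusters)
    # consecutive within-cluster pairs for the lag-1 moment estimator
    pair_lo = np.concatenate(
        [rows[:, :-1].ravel() for s, rows in size_groups.items() if s > 1]
        or [np.empty(0, dtype=int)]
    )
    pair_hi = pair_lo + 1

    beta = np.linalg.lstsq(X, y, rcond=None)[0]  # OLS start
    alpha = 0.0
    scale = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        r = y - X @ beta
        scale = float(np.sum(weights * r * r) / np.sum(weights))
        if corr == "ar1" and len(pair_lo) and scale > 0:
            e = r / np.sqrt(scale)
            wp = np.sqrt(weights[pair_lo] * weights[pair_hi])
            denom = float(np.sum(wp))
            alpha = float(np.sum(wp * e[pair_lo] * e[pair_hi]) / denom) if denom > 0 else 0.0
            alpha = float(np.clip(alpha, -0.99, 0.99))
        else:
            alpha = 0.0

        A = np.zeros((p, p))
        bvec = np.zeros(p)
        for s, rows in size_groups.items():
            Rinv = _ar1_inverse(alpha, s)
            Xg = X[rows]  # (g, s, p)
            wg = weights[rows]  # (g, s)
            yg = y[rows]
            RinvWy = (wg * yg) @ Rinv
            bvec += np.einsum("gsp,gs->p", Xg, RinvWy)
            WX = Xg * wg[:, :, None]
            RinvWX = np.einsum("st,gtp->gsp", Rinv, WX)
            A += np.einsum("gsp,gsq->pq", Xg, RinvWX)
        beta_new = np.linalg.solve(A, bvec)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new

    # robust sandwich at the final beta
    r = y - X @ beta
    A = np.zeros((p, p))
    meat = np.zeros((p, p))
    for s, rows in size_groups.items():
        Rinv = _ar1_inverse(alpha, s)
        Xg = X[rows]
        wg = weights[rows]
        rg = r[rows]
        WX = Xg * wg[:, :, None]
        RinvWX = np.einsum("st,gtp->gsp", Rinv, WX)
        A += np.einsum("gsp,gsq->pq", Xg, RinvWX)
        RinvWr = (wg * rg) @ Rinv
        U = np.einsum("gsp,gs->gp", Xg, RinvWr)
        meat += U.T @ U
    Ainv = np.linalg.inv(A)
    cov = Ainv @ meat @ Ainv.T
    cov = 0.5 * (cov + cov.T)
    return GeeFit(
        beta=beta,
        names=list(names),
        robust_cov=cov,
        ar1_alpha=float(alpha),
        scale=scale,
        n_clusters=n_clusters,
        converged=converged,
        n_iter=it,
    )


def wald_ci(fit: GeeFit, coef: str, level: float = 0.95) -> tuple[float, float]:
    """Robust Wald confidence interval for one coefficient."""
    if coef not in fit.names:
        raise ValueError(f"unknown coefficient {coef!r}")
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    est = fit.coef(coef)
    se = fit.robust_se(coef)
    return (est - z * se, est + z * se)
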