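"""Pooled logistic propensity models and stabilized cumulative weights.

Treatment and visit models are fitted by pooled logistic regression over
all person-intervals.  Stabilized weights are cumulative products over
intervals of numerator/denominator probabilities of the *observed*
binary value.  Numerator ("stabilizing") specifications exclude the
time-dependent covariates from the denominator specification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dgm import Panel, expit

__all__ = [
    "PooledLogisticFit",
    "WeightSet",
    "DegenerateFitError",
    "PositivityError",
    "TREATMENT_DENOMINATOR",
    "TREATMENT_NUMERATOR",
    "VISIT_DENOMINATOR",
    "VISIT_NUMERATOR",
    "build_history_terms",
    "fit_pooled_logistic",
    "stabilized_weights",
    "product_weights",
    "truncate_weights",
    "write_weights_csv",
]

# Default history specifications.  Denominators mirror the conditional
# data-generating models; numerators drop the time-dependent covariates
# (current/lagged confounder and the carried-forward outcome).
TREATMENT_DENOMINATOR = ("v_lag", "last_y", "l_cur", "a_lag", "x1", "x2", "x3")
TREATMENT_NUMERATOR = ("v_lag", "a_lag", "x1", "x2", "x3")
VISIT_DENOMINATOR = ("last_y_prev", "l_lag", "x1", "x2", "x3", "v_lag")
VISIT_NUMERATOR = ("v_lag", "x1", "x2", "x3")


class DegenerateFitError(ValueError):
    """Raised when the modelled event takes a single value."""


class PositivityError(ValueError):
    """Raised when a denominator probability is numerically 0 or 1."""


@dataclass(eq=False)
class PooledLogisticFit:
    """Maximum-likelihood pooled logistic fit over person-intervals."""

    coefficients: pd.Series
    fitted_probabilities: np.ndarray  # (n, t) probability the event equals 1
    regressor_spec: tuple[str, ...]
    converged: bool
    separation_flagged: bool
    n_iter: int
    max_score: float
    modelled: np.ndarray | None = None  # (n, t) cells the likelihood covers

    def prob_observed(self, event_matrix: np.ndarray) -> np.ndarray:
        """Probability of the observed 0/1 value at each cell."""
        p = self.fitted_probabilities
        return np.where(event_matrix == 1, p, 1.0 - p)


@dataclass(eq=False)
class WeightSet:
    """Per-(subject, interval) stabilized cumulative-product weights."""

    sw: np.ndarray  # (n, t), strictly positive
    kind: str  # "treatment" | "visit" | "product"
    numerator_fit: PooledLogisticFit | None = None
    denominator_fit: PooledLogisticFit | None = None
    ratios: np.ndarray | None = None  # per-interval numerator/denominator ratio

    def __post_init__(self) -> None:
        if self.kind not in ("treatment", "visit", "product"):
            raise ValueError(f"unknown weight kind {self.kind!r}")
        if np.any(self.sw <= 0):
            raise ValueError("stabilized weights must be strictly positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.sw.shape

    def scaled(self, factor: np.ndarray, kind: str | None = None) -> "WeightSet":
        return WeightSet(
            sw=self.sw * factor,
            kind=kind or self.kind,
            numerator_fit=self.numerator_fit,
            denominator_fit=self.denominator_fit,
        )


def _lag(mat: np.ndarray) -> np.ndarray:
    out = np.zeros_like(np.asarray(mat, dtype=float))
    out[:, 1:] = mat[:, :-1]
    return out


def _carry_forward_outcome(Y_obs: np.ndarray, include_current: bool) -> np.ndarray:
    """Most recently observed outcome, carried forward (0 before first).

    ``include_current=True`` lets the current interval's outcome (when
    observed) enter the value at that interval, matching the treatment
    model which conditions on the current outcome; ``False`` uses the
    history through the previous interval, as the visit model must.
    """
    n, t = Y_obs.shape
    last = np.zeros((n, t))
    current = np.zeros(n)
    for j in range(t):
        if include_current:
            obs = ~np.isnan(Y_obs[:, j])
            current = np.where(obs, Y_obs[:, j], current)
            last[:, j] = current
        else:
            last[:, j] = current
            obs = ~np.isnan(Y_obs[:, j])
            current = np.where(obs, Y_obs[:, j], current)
    return last


def build_history_terms(
    V: np.ndarray,
    A: np.ndarray,
    L: np.ndarray,
    Y_obs: np.ndarray,
    X: np.ndarray,
    extra: dict[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Named (n, t) regressor arrays computable from observed history."""
    n, t = V.shape
    terms = {
        "const": np.ones((n, t)),
        "v_lag": _lag(V),
        "a_lag": _lag(A),
        "l_lag": _lag(L),
        "l_cur": np.asarray(L, dtype=float),
        "last_y": _carry_forward_outcome(Y_obs, include_current=True),
        "last_y_prev": _carry_forward_outcome(Y_obs, include_current=False),
        "x1": np.broadcast_to(X[:, 0][:, None], (n, t)).copy(),
        "x2": np.broadcast_to(X[:, 1][:, None], (n, t)).copy(),
        "x3": np.broadcast_to(X[:, 2][:, None], (n, t)).copy(),
    }
    if extra:
        terms.update({k: np.asarray(v, dtype=float) for k, v in extra.items()})
    return terms


def panel_history_terms(panel: Panel) -> dict[str, np.ndarray]:
    return build_history_terms(panel.V, panel.A, panel.L, panel.Y_obs, panel.X)


def _irls_logistic(
    y: np.ndarray, Xd: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> tuple[np.ndarray, bool, int]:
    """Newton-Raphson (IRLS) for logistic regression; returns (beta, converged, iters)."""
    n, p = Xd.shape
    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lin = Xd @ beta
        prob = expit(lin)
        w = prob * (1.0 - prob)
        w = np.maximum(w, 1e-12)
        grad = Xd.T @ (y - prob)
        hess = (Xd * w[:, None]).T @ Xd
        hess[np.diag_indices_from(hess)] += 1e-10  # guard near-separation
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    return beta, converged, it


def fit_pooled_logistic(
    panel: Panel,
    event: str,
    regressor_spec=None,
    terms: dict[str, np.ndarray] | None = None,
    event_matrix: np.ndarray | None = None,
    modelled: np.ndarray | None = None,
) -> PooledLogisticFit:
    """Fit a pooled logistic model for the treatment or visit process.

    The likelihood pools the person-intervals where the event is
    actually modelled (``modelled`` mask, default all cells).  Treatment
    is only drawn at visit intervals — at non-visits it continues
    deterministically — so treatment models are fitted on visit cells by
    default (see :func:`stabilized_weights`).  Fitted probabilities are
    still evaluated at every cell.  An intercept is always included.
    """
    if event_matrix is None:
        if event == "treatment":
            event_matrix = panel.A
        elif event == "visit":
            event_matrix = panel.V
        else:
            raise ValueError(f"unknown event {event!r}")
    if regressor_spec is None:
        regressor_spec = (
            TREATMENT_DENOMINATOR if event == "treatment" else VISIT_DENOMINATOR
        )
    regressor_spec = tuple(regressor_spec)
    if terms is None:
        terms = panel_history_terms(panel)

    n, t = event_matrix.shape
    if n * t == 0:
        raise ValueError("empty panel")
    if modelled is None:
        modelled = np.ones((n, t), dtype=bool)
    mask = np.asarray(modelled, dtype=bool).ravel()
    if mask.sum() == 0:
        raise ValueError("no modelled cells")
    y = np.asarray(event_matrix, dtype=float).ravel()
    if np.all(y[mask] == y[mask][0]):
        raise DegenerateFitError(f"{event} takes the constant value {y[mask][0]:g}")
    names = ("const",) + regressor_spec
    Xd = np.column_stack([terms[name].ravel() for name in names])

    beta, converged, n_iter = _irls_logistic(y[mask], Xd[mask])
    prob = expit(Xd @ beta)
    max_score = float(np.max(np.abs(Xd[mask].T @ (y[mask] - prob[mask]))))
    separation = (not converged) or np.max(np.abs(beta)) > 30.0
    return PooledLogisticFit(
        coefficients=pd.Series(beta, index=list(names)),
        fitted_probabilities=prob.reshape(n, t),
        regressor_spec=regressor_spec,
        converged=converged and not separation,
        separation_flagged=bool(separation),
        n_iter=n_iter,
        max_score=max_score,
        modelled=mask.reshape(n, t),
    )


def stabilized_weights(
    panel: Panel,
    event: str,
    numerator_spec=None,
    denominator_spec=None,
    terms: dict[str, np.ndarray] | None = None,
    event_matrix: np.ndarray | None = None,
    fit_scope: str | None = None,
) -> WeightSet:
    """Cumulative-product stabilized weights for one event process.

    ``sw[i, t] = prod_{j<=t} p_num(observed event_ij) / p_den(observed
    event_ij)``, with probabilities of the observed binary value.
    ``fit_scope='visit'`` (the treatment default) fits the models on
    visit cells only and contributes a ratio of one at non-visit cells,
    where the event value is deterministic carry-forward.
    """
    if event_matrix is None:
        event_matrix = panel.A if event == "treatment" else panel.V
    if numerator_spec is None:
        numerator_spec = TREATMENT_NUMERATOR if event == "treatment" else VISIT_NUMERATOR
    if denominator_spec is None:
        denominator_spec = (
            TREATMENT_DENOMINATOR if event == "treatment" else VISIT_DENOMINATOR
        )
    if terms is None:
        terms = panel_history_terms(panel)
    if fit_scope is None:
        fit_scope = "visit" if event == "treatment" else "all"
    if fit_scope not in ("visit", "all"):
        raise ValueError(f"unknown fit_scope {fit_scope!r}")
    modelled = (panel.V == 1) if fit_scope == "visit" else None

    num_fit = fit_pooled_logistic(
        panel, event, numerator_spec, terms=terms, event_matrix=event_matrix,
        modelled=modelled,
    )
    den_fit = fit_pooled_logistic(
        panel, event, denominator_spec, terms=terms, event_matrix=event_matrix,
        modelled=modelled,
    )

    p_num = num_fit.prob_observed(event_matrix)
    p_den = den_fit.prob_observed(event_matrix)
    eps = 1e-12
    mask = num_fit.modelled
    bad = ((p_den < eps) | (p_den > 1.0 - eps)) & mask
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise PositivityError(
            f"denominator probability numerically degenerate at subject {i + 1}, "
            f"interval {j + 1}"
        )
    ratios = np.where(mask, p_num / np.where(mask, p_den, 1.0), 1.0)
    sw = np.cumprod(ratios, axis=1)
    return WeightSet(
        sw=sw, kind=event, numerator_fit=num_fit, denominator_fit=den_fit, ratios=ratios
    )


def product_weights(parts) -> WeightSet:
    """Cellwise product of aligned weight sets (kind = 'product')."""
    parts = list(parts)
    if not parts:
        raise ValueError("need at least one WeightSet")
    shape = parts[0].shape
    for w in parts[1:]:
        if w.shape != shape:
            raise ValueError(f"misaligned weight sets: {w.shape} vs {shape}")
    sw = np.ones(shape)
    for w in parts:
        sw = sw * w.sw
    return WeightSet(sw=sw, kind="product")


def truncate_weights(w: WeightSet, lower_q: float, upper_q: float) -> WeightSet:
    """Winsorize weights at empirical quantiles of the pooled distribution."""
    if not 0.0 <= lower_q < upper_q <= 1.0:
        raise ValueError("need 0 <= lower_q < upper_q <= 1")
    lo = np.quantile(w.sw, lower_q)
    hi = np.quantile(w.sw, upper_q)
    return WeightSet(
        sw=np.clip(w.sw, lo, hi),
        kind=w.kind,
        numerator_fit=w.numerator_fit,
        denominator_fit=w.denominator_fit,
    )


def write_weights_csv(w: WeightSet, path: str | Path) -> None:
    n, t = w.shape
    frame = pd.DataFrame(
        {
            "id": np.repeat(np.arange(1, n + 1), t),
            "interval": np.tile(np.arange(1, t + 1), n),
            "weight": w.sw.ravel(),
            "kind": w.kind,
        }
    )
    frame.to_csv(path, index=False, float_format="%.17g")
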