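"""Exponential-tilting calibration of stabilized longitudinal weights.

The calibrated weights are ``sw * exp(K @ lambda)`` where each row of
``K`` belongs to one (subject, interval) cell and each column encodes
one moment restriction:

* balance columns — cumulative residual sums ``sum_{k<=j} (event_ik -
  e_ik) * basis_{i,k-1}``, weighted total constrained to 0;
* unity columns — interval indicators, weighted total constrained to n
  (mean calibrated weight one per interval);
* subject columns — per-subject cumulative residual sums, weighted
  total constrained to 0 for every subject (latent-confounder balance).

Solving the moment conditions in ``lambda`` is a convex problem (the
residual is the gradient of ``sum(b * exp(K lambda)) - targets @
lambda``); the primary solver is a Barzilai-Borwein spectral gradient
iteration with a non-monotone line search, with a quasi-Newton
root-finder fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .dgm import Panel, expit
from .propensity import WeightSet, _irls_logistic, panel_history_terms

__all__ = [
    "ConstraintSystem",
    "CalibrationResult",
    "build_balance_constraints",
    "build_unity_constraints",
    "build_subject_constraints",
    "assemble_system",
    "solve_lambda",
    "calibrate",
    "constraint_residuals",
    "calibration_report",
]

_CLIP = 50.0


@dataclass
class ConstraintSystem:
    """Moment conditions ``sum_cells b * exp(K row . lambda) * K col = target``."""

    K: np.ndarray  # (N, r)
    targets: np.ndarray  # (r,)
    base_weights: WeightSet
    residual_labels: list[str]

    @property
    def n_constraints(self) -> int:
        return self.K.shape[1]

    def residual(self, lam: np.ndarray, clip: bool = True) -> np.ndarray:
        b = self.base_weights.sw.ravel()
        z = self.K @ lam
        if clip:
            z = np.clip(z, -_CLIP, _CLIP)
        w = b * np.exp(z)
        return self.K.T @ w - self.targets

    def potential(self, lam: np.ndarray, clip: bool = True) -> float:
        b = self.base_weights.sw.ravel()
        z = self.K @ lam
        if clip:
            z = np.clip(z, -_CLIP, _CLIP)
        return float(np.sum(b * np.exp(z)) - self.targets @ lam)

    def jacobian(self, lam: np.ndarray) -> np.ndarray:
        b = self.base_weights.sw.ravel()
        z = np.clip(self.K @ lam, -_CLIP, _CLIP)
        w = b * np.exp(z)
        return (self.K * w[:, None]).T @ self.K


@dataclass
class CalibrationResult:
    lambda_: np.ndarray
    calibrated: WeightSet
    converged: bool
    residual_norm: float
    iterations: int
    system: ConstraintSystem
    message: str = ""


def build_balance_constraints(residuals: np.ndarray, covariate_basis: dict[str, np.ndarray]):
    """Population covariate-balance columns.

    ``residuals`` is the (n, t) matrix ``event - e_hat``;
    ``covariate_basis`` maps term name -> (n, t) array holding the
    *lagged* covariate value aligned at interval k (so the entry at
    column k is the basis evaluated at k-1).  The cell-(i, j) column
    entry is the cumulative inner sum over k <= j.
    """
    cols, labels = [], []
    for name, basis in covariate_basis.items():
        inner = residuals * basis
        cols.append(np.cumsum(inner, axis=1).ravel())
        labels.append(f"balance:{name}")
    return cols, labels


def build_unity_constraints(n_subjects: int, n_intervals: int):
    """Interval-indicator columns with target n (mean weight one per interval)."""
    cols, labels = [], []
    eye = np.eye(n_intervals)
    for j in range(n_intervals):
        cols.append(np.tile(eye[j], n_subjects))
        labels.append(f"unity:{j + 1}")
    return cols, labels


def subject_effect_propensities(
    event_matrix: np.ndarray,
    terms: dict[str, np.ndarray],
    regressor_spec,
    modelled: np.ndarray | None = None,
) -> np.ndarray:
    """Event probabilities from a model with per-subject intercepts.

    The latent-confounder balance restrictions need residuals whose
    per-subject sums vanish at the maximum likelihood estimate, which is
    the score property of subject-specific intercepts (the fitted
    analogue of the latent confounder).  Subjects with a constant event
    are the separated limit: their fitted probability is the observed
    value and their residuals are exactly zero.  Regressors constant
    within subject are absorbed by the intercepts and must not appear in
    ``regressor_spec``.
    """
    event = np.asarray(event_matrix, dtype=float)
    n, t = event.shape
    if modelled is None:
        modelled = np.ones((n, t), dtype=bool)
    e_hat = event.copy()  # degenerate/non-modelled cells: residual exactly zero
    counts = modelled.sum(axis=1)
    sums = np.where(modelled, event, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        keep_subject = (counts > 0) & (sums > 0) & (sums < counts)
    keep = np.flatnonzero(keep_subject)
    if len(keep) == 0:
        return e_hat
    cell_mask = modelled & keep_subject[:, None]
    ri, rj = np.nonzero(cell_mask)
    y = event[ri, rj]
    pos = {s: k for k, s in enumerate(keep)}
    dummies = np.zeros((len(y), len(keep)))
    dummies[np.arange(len(y)), [pos[s] for s in ri]] = 1.0
    blocks = [dummies] + [terms[name][ri, rj][:, None] for name in regressor_spec]
    Xd = np.hstack(blocks)
    beta, _, _ = _irls_logistic(y, Xd, max_iter=200)
    e_hat[ri, rj] = expit(Xd @ beta)
    return e_hat


def build_subject_constraints(residuals: np.ndarray):
    """Per-subject residual columns with target 0.

    The column for subject i carries that subject's per-interval
    residuals on its own cells and zeros elsewhere, so the constraint is
    a vanishing weighted residual sum for every subject.  A cumulative
    variant (inner sums over k <= j, mirroring the population balance
    columns) is attainable only by collapsing the weights of subjects
    whose cumulative residual path never changes sign, which degrades
    every weight in the panel; the per-interval form is the score of the
    subject-specific intercepts and admits interior solutions.
    """
    n, t = residuals.shape
    cols, labels = [], []
    for i in range(n):
        col = np.zeros((n, t))
        col[i] = residuals[i]
        cols.append(col.ravel())
        labels.append(f"subject:{i + 1}")
    return cols, labels


def assemble_system(
    base: WeightSet,
    panel: Panel,
    e_hat: np.ndarray,
    families=("balance", "unity"),
    covariate_basis: dict[str, np.ndarray] | None = None,
    event_matrix: np.ndarray | None = None,
    e_hat_subject: np.ndarray | None = None,
    modelled: np.ndarray | None = None,
) -> ConstraintSystem:
    """Build and prune the constraint system for one weight family.

    ``e_hat_subject`` supplies the propensities behind the per-subject
    latent restrictions (defaults to ``e_hat``).  Redundancy pruning:
    with subject constraints active the global intercept balance column
    is dropped, and any vacuous (all-zero) column is dropped.
    """
    families = tuple(families)
    unknown = set(families) - {"balance", "unity", "subject"}
    if unknown:
        raise ValueError(f"unknown constraint families: {sorted(unknown)}")
    if event_matrix is None:
        if base.kind == "treatment":
            event_matrix = panel.A
        elif base.kind == "visit":
            event_matrix = panel.V
        else:
            raise ValueError("event_matrix required for product weight calibration")
    residuals = np.asarray(event_matrix, dtype=float) - np.asarray(e_hat, dtype=float)
    if modelled is not None:
        residuals = residuals * np.asarray(modelled, dtype=float)
    n, t = residuals.shape

    if covariate_basis is None:
        terms = panel_history_terms(panel)
        covariate_basis = {"const": terms["const"], "l_lag": terms["l_lag"]}

    cols: list[np.ndarray] = []
    labels: list[str] = []
    targets: list[float] = []
    if "balance" in families:
        c, lab = build_balance_constraints(residuals, covariate_basis)
        cols += c
        labels += lab
        targets += [0.0] * len(c)
    if "unity" in families:
        c, lab = build_unity_constraints(n, t)
        cols += c
        labels += lab
        targets += [float(n)] * len(c)
    if "subject" in families:
        if e_hat_subject is None:
            subject_residuals = residuals
        else:
            subject_residuals = np.asarray(event_matrix, dtype=float) - np.asarray(
                e_hat_subject, dtype=float
            )
            if modelled is not None:
                subject_residuals = subject_residuals * np.asarray(modelled, dtype=float)
        c, lab = build_subject_constraints(subject_residuals)
        cols += c
        labels += lab
        targets += [0.0] * len(c)

    keep = []
    for idx, (col, lab) in enumerate(zip(cols, labels)):
        if np.max(np.abs(col)) < 1e-12:
            continue  # vacuous
        keep.append(idx)
    K = np.column_stack([cols[i] for i in keep]) if keep else np.zeros((n * t, 0))
    return ConstraintSystem(
        K=K,
        targets=np.array([targets[i] for i in keep]),
        base_weights=base,
        residual_labels=[labels[i] for i in keep],
    )


def solve_lambda(
    system: ConstraintSystem,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> CalibrationResult:
    """Solve the moment conditions by BB spectral iteration with fallback.

    Non-convergence (including exactly infeasible systems, which arise
    when a subject's cumulative residuals never change sign) is reported
    via ``converged=False``, never silently accepted.
    """
    r = system.n_constraints
    base_sw = system.base_weights.sw

    def _result(lam, converged, iters, msg=""):
        if converged and np.max(np.abs(system.K @ lam), initial=0.0) >= _CLIP:
            converged = False
            msg = "solution sits at the overflow clip"
        if np.all(lam == 0.0):
            sw = base_sw.copy()
        else:
            factor = np.exp(np.clip(system.K @ lam, -_CLIP, _CLIP)).reshape(base_sw.shape)
            sw = base_sw * factor
        calibrated = WeightSet(
            sw=sw,
            kind=system.base_weights.kind,
            numerator_fit=system.base_weights.numerator_fit,
            denominator_fit=system.base_weights.denominator_fit,
        )
        res = system.residual(lam)
        return CalibrationResult(
            lambda_=lam,
            calibrated=calibrated,
            converged=bool(converged),
            residual_norm=float(np.max(np.abs(res), initial=0.0)),
            iterations=iters,
            system=system,
            message=msg,
        )

    lam = np.zeros(r)
    if r == 0:
        return _result(lam, True, 0, "no active constraints")

    g = system.residual(lam)
    if np.max(np.abs(g)) <= tol:
        return _result(lam, True, 0)

    # Barzilai-Borwein spectral gradient descent on the convex potential,
    # non-monotone (GLL) line search over the last 10 accepted values.
    phi = system.potential(lam)
    history = [phi]
    tau = 1.0 / max(np.max(np.abs(g)), 1.0)
    gamma = 1e-4
    it = 0
    failed = False
    for it in range(1, max_iter + 1):
        gnorm2 = float(g @ g)
        step_ok = False
        tau_try = tau
        for _ in range(40):
            lam_new = lam - tau_try * g
            phi_new = system.potential(lam_new)
            if phi_new <= max(history) - gamma * tau_try * gnorm2:
                step_ok = True
                break
            tau_try *= 0.5
        if not step_ok:
            failed = True
            break
        g_new = system.residual(lam_new)
        s = lam_new - lam
        yv = g_new - g
        sy = float(s @ yv)
        if sy > 0:
            tau = min(max(float(s @ s) / sy, 1e-12), 1e12)
        else:
            tau = min(tau_try * 2.0, 1e12)
        lam, g, phi = lam_new, g_new, phi_new
        history.append(phi)
        if len(history) > 10:
            history.pop(0)
        if np.max(np.abs(g)) <= tol:
            return _result(lam, True, it)

    # fallback: quasi-Newton root solve from the best BB iterate
    sol = optimize.root(
        system.residual, lam, jac=system.jacobian, method="hybr", tol=tol * 1e-2
    )
    lam_fb = sol.x
    res_fb = system.residual(lam_fb)
    if np.max(np.abs(res_fb)) <= tol:
        return _result(lam_fb, True, it + int(sol.nfev), "fallback root solver")
    msg = "line search failed" if failed else "max_iter exceeded"
    best = lam_fb if np.max(np.abs(res_fb)) < np.max(np.abs(g)) else lam
    return _result(best, False, it, msg + "; fallback did not converge")


def calibrate(
    base: WeightSet,
    panel: Panel,
    fit=None,
    families=("balance", "unity"),
    covariate_basis: dict[str, np.ndarray] | None = None,
    event_matrix: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> CalibrationResult:
    """Calibrate one stabilized weight family.

    ``fit`` supplies the model-based propensities ``e_hat`` (defaults to
    the base weights' numerator fit, i.e. the model with the
    time-dependent covariate coefficients constrained to zero).  When
    the latent ("subject") family is active, the per-subject residuals
    come from the subject-intercept model so the restrictions are
    attainable near the stabilized weights.
    """
    if fit is None:
        fit = base.numerator_fit
    if fit is None:
        raise ValueError("need a PooledLogisticFit for the model-based propensities")
    if event_matrix is None:
        if base.kind == "treatment":
            event_matrix = panel.A
        elif base.kind == "visit":
            event_matrix = panel.V
        else:
            raise ValueError("event_matrix required for product weight calibration")
    e_hat_subject = None
    if "subject" in families:
        terms = panel_history_terms(panel)
        varying = [
            name
            for name in fit.regressor_spec
            if np.max(np.ptp(terms[name], axis=1)) > 0
        ]
        e_hat_subject = subject_effect_propensities(
            event_matrix, terms, varying, modelled=fit.modelled
        )
    system = assemble_system(
        base,
        panel,
        e_hat=fit.fitted_probabilities,
        families=families,
        covariate_basis=covariate_basis,
        event_matrix=event_matrix,
        e_hat_subject=e_hat_subject,
        modelled=fit.modelled,
    )
    return solve_lambda(system, tol=tol, max_iter=max_iter)


def constraint_residuals(system: ConstraintSystem, calibrated_sw: np.ndarray) -> np.ndarray:
    """Recompute every constraint residual directly from final weights.

    Independent of solver internals: plain weighted column totals minus
    targets.
    """
    w = np.asarray(calibrated_sw, dtype=float).ravel()
    return system.K.T @ w - system.targets


def calibration_report(result: CalibrationResult) -> dict:
    """JSON-ready diagnostics for one calibration run."""
    labels = result.system.residual_labels
    fams: dict[str, int] = {}
    for lab in labels:
        fam = lab.split(":", 1)[0]
        fams[fam] = fams.get(fam, 0) + 1
    res0 = result.system.residual(np.zeros(result.system.n_constraints))
    return {
        "converged": result.converged,
        "iterations": result.iterations,
        "message": result.message,
        "constraints_by_family": fams,
        "residual_norm_before": float(np.max(np.abs(res0), initial=0.0)),
        "residual_norm_after": result.residual_norm,
        "lambda_min": float(result.lambda_.min(initial=0.0)),
        "lambda_max": float(result.lambda_.max(initial=0.0)),
        "lambda_norm": float(np.linalg.norm(result.lambda_)),
    }
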