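"""Monte Carlo study orchestration and the application-style pipeline.

``run_scenario`` repeats panel simulation + weight construction +
weighted GEE across replicates and reduces the per-replicate effect
estimates to the study metrics (bias, relative bias, Monte Carlo error,
root mean square error, coverage, convergence counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CalibrationResult, calibrate
from .config import ScenarioConfig, scenario_config
from .dgm import Panel, baseline_transform, expit, simulate_panel
from .gee import GeeFit, fit_weighted_gee, wald_ci
from .propensity import (
    DegenerateFitError,
    WeightSet,
    build_history_terms,
    product_weights,
    stabilized_weights,
    truncate_weights,
)
from .truth import true_psi

__all__ = [
    "ESTIMATORS",
    "McSummary",
    "ReplicateEstimate",
    "default_estimators",
    "run_replicate",
    "summarize",
    "run_scenario",
    "summaries_to_frame",
    "simulate_two_exposure_panel",
    "run_application_pipeline",
]

ESTIMATORS = (
    "naive",
    "sIPTW",
    "sIPVW",
    "sIPTWxsIPVW",
    "cIPTW",
    "cIPVW",
    "cIPTWxcIPVW",
)

_NEEDS_TREATMENT = {"sIPTW", "sIPTWxsIPVW", "cIPTW", "cIPTWxcIPVW"}
_NEEDS_VISIT = {"sIPVW", "sIPTWxsIPVW", "cIPVW", "cIPTWxcIPVW"}
_NEEDS_CAL_T = {"cIPTW", "cIPTWxcIPVW"}
_NEEDS_CAL_V = {"cIPVW", "cIPTWxcIPVW"}


@dataclass(frozen=True)
class ReplicateEstimate:
    psi: float
    ci_low: float
    ci_high: float
    converged: bool


@dataclass(frozen=True)
class McSummary:
    """Per-estimator Monte Carlo performance metrics."""

    estimator: str
    psi_true: float
    mean_estimate: float
    bias: float
    relative_bias_pct: float
    mce: float
    rmse: float
    coverage: float
    n_converged: int
    n_replicates: int


def default_estimators(config: ScenarioConfig) -> tuple[str, ...]:
    """Estimator set matching the scenario (visit weights only when irregular)."""
    if config.irregular_visits:
        return ("naive", "sIPTW", "sIPVW", "sIPTWxsIPVW", "cIPTWxcIPVW")
    return ("naive", "sIPTW", "cIPTW")


def _msm_rows(panel: Panel, include_visit_lag: bool, burn_in: int = 1):
    """Long-format outcome rows (visited cells only) and the MSM design.

    The first ``burn_in`` intervals are excluded from the outcome model:
    the simulator's cold start (all lagged values zero before the first
    interval) makes the marginal model structurally misspecified there
    (lagged treatment is identically zero and the lagged confounder has
    not reached its stationary distribution).  Weights still cumulate
    from the first interval.
    """
    n, t = panel.n_subjects, panel.n_intervals
    obs = panel.V == 1
    if burn_in:
        obs = obs.copy()
        obs[:, :burn_in] = False
    subj, interval = np.nonzero(obs)
    y = panel.Y_obs[subj, interval]
    a_lag = np.where(interval > 0, panel.A[subj, np.maximum(interval - 1, 0)], 0)
    cols = [np.ones(len(y)), a_lag.astype(float)]
    names = ["const", "a_lag"]
    if include_visit_lag:
        v_lag = np.where(interval > 0, panel.V[subj, np.maximum(interval - 1, 0)], 0)
        cols.append(v_lag.astype(float))
        names.append("v_lag")
    cols += [panel.X[subj, 0], panel.X[subj, 1], panel.X[subj, 2]]
    names += ["x1", "x2", "x3"]
    return y, np.column_stack(cols), subj, interval, names


def run_replicate(
    config: ScenarioConfig,
    estimators=None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    burn_in: int = 1,
) -> dict[str, ReplicateEstimate]:
    """Simulate one panel and estimate the lagged-treatment effect.

    All requested estimators share the single simulated panel (paired
    comparison).  Calibration failures mark only the affected estimator
    as non-converged.
    """
    estimators = tuple(estimators) if estimators else default_estimators(config)
    unknown = set(estimators) - set(ESTIMATORS)
    if unknown:
        raise ValueError(f"unknown estimators: {sorted(unknown)}")
    if any(e in _NEEDS_VISIT for e in estimators) and not config.irregular_visits:
        raise ValueError("visit-weight estimators need irregular_visits=True")
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    panel = simulate_panel(config, rng)
    y, Xd, subj, interval, names = _msm_rows(panel, config.irregular_visits, burn_in)

    failed = "failed"  # sentinel for weight families that could not be built
    weights: dict[str, WeightSet | str] = {}

    def _safe(builder):
        try:
            return builder()
        except (DegenerateFitError, np.linalg.LinAlgError, ValueError):
            return failed

    families = ("balance", "unity", "subject") if config.unmeasured_confounder else (
        "balance",
        "unity",
    )
    sw_t = sw_v = None
    if any(e in _NEEDS_TREATMENT for e in estimators):
        sw_t = _safe(lambda: stabilized_weights(panel, "treatment"))
    if any(e in _NEEDS_VISIT for e in estimators):
        sw_v = _safe(lambda: stabilized_weights(panel, "visit"))
    cal_t = cal_v = None
    if any(e in _NEEDS_CAL_T for e in estimators) and sw_t not in (None, failed):
        cal_t = calibrate(sw_t, panel, families=families)
    if any(e in _NEEDS_CAL_V for e in estimators) and sw_v not in (None, failed):
        cal_v = calibrate(sw_v, panel, families=families)

    weights["naive"] = None
    weights["sIPTW"] = sw_t
    weights["sIPVW"] = sw_v
    if sw_t not in (None, failed) and sw_v not in (None, failed):
        weights["sIPTWxsIPVW"] = product_weights([sw_t, sw_v])
    else:
        weights["sIPTWxsIPVW"] = failed
    weights["cIPTW"] = cal_t.calibrated if cal_t is not None and cal_t.converged else failed
    weights["cIPVW"] = cal_v.calibrated if cal_v is not None and cal_v.converged else failed
    if (
        cal_t is not None
        and cal_v is not None
        and cal_t.converged
        and cal_v.converged
    ):
        weights["cIPTWxcIPVW"] = product_weights([cal_t.calibrated, cal_v.calibrated])
    else:
        weights["cIPTWxcIPVW"] = failed

    out: dict[str, ReplicateEstimate] = {}
    for est in estimators:
        wset = weights.get(est)
        if wset == failed:
            out[est] = ReplicateEstimate(np.nan, np.nan, np.nan, False)
            continue
        row_w = None if wset is None else wset.sw[subj, interval]
        try:
            fit = fit_weighted_gee(y, Xd, subj, weights=row_w, corr="ar1", names=names)
        except (np.linalg.LinAlgError, ValueError):
            out[est] = ReplicateEstimate(np.nan, np.nan, np.nan, False)
            continue
        lo, hi = wald_ci(fit, "a_lag", 0.95)
        out[est] = ReplicateEstimate(fit.coef("a_lag"), lo, hi, fit.converged)
    return out


def summarize(
    estimates,
    ci_lows,
    ci_highs,
    psi_true: float,
    estimator: str = "",
    n_replicates: int | None = None,
) -> McSummary:
    """Reduce converged replicate estimates to the study metrics.

    bias = mean(psi_hat) - psi_true; relative bias uses |psi_true| in the
    denominator; MCE is the replicate standard deviation; rMSE is
    sqrt(bias^2 + MCE^2); coverage is the fraction of confidence
    intervals containing psi_true.
    """
    psis = np.asarray(estimates, dtype=float)
    lo = np.asarray(ci_lows, dtype=float)
    hi = np.asarray(ci_highs, dtype=float)
    ok = np.isfinite(psis) & np.isfinite(lo) & np.isfinite(hi)
    psis, lo, hi = psis[ok], lo[ok], hi[ok]
    if len(psis) < 2:
        raise ValueError("need at least 2 converged replicates")
    if n_replicates is None:
        n_replicates = len(estimates)
    mean_est = float(psis.mean())
    bias = mean_est - psi_true
    rel = bias / abs(psi_true) * 100.0 if psi_true != 0 else np.nan
    mce = float(psis.std(ddof=1))
    rmse = float(np.sqrt(bias**2 + mce**2))
    coverage = float(np.mean((lo <= psi_true) & (psi_true <= hi)))
    return McSummary(
        estimator=estimator,
        psi_true=psi_true,
        mean_estimate=mean_est,
        bias=float(bias),
        relative_bias_pct=float(rel),
        mce=mce,
        rmse=rmse,
        coverage=coverage,
        n_converged=int(len(psis)),
        n_replicates=int(n_replicates),
    )


def _replicate_rng(base_seed: int, k: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(base_seed), int(k)]))


def run_scenario(
    config: ScenarioConfig,
    n_replicates: int,
    base_seed: int = 0,
    estimators=None,
    n_jobs: int = 1,
) -> list[McSummary]:
    """Monte Carlo study for one scenario configuration.

    Replicate seeds derive deterministically from ``base_seed``; results
    do not depend on ``n_jobs``.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    estimators = tuple(estimators) if estimators else default_estimators(config)

    def one(k: int):
        return run_replicate(config, estimators, rng=_replicate_rng(base_seed, k))

    if n_jobs == 1:
        results = [one(k) for k in range(n_replicates)]
    else:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(delayed(one)(k) for k in range(n_replicates))

    psi = true_psi(config)
    summaries = []
    for est in estimators:
        reps = [r[est] for r in results]
        summaries.append(
            summarize(
                [r.psi for r in reps],
                [r.ci_low for r in reps],
                [r.ci_high for r in reps],
                psi,
                estimator=est,
                n_replicates=n_replicates,
            )
        )
    return summaries


def summaries_to_frame(summaries) -> pd.DataFrame:
    """Tabular view mirroring the study's reporting format."""
    return pd.DataFrame(
        {
            "estimator": [s.estimator for s in summaries],
            "effect": "a_lag",
            "psi_true": [s.psi_true for s in summaries],
            "estimate": [s.mean_estimate for s in summaries],
            "bias": [s.bias for s in summaries],
            "relative_bias_pct": [s.relative_bias_pct for s in summaries],
            "mce": [s.mce for s in summaries],
            "rmse": [s.rmse for s in summaries],
            "coverage": [s.coverage for s in summaries],
            "n_converged": [s.n_converged for s in summaries],
            "n_replicates": [s.n_replicates for s in summaries],
        }
    )


# --- application-style pipeline on synthetic two-exposure data -------------


@dataclass
class TwoExposurePanel:
    """Panel with two binary exposures sharing one visit process."""

    V: np.ndarray
    A1: np.ndarray
    A2: np.ndarray
    L: np.ndarray
    Y_obs: np.ndarray
    X: np.ndarray
    effects: tuple[float, float]

    @property
    def n_subjects(self) -> int:
        return self.V.shape[0]

    @property
    def n_intervals(self) -> int:
        return self.V.shape[1]


def simulate_two_exposure_panel(
    n_subjects: int,
    n_intervals: int = 8,
    effects: tuple[float, float] = (-0.4, -0.3),
    seed: int = 0,
) -> TwoExposurePanel:
    """Synthetic cohort with two persistent exposures and irregular visits.

    The outcome depends on each exposure through its cumulative
    prescription count truncated at two, on the lagged visit and on the
    lagged confounder; the confounder influences both exposure
    assignments, creating confounding the weights must remove.
    """
    rng = np.random.default_rng(seed)
    n, t = n_subjects, n_intervals
    eff1, eff2 = effects
    X = baseline_transform(rng.standard_normal((n, 3)))
    x_sum = 0.5 * (X[:, 0] + X[:, 1] + X[:, 2])
    x_visit = 0.1 * (X[:, 0] + X[:, 1] + X[:, 2])
    x_treat = 0.2 * (X[:, 0] + X[:, 1] + X[:, 2])

    V = np.zeros((n, t), dtype=np.int8)
    A1 = np.zeros((n, t), dtype=np.int8)
    A2 = np.zeros((n, t), dtype=np.int8)
    L = np.zeros((n, t), dtype=np.int8)
    Y = np.full((n, t), np.nan)

    v_prev = np.zeros(n)
    l_prev = np.zeros(n)
    a1_prev = np.zeros(n)
    a2_prev = np.zeros(n)
    cum1 = np.zeros(n)
    cum2 = np.zeros(n)
    for j in range(t):
        p_v = expit(2.0 + 0.1 * l_prev + x_visit)
        v = (rng.random(n) < p_v).astype(np.int8)
        y = (
            9.0
            + eff1 * np.minimum(cum1, 2.0)
            + eff2 * np.minimum(cum2, 2.0)
            - 0.1 * v_prev
            + 0.8 * l_prev
            + x_sum
            + np.sqrt(3.0) * rng.standard_normal(n)
        )
        p_l = expit(-0.5 + 0.2 * v_prev + 0.3 * l_prev)
        l_new = (rng.random(n) < p_l).astype(np.int8)
        p_a1 = expit(-1.2 + 0.8 * l_new + x_treat + 2.0 * a1_prev)
        a1_new = (rng.random(n) < p_a1).astype(np.int8)
        p_a2 = expit(-1.2 + 0.8 * l_new + x_treat + 2.0 * a2_prev)
        a2_new = (rng.random(n) < p_a2).astype(np.int8)

        visited = v == 1
        V[:, j] = v
        Y[visited, j] = y[visited]
        L[:, j] = np.where(visited, l_new, l_prev).astype(np.int8)
        A1[:, j] = np.where(visited, a1_new, a1_prev).astype(np.int8)
        A2[:, j] = np.where(visited, a2_new, a2_prev).astype(np.int8)

        v_prev = v.astype(float)
        l_prev = L[:, j].astype(float)
        a1_prev = A1[:, j].astype(float)
        a2_prev = A2[:, j].astype(float)
        cum1 = cum1 + A1[:, j]
        cum2 = cum2 + A2[:, j]

    return TwoExposurePanel(V=V, A1=A1, A2=A2, L=L, Y_obs=Y, X=X, effects=(eff1, eff2))


def _two_exposure_as_panel(p2: TwoExposurePanel, which: str) -> Panel:
    A = p2.A1 if which == "A1" else p2.A2
    return Panel(
        V=p2.V,
        A=A,
        L=p2.L,
        Y_latent=p2.Y_obs.copy(),
        Y_obs=p2.Y_obs,
        X=p2.X,
        eta=np.zeros(p2.n_subjects),
        config=None,
    )


def run_application_pipeline(
    p2: TwoExposurePanel,
    truncation: tuple[float, float] = (0.01, 0.99),
    calibrate_weights: bool = True,
) -> GeeFit:
    """Multi-exposure product-weight pipeline on a two-exposure panel.

    Builds stabilized weights for both exposures and the visit process,
    calibrates each family (balance + unity), multiplies them, truncates
    at the given quantiles and fits the marginal model with cumulative
    prescription counts truncated at two plus the lagged visit.
    A constant exposure degrades gracefully to a unit weight family.
    """
    n, t = p2.V.shape
    parts = []
    for which in ("A1", "A2"):
        panel = _two_exposure_as_panel(p2, which)
        try:
            sw = stabilized_weights(panel, "treatment")
        except DegenerateFitError:
            parts.append(WeightSet(sw=np.ones((n, t)), kind="treatment"))
            continue
        if calibrate_weights:
            cal = calibrate(sw, panel, families=("balance", "unity"))
            if cal.converged:
                sw = cal.calibrated
        parts.append(sw)
    panel_v = _two_exposure_as_panel(p2, "A1")
    try:
        sw_v = stabilized_weights(panel_v, "visit")
        if calibrate_weights:
            cal = calibrate(sw_v, panel_v, families=("balance", "unity"))
            if cal.converged:
                sw_v = cal.calibrated
        parts.append(sw_v)
    except DegenerateFitError:
        parts.append(WeightSet(sw=np.ones((n, t)), kind="visit"))

    prod = truncate_weights(product_weights(parts), *truncation)

    cum1 = np.cumsum(p2.A1, axis=1)
    cum2 = np.cumsum(p2.A2, axis=1)
    cum1_lag = np.zeros((n, t))
    cum2_lag = np.zeros((n, t))
    cum1_lag[:, 1:] = np.minimum(cum1[:, :-1], 2)
    cum2_lag[:, 1:] = np.minimum(cum2[:, :-1], 2)

    obs = p2.V == 1
    subj, interval = np.nonzero(obs)
    y = p2.Y_obs[subj, interval]
    v_lag = np.where(interval > 0, p2.V[subj, np.maximum(interval - 1, 0)], 0)
    Xd = np.column_stack(
        [
            np.ones(len(y)),
            cum1_lag[subj, interval],
            cum2_lag[subj, interval],
            v_lag.astype(float),
            p2.X[subj, 0],
            p2.X[subj, 1],
            p2.X[subj, 2],
        ]
    )
    names = ["const", "cum_a1", "cum_a2", "v_lag", "x1", "x2", "x3"]
    keep = [0] + [k for k in range(1, Xd.shape[1]) if np.ptp(Xd[:, k]) > 0]
    Xd = Xd[:, keep]
    names = [names[k] for k in keep]
    return fit_weighted_gee(
        y, Xd, subj, weights=prod.sw[subj, interval], corr="ar1", names=names
    )
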