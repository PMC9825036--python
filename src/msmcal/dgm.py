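"""Longitudinal panel simulator with visit-driven carry-forward.

Each subject carries a standard-normal latent confounder ``eta`` and
three transformed-normal baseline covariates.  Within every interval the
conditional models are drawn in topological order visit -> outcome ->
confounder -> treatment; at non-visit intervals the outcome is missing
and treatment/confounder are carried forward from the previous interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ScenarioConfig

__all__ = [
    "Panel",
    "expit",
    "draw_baseline_covariates",
    "simulate_panel",
    "panel_to_frame",
    "panel_from_frame",
    "write_panel_csv",
    "read_panel_csv",
]


def expit(x):
    """Numerically stable logistic function exp(x)/(1+exp(x))."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(eq=False)
class Panel:
    """Rectangular subject-by-interval arrays from one simulated cohort.

    ``Y_obs`` is NaN exactly where ``V == 0``; ``Y_latent`` mirrors
    ``Y_obs`` for simulated panels (the outcome is only generated at
    visits) and exists for interface symmetry with intervened
    trajectories, where the outcome is drawn at every interval.
    """

    V: np.ndarray
    A: np.ndarray
    L: np.ndarray
    Y_latent: np.ndarray
    Y_obs: np.ndarray
    X: np.ndarray
    eta: np.ndarray
    config: ScenarioConfig | None = None

    @property
    def n_subjects(self) -> int:
        return self.V.shape[0]

    @property
    def n_intervals(self) -> int:
        return self.V.shape[1]

    def validate(self) -> None:
        """Check the structural invariants; raise AssertionError on failure."""
        V, A, L = self.V, self.A, self.L
        assert set(np.unique(V)) <= {0, 1}
        assert set(np.unique(A)) <= {0, 1}
        assert set(np.unique(L)) <= {0, 1}
        assert np.array_equal(np.isnan(self.Y_obs), V == 0)
        A_prev = np.concatenate([np.zeros((self.n_subjects, 1)), A[:, :-1]], axis=1)
        L_prev = np.concatenate([np.zeros((self.n_subjects, 1)), L[:, :-1]], axis=1)
        assert np.all((1 - V) * np.abs(A - A_prev) == 0)
        assert np.all((1 - V) * np.abs(L - L_prev) == 0)


def draw_baseline_covariates(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw the three baseline covariates for ``n`` subjects.

    Row i is the deterministic transform
    ``(exp(u1/2), u1/(1+exp(u2)), u1*u3/25)`` of an independent
    trivariate standard-normal draw ``u``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    u = rng.standard_normal((n, 3))
    return baseline_transform(u)


def baseline_transform(u: np.ndarray) -> np.ndarray:
    """Map raw trivariate normals to the observed baseline covariates."""
    u = np.atleast_2d(np.asarray(u, dtype=float))
    x1 = np.exp(u[:, 0] / 2.0)
    x2 = u[:, 0] / (1.0 + np.exp(u[:, 1]))
    x3 = u[:, 0] * u[:, 2] / 25.0
    return np.column_stack([x1, x2, x3])


def simulate_panel(config: ScenarioConfig, rng: np.random.Generator | None = None) -> Panel:
    """Simulate one cohort from the conditional data-generating mechanism.

    Draw order (fixed for reproducibility): eta, baseline normals, then
    per interval the uniform/normal variates for visit, outcome,
    confounder and treatment across all subjects.  All lagged values are
    zero before the first interval.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, t = config.n_subjects, config.n_intervals
    th = np.asarray(config.theta)
    mu = np.asarray(config.mu)
    om = np.asarray(config.omega)
    al = np.asarray(config.alpha)
    sd_y = float(np.sqrt(config.sigma2_y))

    eta = rng.standard_normal(n)
    X = draw_baseline_covariates(n, rng)
    x1, x2, x3 = X[:, 0], X[:, 1], X[:, 2]

    V = np.zeros((n, t), dtype=np.int8)
    A = np.zeros((n, t), dtype=np.int8)
    L = np.zeros((n, t), dtype=np.int8)
    Y_obs = np.full((n, t), np.nan)

    v_prev = np.zeros(n)
    a_prev = np.zeros(n)
    l_prev = np.zeros(n)
    x_visit = om[2] * x1 + om[3] * x2 + om[4] * x3
    x_treat = al[5] * x1 + al[6] * x2 + al[7] * x3 + al[8] * eta
    x_out = th[4] * x1 + th[5] * x2 + th[6] * x3 + th[7] * eta

    for j in range(t):
        p_v = expit(om[0] + om[1] * l_prev + x_visit)
        v = (rng.random(n) < p_v).astype(np.int8)
        y_noise = rng.standard_normal(n)
        u_l = rng.random(n)
        u_a = rng.random(n)

        y_mean = th[0] + th[1] * a_prev + th[2] * v_prev + th[3] * l_prev + x_out
        y = y_mean + sd_y * y_noise

        p_l = expit(mu[0] + mu[1] * v_prev + mu[2] * y + mu[3] * l_prev + mu[4] * a_prev)
        l_new = (u_l < p_l).astype(np.int8)
        p_a = expit(
            al[0] + al[1] * v_prev + al[2] * y + al[3] * l_new + al[4] * a_prev + x_treat
        )
        a_new = (u_a < p_a).astype(np.int8)

        visited = v == 1
        V[:, j] = v
        Y_obs[visited, j] = y[visited]
        L[:, j] = np.where(visited, l_new, l_prev).astype(np.int8)
        A[:, j] = np.where(visited, a_new, a_prev).astype(np.int8)

        v_prev = v.astype(float)
        l_prev = L[:, j].astype(float)
        a_prev = A[:, j].astype(float)

    return Panel(
        V=V, A=A, L=L, Y_latent=Y_obs.copy(), Y_obs=Y_obs, X=X, eta=eta, config=config
    )


# --- long-format CSV interchange ------------------------------------------

_COLUMNS = ["id", "interval", "visit", "treatment", "confounder", "outcome", "x1", "x2", "x3"]


def panel_to_frame(panel: Panel) -> pd.DataFrame:
    """Long-format view: one row per (subject, interval), 1-based interval."""
    n, t = panel.n_subjects, panel.n_intervals
    ids = np.repeat(np.arange(1, n + 1), t)
    intervals = np.tile(np.arange(1, t + 1), n)
    frame = pd.DataFrame(
        {
            "id": ids,
            "interval": intervals,
            "visit": panel.V.ravel(),
            "treatment": panel.A.ravel(),
            "confounder": panel.L.ravel(),
            "outcome": panel.Y_obs.ravel(),
            "x1": np.repeat(panel.X[:, 0], t),
            "x2": np.repeat(panel.X[:, 1], t),
            "x3": np.repeat(panel.X[:, 2], t),
        }
    )
    return frame


def panel_from_frame(frame: pd.DataFrame, config: ScenarioConfig | None = None) -> Panel:
    """Rebuild a rectangular Panel from its long-format frame."""
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    frame = frame.sort_values(["id", "interval"], kind="stable")
    ids = frame["id"].to_numpy()
    uniq = np.unique(ids)
    n = len(uniq)
    t = int(frame["interval"].max())
    if len(frame) != n * t:
        raise ValueError("panel is not rectangular")
    shape = (n, t)
    V = frame["visit"].to_numpy().reshape(shape).astype(np.int8)
    A = frame["treatment"].to_numpy().reshape(shape).astype(np.int8)
    L = frame["confounder"].to_numpy().reshape(shape).astype(np.int8)
    Y = frame["outcome"].to_numpy(dtype=float).reshape(shape)
    X = frame[["x1", "x2", "x3"]].to_numpy(dtype=float).reshape(n, t, 3)[:, 0, :]
    return Panel(
        V=V, A=A, L=L, Y_latent=Y.copy(), Y_obs=Y, X=X,
        eta=np.full(n, np.nan), config=config,
    )


def write_panel_csv(panel: Panel, path: str | Path) -> None:
    panel_to_frame(panel).to_csv(path, index=False, float_format="%.17g")


def read_panel_csv(path: str | Path, config: ScenarioConfig | None = None) -> Panel:
    return panel_from_frame(pd.read_csv(path), config=config)
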