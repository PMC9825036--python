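"""Scenario configuration for the longitudinal data-generating mechanism.

A :class:`ScenarioConfig` bundles every coefficient of the conditional
models (outcome, confounder, visit, treatment), the panel dimensions and
the scenario flags.  The four canonical simulation scenarios are the
cross of ``irregular_visits`` x ``unmeasured_confounder``; their
coefficient values ship as YAML fixtures under ``msmcal/scenarios/``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "ScenarioConfig",
    "scenario_config",
    "load_config",
    "save_config",
    "REGULAR_VISIT_INTERCEPT",
    "IRREGULAR_VISIT_INTERCEPT",
    "LATENT_LOADING",
]

#: visit-model intercept used when every interval is (effectively) visited
REGULAR_VISIT_INTERCEPT = 16.0
#: visit-model intercept producing ~88% visit probability at zero covariates
IRREGULAR_VISIT_INTERCEPT = 2.0
#: loading of the subject-level latent confounder on outcome and treatment
LATENT_LOADING = 0.1


@dataclass(frozen=True)
class ScenarioConfig:
    """All coefficients and dimensions of the data-generating mechanism.

    Parameters
    ----------
    theta
        Outcome-model coefficients ``(theta0..theta7)``: intercept, lagged
        treatment, lagged visit, lagged confounder, x1, x2, x3, latent
        confounder loading.
    sigma2_y
        Outcome error variance.
    mu
        Confounder-model coefficients ``(mu0..mu4)``: intercept, lagged
        visit, current outcome, lagged confounder, lagged treatment.
    omega
        Visit-model coefficients ``(omega0..omega4)``: intercept, lagged
        confounder, x1, x2, x3.
    alpha
        Treatment-model coefficients ``(alpha0..alpha8)``: intercept,
        lagged visit, current outcome, current confounder, lagged
        treatment, x1, x2, x3, latent confounder loading.
    n_subjects, n_intervals
        Panel dimensions.
    irregular_visits
        When False, ``omega[0]`` is forced to
        :data:`REGULAR_VISIT_INTERCEPT` so visits occur essentially
        always.
    unmeasured_confounder
        When False, ``theta[7]`` and ``alpha[8]`` are forced to zero.
    seed
        Default seed for panel simulation.
    """

    theta: tuple[float, ...] = (9.0, -0.3, -0.1, 0.5, 0.5, 0.5, 0.5, LATENT_LOADING)
    sigma2_y: float = 3.0
    mu: tuple[float, ...] = (0.0, 0.1, 0.0, 0.0, 0.1)
    omega: tuple[float, ...] = (IRREGULAR_VISIT_INTERCEPT, 0.1, 0.1, 0.1, 0.1)
    alpha: tuple[float, ...] = (0.0, 0.1, 0.1, 0.1, 0.0, 0.3, 0.3, 0.6, LATENT_LOADING)
    n_subjects: int = 100
    n_intervals: int = 10
    irregular_visits: bool = True
    unmeasured_confounder: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", tuple(float(v) for v in self.theta))
        object.__setattr__(self, "mu", tuple(float(v) for v in self.mu))
        object.__setattr__(self, "omega", tuple(float(v) for v in self.omega))
        object.__setattr__(self, "alpha", tuple(float(v) for v in self.alpha))
        if len(self.theta) != 8:
            raise ValueError("theta must have 8 entries (theta0..theta7)")
        if len(self.mu) != 5:
            raise ValueError("mu must have 5 entries (mu0..mu4)")
        if len(self.omega) != 5:
            raise ValueError("omega must have 5 entries (omega0..omega4)")
        if len(self.alpha) != 9:
            raise ValueError("alpha must have 9 entries (alpha0..alpha8)")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_intervals < 1:
            raise ValueError("n_intervals must be >= 1")
        if not self.sigma2_y > 0:
            raise ValueError("sigma2_y must be positive")
        if not self.unmeasured_confounder:
            theta = list(self.theta)
            alpha = list(self.alpha)
            theta[7] = 0.0
            alpha[8] = 0.0
            object.__setattr__(self, "theta", tuple(theta))
            object.__setattr__(self, "alpha", tuple(alpha))
        if not self.irregular_visits:
            omega = list(self.omega)
            omega[0] = REGULAR_VISIT_INTERCEPT
            object.__setattr__(self, "omega", tuple(omega))

    def replace(self, **changes) -> "ScenarioConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return {
            "theta": list(self.theta),
            "sigma2_y": self.sigma2_y,
            "mu": list(self.mu),
            "omega": list(self.omega),
            "alpha": list(self.alpha),
            "n_subjects": self.n_subjects,
            "n_intervals": self.n_intervals,
            "irregular_visits": self.irregular_visits,
            "unmeasured_confounder": self.unmeasured_confounder,
            "seed": self.seed,
        }


def scenario_config(scenario: int, **overrides) -> ScenarioConfig:
    """Build the canonical configuration for scenario 1-4.

    Scenario 1: regular visits, no latent confounder.
    Scenario 2: regular visits, latent confounder.
    Scenario 3: irregular visits, no latent confounder.
    Scenario 4: irregular visits, latent confounder.
    """
    if scenario not in (1, 2, 3, 4):
        raise ValueError(f"scenario must be 1..4, got {scenario}")
    irregular = scenario in (3, 4)
    latent = scenario in (2, 4)
    base = ScenarioConfig(
        irregular_visits=irregular,
        unmeasured_confounder=latent,
    )
    if overrides:
        base = base.replace(**overrides)
    return base


def load_config(source: str | Path) -> ScenarioConfig:
    """Read a ScenarioConfig from a YAML (or JSON) file."""
    with open(source) as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict):
        raise ValueError(f"expected a mapping in {source}")
    fields = {f.name for f in dataclasses.fields(ScenarioConfig)}
    unknown = set(payload) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return ScenarioConfig(**payload)


def save_config(config: ScenarioConfig, target: str | Path) -> None:
    with open(target, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def packaged_scenario_path(scenario: int):
    """Path to the shipped YAML fixture for scenario 1-4."""
    return resources.files("msmcal") / "scenarios" / f"scenario{scenario}.yaml"
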