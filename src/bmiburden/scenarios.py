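"""BMI trajectories for the business-as-usual and counterfactual scenarios.

Four canonical trajectories over 2019-2030 share the 2019 baseline:

* ``BAU``   - stratum mean BMI grows 0.4 %/year (the 2003-2017 trend);
* ``S1``    - growth halved to 0.2 %/year;
* ``S2``    - each stratum's overweight prevalence P(BMI >= 25) held at its
  2019 level (pooled, the current ~77 % prevalence), i.e. the frozen baseline;
* ``S3``    - overweight prevalence reduced linearly by 0.61 % of the 2019
  level per year, a 6.7 % relative reduction by 2030.

Prevalence-mechanism scenarios move the whole stratum distribution by a mean
shift with fixed spread: for a normal stratum the mean solving
P(BMI >= 25) = target is 25 + sd * z(target) in closed form.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    OVERWEIGHT_BMI,
    SCENARIOS,
    TMREL_SCENARIO,
    BMIDistribution,
    BMITrajectory,
    ModelConfig,
    ParameterError,
)

__all__ = [
    "ScenarioSpec",
    "mean_growth_trajectory",
    "prevalence_to_mean_shift",
    "overweight_prevalence",
    "build_canonical_scenarios",
    "tmrel_trajectory",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Mechanism and parameters of one scenario."""

    scenario_id: str
    mechanism: str  # mean_growth_rate | prevalence_hold | prevalence_reduction
    rate: float = 0.0

    def __post_init__(self) -> None:
        if self.mechanism not in (
            "mean_growth_rate",
            "prevalence_hold",
            "prevalence_reduction",
        ):
            raise ParameterError(f"unknown mechanism {self.mechanism!r}")
        if self.rate < 0:
            raise ParameterError("mechanism rate must be non-negative")


def canonical_scenario_specs(config: ModelConfig) -> dict[str, ScenarioSpec]:
    return {
        "BAU": ScenarioSpec("BAU", "mean_growth_rate", config.bau_annual_bmi_increase),
        "S1": ScenarioSpec("S1", "mean_growth_rate", config.scenario1_annual_bmi_increase),
        "S2": ScenarioSpec("S2", "prevalence_hold"),
        "S3": ScenarioSpec("S3", "prevalence_reduction", config.scenario3_annual_step),
    }


def overweight_prevalence(dist: BMIDistribution) -> float:
    """P(BMI >= 25) for a normal stratum distribution (exact, not gridded)."""
    if dist.sd == 0.0:
        return float(dist.mean >= OVERWEIGHT_BMI)
    return float(stats.norm.sf(OVERWEIGHT_BMI, loc=dist.mean, scale=dist.sd))


def prevalence_to_mean_shift(
    dist: BMIDistribution, target_prevalence: float
) -> BMIDistribution:
    """Distribution with the mean shifted (sd fixed) to hit a prevalence target."""
    if not 0.0 < target_prevalence < 1.0:
        raise ParameterError("target prevalence must be strictly inside (0, 1)")
    if dist.sd == 0.0:
        raise ParameterError("cannot shift a point mass to a prevalence target")
    new_mean = OVERWEIGHT_BMI + dist.sd * stats.norm.ppf(target_prevalence)
    return BMIDistribution(float(new_mean), dist.sd)


def _baseline_frame(baseline: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    return baseline["mean_bmi"].astype(float), baseline["sd_bmi"].astype(float)


def mean_growth_trajectory(
    baseline: pd.DataFrame,
    annual_rate: float,
    config: ModelConfig,
    scenario_id: str = "BAU",
) -> BMITrajectory:
    """Compound growth of every stratum mean: mean(t) = mean0 * (1+rate)^(t-t0)."""
    if annual_rate < 0:
        raise ParameterError(
            "annual growth rate must be non-negative; use a prevalence mechanism "
            "for reductions"
        )
    mean0, sd = _baseline_frame(baseline)
    years = list(config.years)
    means = pd.DataFrame(
        {
            y: mean0 * (1.0 + annual_rate) ** (y - config.start_year)
            for y in years
        }
    )
    return BMITrajectory(scenario_id, means, sd)


def _prevalence_trajectory(
    baseline: pd.DataFrame,
    config: ModelConfig,
    annual_step: float,
    scenario_id: str,
) -> BMITrajectory:
    """Per-stratum overweight prevalence reduced by annual_step x (t - t0), relative."""
    mean0, sd = _baseline_frame(baseline)
    base_prev = stats.norm.sf(OVERWEIGHT_BMI, loc=mean0.to_numpy(), scale=sd.to_numpy())
    years = list(config.years)
    cols = {}
    for y in years:
        factor = 1.0 - annual_step * (y - config.start_year)
        if factor <= 0:
            raise ParameterError(f"{scenario_id}: prevalence reduced below zero by {y}")
        if y == config.start_year:
            cols[y] = mean0.to_numpy(dtype=float)
        else:
            target = np.clip(base_prev * factor, 1e-12, 1 - 1e-12)
            cols[y] = OVERWEIGHT_BMI + sd.to_numpy() * stats.norm.ppf(target)
    means = pd.DataFrame(cols, index=baseline.index)
    return BMITrajectory(scenario_id, means, sd)


def build_canonical_scenarios(
    config: ModelConfig, baseline: pd.DataFrame
) -> dict[str, BMITrajectory]:
    """The four scenario trajectories, all anchored at the 2019 baseline."""
    specs = canonical_scenario_specs(config)
    out: dict[str, BMITrajectory] = {}
    for sid in SCENARIOS:
        spec = specs[sid]
        if spec.mechanism == "mean_growth_rate":
            out[sid] = mean_growth_trajectory(baseline, spec.rate, config, sid)
        elif spec.mechanism == "prevalence_hold":
            # Holding each stratum's own 2019 overweight prevalence fixes the
            # distribution itself (mean shift has a fixed point at the current
            # prevalence), so S2 is the frozen baseline.
            out[sid] = _prevalence_trajectory(baseline, config, 0.0, sid)
        else:
            out[sid] = _prevalence_trajectory(baseline, config, spec.rate, sid)
    return out


def tmrel_trajectory(config: ModelConfig, baseline: pd.DataFrame) -> BMITrajectory:
    """Counterfactual with BMI held at the theoretical minimum (22 kg/m2).

    Point-mass distributions every year; the attributable burden of a
    scenario is its burden minus the burden under this trajectory.
    """
    years = list(config.years)
    means = pd.DataFrame(
        {y: np.full(len(baseline.index), config.tmrel) for y in years},
        index=baseline.index,
    )
    sd = pd.Series(0.0, index=baseline.index)
    return BMITrajectory(TMREL_SCENARIO, means, sd, degenerate=True)
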