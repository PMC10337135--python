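"""Synthetic Chilean-style input bundle.

Real inputs for this model are national survey BMI distributions, official
demography/mortality, and GBD-style disease rates, none of which are
redistributable.  This module generates a fully self-consistent stand-in:

* a closed cohort aged 20-80, both sexes, with Gompertz all-cause mortality;
* normal BMI distributions per stratum anchored to the survey headline
  figures (male mean 28.1, female 29.4 kg/m2; pooled overweight prevalence
  75.7 %), with the stratum spread solved from the prevalence anchor;
* order-of-magnitude plausible disease rates with age-increasing incidence,
  remission for cancers only, and prevalence set to the illness-death
  steady state so the bundle always passes ``validate_epi_consistency``.

Everything is deterministic given the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import (
    AGE_HI,
    AGE_LO,
    BREAST_CANCER,
    CANCERS,
    DISEASES,
    FEMALE,
    MALE,
    SEXES,
    OVERWEIGHT_BMI,
    DiseaseEpi,
    ModelConfig,
    ModelInputs,
    ParameterError,
    PopulationTable,
    default_rr_specs,
    strata_index,
)

__all__ = [
    "SyntheticParams",
    "generate_population",
    "generate_bmi_baseline",
    "generate_disease_epi",
    "generate_bundle",
    "steady_state_prevalence",
]

#: (incidence at age 20 /py, exponential age slope /y, case fatality /py,
#:  remission /py).  Magnitudes are plausible, not calibrated to GBD.
_DISEASE_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "coronary_heart_disease": (5e-5, 0.080, 0.040, 0.0),
    "stroke": (4e-5, 0.085, 0.060, 0.0),
    "hypertensive_heart_disease": (5e-6, 0.090, 0.030, 0.0),
    "type2_diabetes": (4e-4, 0.035, 0.005, 0.0),
    "chronic_kidney_disease": (2e-4, 0.045, 0.010, 0.0),
    "cirrhosis": (2e-5, 0.060, 0.070, 0.0),
    "colorectal_cancer": (2e-6, 0.100, 0.080, 0.040),
    "kidney_cancer": (8e-7, 0.095, 0.070, 0.040),
    "liver_cancer": (5e-7, 0.100, 0.250, 0.020),
    "breast_cancer": (1e-5, 0.060, 0.030, 0.050),
    "pancreatic_cancer": (5e-7, 0.100, 0.300, 0.010),
}


@dataclass(frozen=True)
class SyntheticParams:
    """Knobs of the generator; the defaults are the study conditions."""

    seed: int = 0
    scale: float = 1e5  # persons per sex
    bmi_mean: dict[str, float] = field(
        default_factory=lambda: {MALE: 28.1, FEMALE: 29.4}
    )
    overweight_prevalence: float = 0.757
    bmi_age_slope: float = 0.02  # kg/m2 per year of age, centred on the cohort
    age_structure_decay: float = 0.015  # exponential decline of counts with age
    gompertz: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {MALE: (8.0e-4, 0.075), FEMALE: (4.5e-4, 0.080)}
    )
    incidence_scale: dict[str, float] = field(default_factory=dict)
    rate_jitter_sd: float = 0.05  # lognormal sd of per-stratum rate noise

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ParameterError("population scale must be positive")
        if not 0.0 < self.overweight_prevalence < 1.0:
            raise ParameterError("anchor prevalence must be inside (0, 1)")


def _ages() -> np.ndarray:
    return np.arange(AGE_LO, AGE_HI + 1)


def generate_population(params: SyntheticParams) -> PopulationTable:
    """Closed cohort with a gently declining age structure and Gompertz mortality."""
    ages = _ages()
    weights = np.exp(-params.age_structure_decay * (ages - AGE_LO))
    weights /= weights.sum()
    rows = []
    for sex in SEXES:
        a0, b = params.gompertz[sex]
        mort = a0 * np.exp(b * (ages - AGE_LO))
        counts = np.round(params.scale * weights)
        rows.append(
            pd.DataFrame(
                {"count": counts, "all_cause_mortality_rate": mort},
                index=pd.MultiIndex.from_product([[sex], ages], names=["sex", "age"]),
            )
        )
    return PopulationTable(pd.concat(rows).reindex(strata_index()))


def _solve_sd(age_means: np.ndarray, weights: np.ndarray, target: float) -> float:
    """Stratum sd such that count-weighted P(BMI >= 25) equals the target."""

    def pooled(sd: float) -> float:
        return float(
            np.average(stats.norm.sf(OVERWEIGHT_BMI, loc=age_means, scale=sd), weights=weights)
        ) - target

    lo, hi = 0.3, 25.0
    if pooled(lo) * pooled(hi) > 0:
        raise ParameterError(
            "anchor mean/prevalence pair is infeasible for a normal distribution"
        )
    return float(optimize.brentq(pooled, lo, hi, xtol=1e-10))


def generate_bmi_baseline(
    params: SyntheticParams, pop: PopulationTable | None = None
) -> pd.DataFrame:
    """Normal BMI distribution per stratum hitting the pooled anchors.

    The count-weighted mean equals the sex anchor exactly (the age gradient
    is centred on the weighted mean age) and the pooled overweight prevalence
    equals the anchor by construction of the solved sd.
    """
    pop = pop or generate_population(params)
    ages = _ages()
    frames = []
    for sex in SEXES:
        counts = pop.data.loc[sex, "count"].to_numpy(dtype=float)
        mean_age = np.average(ages, weights=counts)
        means = params.bmi_mean[sex] + params.bmi_age_slope * (ages - mean_age)
        sd = _solve_sd(means, counts, params.overweight_prevalence)
        frames.append(
            pd.DataFrame(
                {"mean_bmi": means, "sd_bmi": sd},
                index=pd.MultiIndex.from_product([[sex], ages], names=["sex", "age"]),
            )
        )
    return pd.concat(frames).reindex(strata_index())


def steady_state_prevalence(
    incidence: np.ndarray, remission: np.ndarray, case_fatality: np.ndarray
) -> np.ndarray:
    """Equilibrium diseased proportion of the illness-death process.

    Among survivors with equal other-cause mortality in both living states,
    p(t) = C/(S+C) evolves as dp/dt = i(1-p) - (r+f)p + f p^2; the root in
    [0, 1] of f p^2 - (i+r+f) p + i = 0 is the steady state (i/(i+r) when
    case fatality is zero).
    """
    i = np.asarray(incidence, dtype=float)
    r = np.asarray(remission, dtype=float)
    f = np.asarray(case_fatality, dtype=float)
    total = i + r + f
    p = np.zeros_like(i)
    lin = (f <= 1e-12) & (total > 0)
    p[lin] = i[lin] / total[lin]
    quad = f > 1e-12
    disc = np.sqrt(np.maximum(total[quad] ** 2 - 4.0 * f[quad] * i[quad], 0.0))
    p[quad] = (total[quad] - disc) / (2.0 * f[quad])
    return np.clip(p, 0.0, 1.0)


def generate_disease_epi(
    params: SyntheticParams, pop: PopulationTable | None = None
) -> dict[str, DiseaseEpi]:
    """GBD-like rates for the 11 diseases, consistent by construction."""
    rng = np.random.default_rng(params.seed)
    ages = _ages()
    out: dict[str, DiseaseEpi] = {}
    for disease in DISEASES:
        i0, slope, fatality, remission = _DISEASE_PARAMS[disease]
        i0 *= params.incidence_scale.get(disease, 1.0)
        frames = []
        for sex in SEXES:
            if disease == BREAST_CANCER and sex == MALE:
                inc = np.zeros_like(ages, dtype=float)
            else:
                sex_factor = 1.2 if sex == MALE and disease != BREAST_CANCER else 1.0
                jitter = np.exp(
                    rng.normal(0.0, params.rate_jitter_sd, size=ages.size)
                )
                inc = i0 * sex_factor * np.exp(slope * (ages - AGE_LO)) * jitter
            rem = np.full_like(ages, remission, dtype=float)
            fat = np.full_like(ages, fatality, dtype=float)
            prev = steady_state_prevalence(inc, rem, fat)
            frames.append(
                pd.DataFrame(
                    {
                        "incidence": inc,
                        "remission": rem,
                        "case_fatality": fat,
                        "prevalence": prev,
                    },
                    index=pd.MultiIndex.from_product(
                        [[sex], ages], names=["sex", "age"]
                    ),
                )
            )
        out[disease] = DiseaseEpi(disease, pd.concat(frames).reindex(strata_index()))
    return out


def generate_bundle(
    params: SyntheticParams | None = None, config: ModelConfig | None = None
) -> ModelInputs:
    """Full validated input bundle: population, BMI baseline, epi, RRs, config."""
    params = params or SyntheticParams()
    config = config or ModelConfig(seed=params.seed)
    pop = generate_population(params)
    return ModelInputs(
        population=pop,
        epi=generate_disease_epi(params, pop),
        bmi_baseline=generate_bmi_baseline(params, pop),
        rr_specs=default_rr_specs(config.tmrel),
        config=config,
    )
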