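"""Core data structures and the canonical disease registry.

The model follows eleven BMI-related non-communicable diseases in Chilean
adults aged 20-80: three cardiovascular diseases, type 2 diabetes, chronic
kidney disease, cirrhosis, and five cancers.  Disease identifiers are fixed
strings; every input table is validated against this registry.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)

CORONARY_HEART_DISEASE = "coronary_heart_disease"
STROKE = "stroke"
HYPERTENSIVE_HEART_DISEASE = "hypertensive_heart_disease"
TYPE2_DIABETES = "type2_diabetes"
CHRONIC_KIDNEY_DISEASE = "chronic_kidney_disease"
CIRRHOSIS = "cirrhosis"
COLORECTAL_CANCER = "colorectal_cancer"
KIDNEY_CANCER = "kidney_cancer"
LIVER_CANCER = "liver_cancer"
BREAST_CANCER = "breast_cancer"
PANCREATIC_CANCER = "pancreatic_cancer"

CANCERS = (
    COLORECTAL_CANCER,
    KIDNEY_CANCER,
    LIVER_CANCER,
    BREAST_CANCER,
    PANCREATIC_CANCER,
)
NON_CANCERS = (
    CORONARY_HEART_DISEASE,
    STROKE,
    HYPERTENSIVE_HEART_DISEASE,
    TYPE2_DIABETES,
    CHRONIC_KIDNEY_DISEASE,
    CIRRHOSIS,
)
DISEASES = NON_CANCERS + CANCERS

#: Disease groups used by the reporting layer.
CARDIOVASCULAR = (CORONARY_HEART_DISEASE, STROKE, HYPERTENSIVE_HEART_DISEASE)

#: Aggregate row labels in burden tables.
TOTAL = "TOTAL"
TOTAL_CANCER = "TOTAL_CANCER"

#: Lag between a change in BMI and its effect on disease incidence (years).
LAG_NON_CANCER = 5
LAG_CANCER = 10

#: Baseline cohort age span and the oldest age with a relative-risk band.
AGE_LO, AGE_HI = 20, 80
MAX_RR_AGE = 89

OVERWEIGHT_BMI = 25.0

SCENARIOS = ("BAU", "S1", "S2", "S3")
TMREL_SCENARIO = "TMREL"

BURDEN_COLUMNS = ["outcome", "disease_id", "scenario_id", "year", "value"]


def lag_for(disease_id: str) -> int:
    """Incidence lag in years for one disease (10 for cancers, 5 otherwise)."""
    return LAG_CANCER if disease_id in CANCERS else LAG_NON_CANCER


def strata_index() -> pd.MultiIndex:
    """Canonical (sex, age) stratum index: both sexes, single-year ages 20-80."""
    return pd.MultiIndex.from_product(
        [list(SEXES), range(AGE_LO, AGE_HI + 1)], names=["sex", "age"]
    )


class SchemaError(ValueError):
    """An input table violates its documented schema."""


class ParameterError(ValueError):
    """A model or generator parameter is out of its valid range."""


class SpecificationGapError(LookupError):
    """A relative-risk specification has no band covering a queried stratum."""


@dataclass(frozen=True)
class RRBand:
    """One row of a relative-risk specification.

    For the per-5-kg/m2 log-linear form, ``rr`` is the risk ratio per 5 BMI
    units within the (sex, age) key; for the categorical form it is the risk
    level of the BMI interval [bmi_lo, bmi_hi).
    """

    rr: float
    rr_low: float
    rr_high: float
    sex: str = "both"
    age_lo: int = AGE_LO
    age_hi: int = MAX_RR_AGE
    bmi_lo: float = 10.0
    bmi_hi: float = 60.0

    def __post_init__(self) -> None:
        if not (self.rr_low <= self.rr <= self.rr_high):
            raise ParameterError(
                f"RR band CI does not bracket the point: {self.rr_low}, {self.rr}, {self.rr_high}"
            )
        if self.rr_low <= 0:
            raise ParameterError("RR bounds must be positive")
        if self.sex not in ("both",) + SEXES:
            raise ParameterError(f"unknown sex filter {self.sex!r}")


@dataclass(frozen=True)
class RRSpec:
    """Relative-risk specification for one disease.

    form
        ``per5_loglinear``: RR(bmi) = band_rr ** ((bmi - tmrel) / 5), floored
        at 1 below the TMREL (risk reversal below BMI 22 is not modelled).
        ``categorical``: step function over BMI intervals, used as printed
        (bands below the overweight cut may carry RR < 1).
    outside_window_rr
        If set (liver 35-79 years, breast women > 60 years), strata outside
        every band take this neutral value instead of the nearest band.
    """

    disease_id: str
    form: str
    bands: tuple[RRBand, ...]
    tmrel: float = 22.0
    outside_window_rr: float | None = None

    def __post_init__(self) -> None:
        if self.disease_id not in DISEASES:
            raise SchemaError(f"unknown disease_id {self.disease_id!r}")
        if self.form not in ("per5_loglinear", "categorical"):
            raise ParameterError(f"unknown RR form {self.form!r}")
        if not self.bands:
            raise ParameterError(f"{self.disease_id}: RRSpec needs at least one band")
        # bands must not overlap in their keying dimension (age for the
        # log-linear form, BMI for the categorical form)
        for i, a in enumerate(self.bands):
            for b in self.bands[i + 1 :]:
                if a.sex != b.sex and "both" not in (a.sex, b.sex):
                    continue
                if self.form == "per5_loglinear":
                    if a.age_lo <= b.age_hi and b.age_lo <= a.age_hi:
                        raise ParameterError(
                            f"{self.disease_id}: overlapping age bands "
                            f"{(a.age_lo, a.age_hi)} / {(b.age_lo, b.age_hi)}"
                        )
                else:
                    if a.bmi_lo < b.bmi_hi and b.bmi_lo < a.bmi_hi:
                        raise ParameterError(
                            f"{self.disease_id}: overlapping BMI bands "
                            f"{(a.bmi_lo, a.bmi_hi)} / {(b.bmi_lo, b.bmi_hi)}"
                        )


def default_rr_specs(tmrel: float = 22.0) -> dict[str, RRSpec]:
    """Published meta-analytic relative risks for the 11 diseases.

    Cardiovascular diseases and cancers use the per-5-kg/m2 log-linear form
    with age (or sex) bands; hypertensive heart disease, diabetes, chronic
    kidney disease and cirrhosis use two categorical BMI bands (15-25, 25-50).
    Ages 20-34 fall back to the youngest printed band and ages above the
    oldest band use the oldest, except where the source restricts
    applicability (liver: 35-79 years; breast: women over 60), in which case
    RR = 1 outside the window.
    """

    def per5(disease, bands, outside=None):
        return RRSpec(disease, "per5_loglinear", tuple(bands), tmrel, outside)

    def cat(disease, low, high):
        return RRSpec(
            disease,
            "categorical",
            (
                RRBand(*low, bmi_lo=15.0, bmi_hi=25.0),
                RRBand(*high, bmi_lo=25.0, bmi_hi=50.0),
            ),
            tmrel,
        )

    specs = {
        CORONARY_HEART_DISEASE: per5(
            CORONARY_HEART_DISEASE,
            [
                RRBand(1.50, 1.39, 1.62, age_lo=35, age_hi=59),
                RRBand(1.40, 1.32, 1.49, age_lo=60, age_hi=69),
                RRBand(1.31, 1.23, 1.40, age_lo=70, age_hi=79),
                RRBand(1.30, 1.17, 1.45, age_lo=80, age_hi=89),
            ],
        ),
        STROKE: per5(
            STROKE,
            [
                RRBand(1.76, 1.52, 2.04, age_lo=35, age_hi=59),
                RRBand(1.49, 1.34, 1.67, age_lo=60, age_hi=69),
                RRBand(1.33, 1.19, 1.48, age_lo=70, age_hi=79),
                RRBand(1.10, 0.94, 1.30, age_lo=80, age_hi=89),
            ],
        ),
        HYPERTENSIVE_HEART_DISEASE: cat(
            HYPERTENSIVE_HEART_DISEASE, (1.17, 0.77, 1.76), (2.03, 1.75, 2.36)
        ),
        TYPE2_DIABETES: cat(TYPE2_DIABETES, (0.96, 0.59, 1.55), (2.16, 1.89, 2.46)),
        CHRONIC_KIDNEY_DISEASE: cat(
            CHRONIC_KIDNEY_DISEASE, (1.14, 0.74, 1.77), (1.59, 1.27, 1.99)
        ),
        CIRRHOSIS: cat(CIRRHOSIS, (0.73, 0.54, 1.00), (1.79, 1.54, 2.08)),
        COLORECTAL_CANCER: per5(
            COLORECTAL_CANCER,
            [RRBand(1.24, 1.20, 1.28, sex=MALE), RRBand(1.09, 1.05, 1.13, sex=FEMALE)],
        ),
        KIDNEY_CANCER: per5(
            KIDNEY_CANCER,
            [RRBand(1.24, 1.20, 1.28, sex=MALE), RRBand(1.09, 1.05, 1.13, sex=FEMALE)],
        ),
        LIVER_CANCER: per5(
            LIVER_CANCER, [RRBand(1.47, 1.26, 1.71, age_lo=35, age_hi=79)], outside=1.0
        ),
        BREAST_CANCER: per5(
            BREAST_CANCER,
            [RRBand(1.12, 1.08, 1.16, sex=FEMALE, age_lo=61, age_hi=89)],
            outside=1.0,
        ),
        PANCREATIC_CANCER: per5(PANCREATIC_CANCER, [RRBand(1.10, 1.07, 1.14)]),
    }
    return specs


@dataclass(frozen=True)
class ModelConfig:
    """Projection settings: horizon, scenario parameters, TMREL and grid."""

    start_year: int = 2019
    end_year: int = 2030
    bau_annual_bmi_increase: float = 0.004
    scenario1_annual_bmi_increase: float = 0.002
    scenario2_prevalence_target: float = 0.769
    scenario3_total_reduction: float = 0.067
    scenario3_annual_step: float = 0.0061
    n_draws: int = 1000
    seed: int = 0
    tmrel: float = 22.0
    bmi_grid_lo: float = 10.0
    bmi_grid_hi: float = 60.0
    bmi_grid_step: float = 0.1

    def __post_init__(self) -> None:
        if self.start_year >= self.end_year:
            raise ParameterError("start_year must precede end_year")
        for name in (
            "bau_annual_bmi_increase",
            "scenario1_annual_bmi_increase",
            "scenario2_prevalence_target",
            "scenario3_total_reduction",
            "scenario3_annual_step",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.n_draws < 1:
            raise ParameterError("n_draws must be >= 1")
        if self.bmi_grid_step <= 0 or self.bmi_grid_lo >= self.bmi_grid_hi:
            raise ParameterError("invalid BMI grid")

    @property
    def years(self) -> range:
        """All calendar years of the horizon, start through end inclusive."""
        return range(self.start_year, self.end_year + 1)

    @property
    def cycle_years(self) -> range:
        """Start years of the annual cycles (one cycle per year of horizon)."""
        return range(self.start_year, self.end_year)

    @property
    def n_cycles(self) -> int:
        return self.end_year - self.start_year


@dataclass
class PopulationTable:
    """Closed-cohort population: counts and all-cause mortality by stratum.

    ``data`` is indexed by the canonical (sex, age) MultiIndex with columns
    ``count`` (persons) and ``all_cause_mortality_rate`` (per person-year).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"count", "all_cause_mortality_rate"}
        missing = required - set(self.data.columns)
        if missing:
            raise SchemaError(f"population table missing columns {sorted(missing)}")
        want = strata_index()
        if not self.data.index.equals(want):
            gaps = want.difference(self.data.index)
            raise SchemaError(
                f"population table stratum gap: {list(gaps[:4])}{'...' if len(gaps) > 4 else ''}"
            )
        if (self.data["count"] < 0).any():
            raise SchemaError("population counts must be non-negative")
        rate = self.data["all_cause_mortality_rate"]
        if (rate < 0).any():
            raise SchemaError("mortality rates must be non-negative")

    def mortality_at(self, sex: str, age: int) -> float:
        """All-cause mortality rate, holding the age-80 value above the table."""
        return float(self.data.loc[(sex, min(age, AGE_HI)), "all_cause_mortality_rate"])


@dataclass
class DiseaseEpi:
    """Epidemiological rates for one disease by stratum.

    Columns: ``incidence``, ``remission``, ``case_fatality`` (per person-year)
    and ``prevalence`` (proportion).  Remission is identically zero for the
    non-cancer diseases; the lag is 5 years (10 for cancers).
    """

    disease_id: str
    data: pd.DataFrame
    lag_years: int | None = None

    def __post_init__(self) -> None:
        if self.disease_id not in DISEASES:
            raise SchemaError(f"unknown disease_id {self.disease_id!r}")
        if self.lag_years is None:
            self.lag_years = lag_for(self.disease_id)
        required = {"incidence", "remission", "case_fatality", "prevalence"}
        missing = required - set(self.data.columns)
        if missing:
            raise SchemaError(
                f"disease_epi[{self.disease_id}] missing columns {sorted(missing)}"
            )
        want = strata_index()
        if not self.data.index.equals(want):
            gaps = want.difference(self.data.index)
            raise SchemaError(
                f"disease_epi[{self.disease_id}] stratum gap: {list(gaps[:4])}"
            )
        for col in ("incidence", "remission", "case_fatality"):
            if (self.data[col] < 0).any():
                raise SchemaError(f"disease_epi[{self.disease_id}].{col} has negative rates")
        p = self.data["prevalence"]
        if ((p < 0) | (p > 1)).any():
            raise SchemaError(f"disease_epi[{self.disease_id}].prevalence outside [0, 1]")


@dataclass(frozen=True)
class BMIDistribution:
    """Normal BMI distribution for one stratum; sd == 0 denotes a point mass."""

    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ParameterError("sd must be non-negative")


@dataclass
class BMITrajectory:
    """Year-by-year BMI distributions per stratum under one scenario.

    ``means`` is a (sex, age)-indexed DataFrame with one column per calendar
    year; ``sd`` a Series on the same index (all four scenario mechanisms
    leave the stratum spread unchanged).  ``degenerate`` marks the TMREL
    trajectory, whose distributions are point masses at the TMREL.
    """

    scenario_id: str
    means: pd.DataFrame
    sd: pd.Series
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and (self.sd <= 0).any():
            raise ParameterError(f"{self.scenario_id}: stratum sd must be positive")

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.means.columns]

    def distribution(self, sex: str, age: int, year: int) -> BMIDistribution:
        sd = 0.0 if self.degenerate else float(self.sd.loc[(sex, age)])
        return BMIDistribution(float(self.means.loc[(sex, age), year]), sd)


@dataclass
class ModelInputs:
    """Validated bundle of everything the projection needs."""

    population: PopulationTable
    epi: dict[str, DiseaseEpi]
    bmi_baseline: pd.DataFrame  # (sex, age) index, columns mean_bmi / sd_bmi
    rr_specs: dict[str, RRSpec]
    config: ModelConfig

    def __post_init__(self) -> None:
        for d in DISEASES:
            if d not in self.epi:
                raise SchemaError(f"missing disease_epi for {d}")
            if d not in self.rr_specs:
                raise SchemaError(f"missing rr_spec for {d}")
        extra = set(self.epi) - set(DISEASES)
        if extra:
            raise SchemaError(f"disease_epi has unknown diseases {sorted(extra)}")
        required = {"mean_bmi", "sd_bmi"}
        missing = required - set(self.bmi_baseline.columns)
        if missing:
            raise SchemaError(f"bmi_baseline missing columns {sorted(missing)}")
        if not self.bmi_baseline.index.equals(strata_index()):
            raise SchemaError("bmi_baseline stratum gap")
        if (self.bmi_baseline["sd_bmi"] <= 0).any():
            raise SchemaError("bmi_baseline sd_bmi must be positive")
        for d, epi in self.epi.items():
            if d not in CANCERS and (epi.data["remission"] != 0).any():
                raise SchemaError(f"non-zero remission for non-cancer disease {d}")
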