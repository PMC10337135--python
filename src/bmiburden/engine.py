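"""Proportional multistate life table engine.

A main cohort life table (Chilean adults aged 20-80 in 2019, closed cohort,
no new entrants) runs alongside eleven disease life tables.  Each disease
table moves people through four states - healthy S, diseased C, dead from
the disease D_d and dead from other causes D_o - in annual cycles with
person-year rates converted to probabilities as q = 1 - exp(-rate) and
events ordered incidence -> remission -> case fatality -> other-cause death.

Scenario BMI trajectories act on disease inflow through incidence
multipliers: for the cycle starting in year t, the multiplier is the
RR-weighted mass of the scenario's BMI distribution at t+1 (exposure reached
over the cycle) divided by that of the frozen 2019 baseline, delayed by the
disease lag (5 years, 10 for cancers).  Before the lag completes the
multiplier is held at the trajectory's start-year value, which is 1 for the
four scenarios (they share the 2019 baseline) and the full TMREL ratio for
the always-at-22 counterfactual, whose exposure predates the horizon.

Changes in disease mortality feed back into the main life table: its total
mortality is the cause-deleted rate plus the disease tables' current
per-capita disease mortality.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    AGE_HI,
    AGE_LO,
    BURDEN_COLUMNS,
    DISEASES,
    MAX_RR_AGE,
    SEXES,
    BMITrajectory,
    ModelInputs,
    ParameterError,
    RRSpec,
    strata_index,
)
from .risk import bmi_grid, normal_weights, rr_at_bmi, rr_on_grid

__all__ = [
    "apply_lag",
    "run_disease_lifetable",
    "run_mslt",
    "attributable_burden",
    "MsltRun",
    "RunContext",
]


def apply_lag(
    series: pd.Series, lag_years: int, start_year: int, fill: float = 1.0
) -> pd.Series:
    """Delay a per-year multiplier series by a disease lag.

    The returned series has the same year index; value at year t is the
    input value at t - lag, and ``fill`` (neutral, 1) for years before
    start_year + lag.  With lag 0 this is the identity; with a lag longer
    than the horizon every value is the fill, i.e. an all-neutral series.
    """
    if lag_years < 0:
        raise ParameterError("lag must be non-negative")
    years = series.index.to_numpy()
    src = years - lag_years
    values = np.where(
        src >= start_year,
        series.reindex(np.clip(src, years.min(), years.max())).to_numpy(),
        fill,
    )
    return pd.Series(values, index=series.index)


def run_disease_lifetable(
    cohort: np.ndarray,
    prevalence0: np.ndarray,
    incidence: np.ndarray,
    remission: np.ndarray,
    case_fatality: np.ndarray,
    other_mortality: np.ndarray,
    multipliers: np.ndarray,
) -> dict[str, np.ndarray]:
    """Advance one disease's four-state life table over the horizon.

    Parameters are arrays over (stratum, cycle) for the rates (already
    resolved to the cohort's age in each cycle) and over stratum for the
    initial cohort and prevalence.  Returns state trajectories with one more
    column than cycles (start-of-year states) plus per-cycle incident cases,
    disease deaths and the start-of-cycle diseased proportion among the
    alive, used by the main life table.  S + C + D_d + D_o is conserved.
    """
    cohort = np.asarray(cohort, dtype=float)
    n_s, n_k = np.asarray(incidence).shape
    S = np.empty((n_s, n_k + 1))
    C = np.empty((n_s, n_k + 1))
    Dd = np.zeros((n_s, n_k + 1))
    Do = np.zeros((n_s, n_k + 1))
    C[:, 0] = cohort * np.asarray(prevalence0, dtype=float)
    S[:, 0] = cohort - C[:, 0]
    new_cases = np.empty((n_s, n_k))
    disease_deaths = np.empty((n_s, n_k))
    prevalent_share = np.empty((n_s, n_k))

    for k in range(n_k):
        eff_inc = incidence[:, k] * multipliers[:, k]
        if (eff_inc < 0).any():
            raise ArithmeticError("negative effective incidence rate")
        q_i = 1.0 - np.exp(-eff_inc)
        q_r = 1.0 - np.exp(-remission[:, k])
        q_f = 1.0 - np.exp(-case_fatality[:, k])
        q_m = 1.0 - np.exp(-other_mortality[:, k])

        alive = S[:, k] + C[:, k]
        prevalent_share[:, k] = np.divide(
            C[:, k], alive, out=np.zeros(n_s), where=alive > 0
        )

        cases = S[:, k] * q_i
        s1 = S[:, k] - cases
        c1 = C[:, k] + cases
        remitted = c1 * q_r
        c2 = c1 - remitted
        s2 = s1 + remitted
        died_disease = c2 * q_f
        c3 = c2 - died_disease
        died_other = (s2 + c3) * q_m

        S[:, k + 1] = s2 * (1.0 - q_m)
        C[:, k + 1] = c3 * (1.0 - q_m)
        Dd[:, k + 1] = Dd[:, k] + died_disease
        Do[:, k + 1] = Do[:, k] + died_other
        new_cases[:, k] = cases
        disease_deaths[:, k] = died_disease

    return {
        "S": S,
        "C": C,
        "Dd": Dd,
        "Do": Do,
        "new_cases": new_cases,
        "disease_deaths": disease_deaths,
        "prevalent_share": prevalent_share,
    }


class RunContext:
    """Precomputed, shareable pieces of a projection run.

    Holds the stratum layout, the BMI grid, per-disease RR matrices over
    (sex, current age, grid) and the baseline-distribution denominators of
    the incidence multipliers.  One context can serve every trajectory of a
    run (and of one Monte Carlo draw), which is where the engine spends its
    time.
    """

    def __init__(
        self,
        inputs: ModelInputs,
        rr_specs: dict[str, RRSpec] | None = None,
        bmi_baseline: pd.DataFrame | None = None,
    ):
        self.inputs = inputs
        self.config = inputs.config
        self.rr_specs = rr_specs or inputs.rr_specs
        self.baseline = bmi_baseline if bmi_baseline is not None else inputs.bmi_baseline
        self.grid = bmi_grid(self.config)
        self.index = strata_index()
        self.n_strata = len(self.index)
        self.a0 = self.index.get_level_values("age").to_numpy()
        self.sex_code = (self.index.get_level_values("sex") == SEXES[1]).astype(int)
        self.counts = inputs.population.data["count"].to_numpy(dtype=float)

        base = self.baseline.reindex(self.index)
        self.base_mean = base["mean_bmi"].to_numpy(dtype=float)
        self.base_sd = base["sd_bmi"].to_numpy(dtype=float)
        self.w_base = normal_weights(self.base_mean, self.base_sd, self.grid)

        ages = np.arange(AGE_LO, MAX_RR_AGE + 1)
        self._rr_ages = ages
        self._rr_mat: dict[str, np.ndarray] = {}
        self._rr_exact_tmrel: dict[str, np.ndarray] = {}
        for disease in DISEASES:
            spec = self.rr_specs[disease]
            mat = np.empty((2, ages.size, self.grid.size))
            exact = np.empty((2, ages.size))
            for s_i, sex in enumerate(SEXES):
                for a_i, age in enumerate(ages):
                    mat[s_i, a_i] = rr_on_grid(spec, sex, int(age), self.grid)
                    exact[s_i, a_i] = rr_at_bmi(spec, sex, int(age), self.config.tmrel)
            self._rr_mat[disease] = mat
            self._rr_exact_tmrel[disease] = exact
        self._den: dict[str, np.ndarray] = {}

    def _rr_rows(self, disease: str, cycle: int) -> np.ndarray:
        """(stratum, grid) RR values at each cohort's age in a given cycle."""
        ages = np.clip(self.a0 + cycle, AGE_LO, MAX_RR_AGE) - AGE_LO
        return self._rr_mat[disease][self.sex_code, ages]

    def denominator(self, disease: str) -> np.ndarray:
        """Baseline RR-weighted mass per (stratum, cycle)."""
        if disease not in self._den:
            n_k = self.config.n_cycles
            den = np.empty((self.n_strata, n_k))
            for k in range(n_k):
                den[:, k] = np.einsum("sg,sg->s", self.w_base, self._rr_rows(disease, k))
            self._den[disease] = den
        return self._den[disease]

    def multiplier_matrix(
        self, trajectory: BMITrajectory, disease: str
    ) -> np.ndarray:
        """Lagged incidence multipliers per (stratum, cycle) for one disease.

        Cycle k (starting year t = start + k) uses the trajectory's
        distribution at the effective exposure year max(start, t + 1 - lag),
        which encodes both the end-of-cycle exposure convention and the
        neutral hold at the trajectory's start-year value before the lag
        completes.
        """
        cfg = self.config
        lag = self.inputs.epi[disease].lag_years
        n_k = cfg.n_cycles
        den = self.denominator(disease)
        num = np.empty_like(den)
        means = trajectory.means.reindex(self.index)
        sd = trajectory.sd.reindex(self.index).to_numpy(dtype=float)
        weight_cache: dict[int, np.ndarray] = {}
        for k in range(n_k):
            year = max(cfg.start_year, cfg.start_year + k + 1 - lag)
            if trajectory.degenerate:
                ages = np.clip(self.a0 + k, AGE_LO, MAX_RR_AGE) - AGE_LO
                num[:, k] = self._rr_exact_tmrel[disease][self.sex_code, ages]
            else:
                if year not in weight_cache:
                    weight_cache[year] = normal_weights(
                        means[year].to_numpy(dtype=float), sd, self.grid
                    )
                num[:, k] = np.einsum(
                    "sg,sg->s", weight_cache[year], self._rr_rows(disease, k)
                )
        return num / den


@dataclass
class MsltRun:
    """Output of one projection run under one trajectory."""

    scenario_id: str
    burden: pd.DataFrame  # outcome, disease_id, scenario_id, year, value
    life_table: pd.DataFrame  # sex, year, alive
    states: dict[str, dict[str, np.ndarray]] = field(repr=False, default_factory=dict)

    def period_total(self, outcome: str) -> float:
        sub = self.burden[self.burden["outcome"] == outcome]
        return float(sub["value"].sum())


def _age_resolved(values_by_sex: dict[str, np.ndarray], ctx: RunContext) -> np.ndarray:
    """Expand per-(sex, age) rate vectors to (stratum, cycle) at current age."""
    n_k = ctx.config.n_cycles
    out = np.empty((ctx.n_strata, n_k))
    stacked = np.stack([values_by_sex[sex] for sex in SEXES])  # (2, n_age)
    for k in range(n_k):
        ages = np.clip(ctx.a0 + k, AGE_LO, AGE_HI) - AGE_LO
        out[:, k] = stacked[ctx.sex_code, ages]
    return out


def _by_sex(frame: pd.DataFrame, column: str) -> dict[str, np.ndarray]:
    return {sex: frame.loc[sex, column].to_numpy(dtype=float) for sex in SEXES}


def run_mslt(
    inputs: ModelInputs,
    trajectory: BMITrajectory,
    context: RunContext | None = None,
) -> MsltRun:
    """Run the coupled main + 11 disease life tables under one trajectory.

    Returns absolute incident cases and disease deaths per disease and year
    (years label the end of each annual cycle, start_year+1 .. end_year,
    summed over strata) plus the main life table's alive counts.
    """
    ctx = context or RunContext(inputs)
    cfg = inputs.config
    n_k = cfg.n_cycles
    out_years = np.arange(cfg.start_year + 1, cfg.end_year + 1)

    mort = _age_resolved(_by_sex(inputs.population.data, "all_cause_mortality_rate"), ctx)

    # Cause-deleted background mortality for the main table and per-disease
    # other-cause mortality; prevalence x case fatality approximates each
    # disease's share of the all-cause rate.
    disease_mort_in = np.zeros_like(mort)
    per_disease: dict[str, dict[str, np.ndarray]] = {}
    rows = []
    for disease in DISEASES:
        epi = inputs.epi[disease]
        i_mat = _age_resolved(_by_sex(epi.data, "incidence"), ctx)
        r_mat = _age_resolved(_by_sex(epi.data, "remission"), ctx)
        f_mat = _age_resolved(_by_sex(epi.data, "case_fatality"), ctx)
        p_mat = _age_resolved(_by_sex(epi.data, "prevalence"), ctx)
        disease_mort_in += p_mat * f_mat
        per_disease[disease] = {"i": i_mat, "r": r_mat, "f": f_mat, "p": p_mat}

    results: dict[str, dict[str, np.ndarray]] = {}
    for disease in DISEASES:
        d = per_disease[disease]
        other = np.maximum(mort - d["p"] * d["f"], 0.0)
        mult = ctx.multiplier_matrix(trajectory, disease)
        prev0 = inputs.epi[disease].data["prevalence"].reindex(ctx.index).to_numpy()
        res = run_disease_lifetable(
            ctx.counts, prev0, d["i"], d["r"], d["f"], other, mult
        )
        results[disease] = res
        for outcome, key in (("cases", "new_cases"), ("deaths", "disease_deaths")):
            totals = res[key].sum(axis=0)
            rows.extend(
                {
                    "outcome": outcome,
                    "disease_id": disease,
                    "scenario_id": trajectory.scenario_id,
                    "year": int(y),
                    "value": float(v),
                }
                for y, v in zip(out_years, totals)
            )
    burden = pd.DataFrame(rows, columns=BURDEN_COLUMNS)

    # Main life table: cause-deleted all-cause mortality plus the disease
    # tables' evolving per-capita disease mortality.
    deleted = np.maximum(mort - disease_mort_in, 0.0)
    alive = np.empty((ctx.n_strata, n_k + 1))
    alive[:, 0] = ctx.counts
    for k in range(n_k):
        m_dis = np.zeros(ctx.n_strata)
        for disease in DISEASES:
            f_k = per_disease[disease]["f"][:, k]
            m_dis += results[disease]["prevalent_share"][:, k] * f_k
        q = 1.0 - np.exp(-(deleted[:, k] + m_dis))
        alive[:, k + 1] = alive[:, k] * (1.0 - q)
    lt_rows = []
    sex_labels = ctx.index.get_level_values("sex").to_numpy()
    for sex in SEXES:
        mask = sex_labels == sex
        for j, year in enumerate(range(cfg.start_year, cfg.end_year + 1)):
            lt_rows.append(
                {"sex": sex, "year": year, "alive": float(alive[mask, j].sum())}
            )
    life_table = pd.DataFrame(lt_rows)

    return MsltRun(trajectory.scenario_id, burden, life_table, results)


def attributable_burden(
    inputs: ModelInputs,
    trajectory: BMITrajectory,
    tmrel_run: MsltRun | None = None,
    context: RunContext | None = None,
) -> pd.DataFrame:
    """Burden attributable to overweight under one trajectory.

    Difference between the trajectory's run and the counterfactual run with
    BMI held at the TMREL (22 kg/m2) for all years; non-negative per
    disease/year under the floored relative-risk curves.
    """
    from .scenarios import tmrel_trajectory  # local import to avoid a cycle

    ctx = context or RunContext(inputs)
    if tmrel_run is None:
        tmrel_run = run_mslt(inputs, tmrel_trajectory(inputs.config, ctx.baseline), ctx)
    run = run_mslt(inputs, trajectory, ctx)
    key = ["outcome", "disease_id", "year"]
    merged = run.burden.merge(
        tmrel_run.burden[key + ["value"]], on=key, suffixes=("", "_tmrel")
    )
    merged["value"] = merged["value"] - merged["value_tmrel"]
    return merged[BURDEN_COLUMNS]
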