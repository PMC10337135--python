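"""Reading, writing and validating model inputs, plus the shipped fixture of
the published burden tables.

All tables are long/tidy UTF-8 CSVs with a mandatory header row; the config
is YAML mirroring :class:`~bmiburden.datatypes.ModelConfig` plus relative
paths to the four input CSVs.  Schema violations raise :class:`SchemaError`
naming the offending file, column or stratum.
"""
from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    CANCERS,
    DISEASES,
    SEXES,
    TOTAL_CANCER,
    DiseaseEpi,
    ModelConfig,
    ModelInputs,
    PopulationTable,
    RRBand,
    RRSpec,
    SchemaError,
    strata_index,
)
from .synthetic import steady_state_prevalence

__all__ = [
    "load_inputs",
    "write_inputs",
    "load_reported_burden",
    "validate_epi_consistency",
]

_POPULATION_COLS = ["sex", "age", "count", "all_cause_mortality_rate"]
_EPI_COLS = [
    "disease_id",
    "sex",
    "age",
    "incidence",
    "remission",
    "case_fatality",
    "prevalence",
]
_RR_COLS = [
    "disease_id",
    "form",
    "sex",
    "age_lo",
    "age_hi",
    "bmi_lo",
    "bmi_hi",
    "rr",
    "rr_low",
    "rr_high",
]
_BMI_COLS = ["sex", "age", "mean_bmi", "sd_bmi"]

_CONFIG_FIELDS = [
    "start_year",
    "end_year",
    "bau_annual_bmi_increase",
    "scenario1_annual_bmi_increase",
    "scenario2_prevalence_target",
    "scenario3_total_reduction",
    "scenario3_annual_step",
    "n_draws",
    "seed",
    "tmrel",
    "bmi_grid_lo",
    "bmi_grid_hi",
    "bmi_grid_step",
]


def _read_csv(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    return df


def _stratum_frame(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    bad_sex = set(df["sex"]) - set(SEXES)
    if bad_sex:
        raise SchemaError(f"{path.name}: unknown sex value(s) {sorted(bad_sex)}")
    out = df.set_index(["sex", "age"]).sort_index()
    if out.index.has_duplicates:
        dup = out.index[out.index.duplicated()][0]
        raise SchemaError(f"{path.name}: duplicate stratum {dup}")
    want = strata_index()
    gaps = want.difference(out.index)
    if len(gaps):
        raise SchemaError(f"{path.name}: stratum gap at {list(gaps[:4])}")
    return out.reindex(want)


def load_inputs(config_path: str | Path) -> ModelInputs:
    """Load and validate the full input bundle referenced by a YAML config."""
    config_path = Path(config_path)
    if not config_path.exists():
        raise SchemaError(f"{config_path}: config file not found")
    raw = yaml.safe_load(config_path.read_text())
    files = raw.get("inputs", {})
    for key in ("population", "disease_epi", "rr_spec", "bmi_baseline"):
        if key not in files:
            raise SchemaError(f"{config_path.name}: missing inputs.{key} entry")
    base = config_path.parent
    config = ModelConfig(**{k: raw[k] for k in _CONFIG_FIELDS if k in raw})

    pop_path = base / files["population"]
    pop = PopulationTable(
        _stratum_frame(_read_csv(pop_path, _POPULATION_COLS), pop_path)[
            ["count", "all_cause_mortality_rate"]
        ]
    )

    epi_path = base / files["disease_epi"]
    epi_df = _read_csv(epi_path, _EPI_COLS)
    unknown = set(epi_df["disease_id"]) - set(DISEASES)
    if unknown:
        raise SchemaError(f"{epi_path.name}: unknown disease_id {sorted(unknown)}")
    epi = {}
    for disease, sub in epi_df.groupby("disease_id"):
        epi[disease] = DiseaseEpi(
            disease,
            _stratum_frame(sub.drop(columns="disease_id"), epi_path)[
                ["incidence", "remission", "case_fatality", "prevalence"]
            ],
        )
    for disease in DISEASES:
        if disease not in epi:
            raise SchemaError(f"{epi_path.name}: no rows for disease {disease}")

    rr_path = base / files["rr_spec"]
    rr_df = _read_csv(rr_path, _RR_COLS)
    unknown = set(rr_df["disease_id"]) - set(DISEASES)
    if unknown:
        raise SchemaError(f"{rr_path.name}: unknown disease_id {sorted(unknown)}")
    rr_specs = {}
    for disease, sub in rr_df.groupby("disease_id"):
        forms = set(sub["form"])
        if len(forms) != 1:
            raise SchemaError(f"{rr_path.name}: {disease} mixes RR forms {sorted(forms)}")
        outside = None
        if "outside_rr" in sub.columns and sub["outside_rr"].notna().any():
            outside = float(sub["outside_rr"].dropna().iloc[0])
        bands = tuple(
            RRBand(
                rr=float(row.rr),
                rr_low=float(row.rr_low),
                rr_high=float(row.rr_high),
                sex=str(row.sex),
                age_lo=int(row.age_lo),
                age_hi=int(row.age_hi),
                bmi_lo=float(row.bmi_lo),
                bmi_hi=float(row.bmi_hi),
            )
            for row in sub.itertuples()
        )
        rr_specs[disease] = RRSpec(
            disease, forms.pop(), bands, tmrel=config.tmrel, outside_window_rr=outside
        )

    bmi_path = base / files["bmi_baseline"]
    bmi = _stratum_frame(_read_csv(bmi_path, _BMI_COLS), bmi_path)[
        ["mean_bmi", "sd_bmi"]
    ]

    return ModelInputs(
        population=pop, epi=epi, bmi_baseline=bmi, rr_specs=rr_specs, config=config
    )


def write_inputs(inputs: ModelInputs, out_dir: str | Path) -> Path:
    """Write the bundle as the documented CSV schemas plus a YAML config.

    Returns the path of the written config file; ``load_inputs`` on that path
    round-trips the bundle field by field.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    pop = inputs.population.data.reset_index()
    pop.to_csv(out_dir / "population.csv", index=False)

    epi_rows = []
    for disease in DISEASES:
        sub = inputs.epi[disease].data.reset_index()
        sub.insert(0, "disease_id", disease)
        epi_rows.append(sub)
    pd.concat(epi_rows).to_csv(out_dir / "disease_epi.csv", index=False)

    rr_rows = []
    for disease in DISEASES:
        spec = inputs.rr_specs[disease]
        for b in spec.bands:
            rr_rows.append(
                {
                    "disease_id": disease,
                    "form": spec.form,
                    "sex": b.sex,
                    "age_lo": b.age_lo,
                    "age_hi": b.age_hi,
                    "bmi_lo": b.bmi_lo,
                    "bmi_hi": b.bmi_hi,
                    "rr": b.rr,
                    "rr_low": b.rr_low,
                    "rr_high": b.rr_high,
                    "outside_rr": spec.outside_window_rr,
                }
            )
    pd.DataFrame(rr_rows).to_csv(out_dir / "rr_spec.csv", index=False)

    inputs.bmi_baseline.reset_index().to_csv(out_dir / "bmi_baseline.csv", index=False)

    cfg = {k: getattr(inputs.config, k) for k in _CONFIG_FIELDS}
    cfg["inputs"] = {
        "population": "population.csv",
        "disease_epi": "disease_epi.csv",
        "rr_spec": "rr_spec.csv",
        "bmi_baseline": "bmi_baseline.csv",
    }
    config_path = out_dir / "config.yaml"
    config_path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return config_path


def load_reported_burden() -> pd.DataFrame:
    """The published period-total burden tables shipped as an in-repo fixture.

    Cases and deaths of the 11 diseases (plus the printed cancer subtotal)
    attributable to overweight over 2019-2030 per scenario, with their 95%
    CIs as printed.  Two garbled value cells and two garbled CI cells are
    repaired as documented in the fixture header; repaired cells carry a
    non-empty ``flag``.
    """
    ref = importlib.resources.files("bmiburden.data") / "reported_burden.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, comment="#")
    df["flag"] = df["flag"].fillna("")
    return df


def validate_epi_consistency(
    epi: DiseaseEpi,
    pop: PopulationTable,
    ratio_band: float = 3.0,
    abs_tol: float = 0.005,
) -> list[str]:
    """Internal-consistency findings for one disease's rates.

    A light-weight stand-in for a full rate-balancing adjustment: flags
    (a) rates that do not convert to valid annual probabilities,
    (b) non-zero remission outside the cancers,
    (c) prevalence grossly inconsistent with the illness-death steady state
    implied by incidence, remission and case fatality (ratio outside
    [1/ratio_band, ratio_band], ignoring strata where both are < abs_tol).
    Returns an empty list for a consistent table.
    """
    findings: list[str] = []
    data = epi.data
    for col in ("incidence", "remission", "case_fatality"):
        if (data[col] < 0).any():
            findings.append(f"{epi.disease_id}: negative {col} rate")
    if (pop.data["all_cause_mortality_rate"] < 0).any():
        findings.append("population: negative all-cause mortality rate")
    if ((data["prevalence"] < 0) | (data["prevalence"] > 1)).any():
        findings.append(f"{epi.disease_id}: prevalence outside [0, 1]")

    if epi.disease_id not in CANCERS and (data["remission"] > 0).any():
        findings.append(f"{epi.disease_id}: non-zero remission for non-cancer")

    expected = steady_state_prevalence(
        data["incidence"].to_numpy(),
        data["remission"].to_numpy(),
        data["case_fatality"].to_numpy(),
    )
    observed = data["prevalence"].to_numpy()
    material = (observed > abs_tol) | (expected > abs_tol)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(expected > 0, observed / expected, np.inf)
    bad = material & ((ratio > ratio_band) | (ratio < 1.0 / ratio_band))
    if bad.any():
        stratum = data.index[bad][0]
        findings.append(
            f"{epi.disease_id}: prevalence inconsistent with illness-death "
            f"steady state at {len(np.flatnonzero(bad))} strata "
            f"(first: {stratum}, observed {observed[bad][0]:.4g}, "
            f"steady-state {expected[bad][0]:.4g})"
        )
    return findings
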