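"""Aggregation of burden tables into headline quantities.

Totals per scenario (with the cancer subtotal), averted burden relative to
business-as-usual, disease-group shares and per-year trend series - the
quantities the published tables print - plus an arithmetic verification of
the shipped fixture of those tables.  Internal arithmetic is unrounded;
rounding (counts to integers, shares to one decimal) happens only at
presentation.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    CANCERS,
    CARDIOVASCULAR,
    DISEASES,
    NON_CANCERS,
    TOTAL,
    TOTAL_CANCER,
)

__all__ = [
    "aggregate_totals",
    "averted",
    "shares",
    "trend_series",
    "verify_reported_identities",
    "DEFAULT_GROUPING",
]

#: Reporting groups used for shares: the three cardiovascular diseases are
#: one group, every other disease stands alone.
DEFAULT_GROUPING: dict[str, tuple[str, ...]] = {
    "cardiovascular": CARDIOVASCULAR,
    **{d: (d,) for d in DISEASES if d not in CARDIOVASCULAR},
}


def _scenario_col(burden: pd.DataFrame) -> str:
    for name in ("scenario_id", "scenario"):
        if name in burden.columns:
            return name
    raise KeyError("burden table has no scenario column")


def aggregate_totals(burden: pd.DataFrame) -> pd.DataFrame:
    """Period totals per outcome and scenario, with the cancer subtotal.

    TOTAL_CANCER is the sum over the five cancers (or the table's own
    subtotal rows when present, as in the shipped fixture); TOTAL is the sum
    of the six non-cancer diseases plus TOTAL_CANCER.  Year columns, if
    present, are summed over.  Raises if any of the 11 diseases is missing.
    """
    scen = _scenario_col(burden)
    missing = set(DISEASES) - set(burden["disease_id"])
    if missing:
        raise ValueError(f"burden table missing disease(s) {sorted(missing)}")
    sums = burden.groupby(["outcome", scen, "disease_id"])["value"].sum()

    rows = []
    for (outcome, scenario), sub in sums.groupby(level=[0, 1]):
        sub = sub.droplevel([0, 1])
        cancer = (
            float(sub[TOTAL_CANCER])
            if TOTAL_CANCER in sub.index
            else float(sub[list(CANCERS)].sum())
        )
        total = float(sub[list(NON_CANCERS)].sum()) + cancer
        rows.append((outcome, scenario, TOTAL_CANCER, cancer))
        rows.append((outcome, scenario, TOTAL, total))
    return pd.DataFrame(rows, columns=["outcome", scen, "disease_id", "value"])


def averted(burden: pd.DataFrame) -> pd.DataFrame:
    """Averted burden: BAU minus scenario, per disease plus both totals.

    Requires a BAU column partner for every scenario; averted values for BAU
    itself are identically zero and included for the neutrality identity.
    """
    scen = _scenario_col(burden)
    if "BAU" not in set(burden[scen]):
        raise ValueError("burden table has no BAU scenario to difference against")
    per_disease = burden[burden["disease_id"].isin(DISEASES)].groupby(
        ["outcome", scen, "disease_id"]
    )["value"].sum()
    totals = aggregate_totals(burden).set_index(["outcome", scen, "disease_id"])["value"]
    combined = pd.concat([per_disease, totals])
    wide = combined.unstack(scen)
    diff = wide.sub(wide["BAU"], axis=0).mul(-1)
    out = diff.stack().rename("averted").reset_index()
    out.columns = ["outcome", "disease_id", scen, "averted"]
    return out


def shares(
    burden: pd.DataFrame, grouping: dict[str, tuple[str, ...]] | None = None
) -> pd.DataFrame:
    """Percent of the scenario total per disease group, one decimal place.

    The grouping must partition the 11 diseases exactly.
    """
    grouping = grouping or DEFAULT_GROUPING
    members = [d for group in grouping.values() for d in group]
    if sorted(members) != sorted(DISEASES):
        raise ValueError("grouping must partition the 11 diseases exactly")
    scen = _scenario_col(burden)
    per_disease = burden.groupby(["outcome", scen, "disease_id"])["value"].sum()
    per_disease = per_disease[
        per_disease.index.get_level_values("disease_id").isin(DISEASES)
    ]
    totals = per_disease.groupby(level=[0, 1]).sum()
    rows = []
    for (outcome, scenario), total in totals.items():
        for name, group in grouping.items():
            value = per_disease.loc[outcome, scenario].reindex(list(group)).sum()
            rows.append(
                (outcome, scenario, name, round(100.0 * float(value) / float(total), 1))
            )
    return pd.DataFrame(rows, columns=["outcome", scen, "group", "share_pct"])


def trend_series(burden: pd.DataFrame, cumulative: bool = True) -> pd.DataFrame:
    """Per-year total cases/deaths per scenario (the published trend figure).

    Returns a long frame outcome x scenario x year; cumulative sums are
    nondecreasing in year by construction.
    """
    scen = _scenario_col(burden)
    if "year" not in burden.columns:
        raise ValueError("trend_series needs a per-year burden table")
    only = burden[burden["disease_id"].isin(DISEASES)]
    yearly = (
        only.groupby(["outcome", scen, "year"])["value"].sum().rename("value").reset_index()
    )
    if cumulative:
        yearly["value"] = yearly.groupby(["outcome", scen])["value"].cumsum()
    return yearly


def plot_trends(trend: pd.DataFrame, path: str) -> str:
    """Save a two-panel cumulative cases/deaths trend figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scen = _scenario_col(trend)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    for ax, outcome in zip(axes, ("cases", "deaths")):
        sub = trend[trend["outcome"] == outcome]
        for sid, lines in sub.groupby(scen):
            ax.plot(lines["year"], lines["value"], label=sid)
        ax.set_title(f"Attributable {outcome}")
        ax.set_xlabel("year")
        ax.set_ylabel("persons (cumulative)")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def verify_reported_identities(fixture: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic identities of the published tables, checked on the fixture.

    Each row: an identity name, the expected (printed) value, the value
    recomputed from the fixture cells, and whether they agree exactly.
    """
    checks = []

    def add(name, expected, got):
        checks.append(
            {"identity": name, "expected": expected, "got": got, "ok": expected == got}
        )

    totals = aggregate_totals(fixture).set_index(["outcome", "scenario", "disease_id"])[
        "value"
    ]
    printed_totals = {
        ("cases", "BAU"): 669100,
        ("cases", "S1"): 661975,
        ("cases", "S2"): 659010,
        ("cases", "S3"): 644135,
        ("deaths", "BAU"): 117348,
        ("deaths", "S1"): 115897,
        ("deaths", "S2"): 115279,
        ("deaths", "S3"): 112275,
    }
    for (outcome, sid), value in printed_totals.items():
        add(f"total {outcome} {sid}", value, int(round(totals[outcome, sid, TOTAL])))

    cancer_cells = fixture[fixture["disease_id"].isin(CANCERS)]
    subtotal = fixture[fixture["disease_id"] == TOTAL_CANCER]
    for (outcome, sid), sub in cancer_cells.groupby(["outcome", "scenario"]):
        printed = subtotal[
            (subtotal["outcome"] == outcome) & (subtotal["scenario"] == sid)
        ]["value"].iloc[0]
        add(f"cancer subtotal {outcome} {sid}", int(printed), int(sub["value"].sum()))

    av = averted(fixture).set_index(["outcome", "disease_id", "scenario"])["averted"]
    printed_averted = {
        ("cases", "S1"): 7125,
        ("cases", "S2"): 10090,
        ("cases", "S3"): 24965,
        ("deaths", "S1"): 1451,
        ("deaths", "S2"): 2069,
        ("deaths", "S3"): 5073,
    }
    for (outcome, sid), value in printed_averted.items():
        add(f"averted {outcome} {sid}", value, int(round(av[outcome, TOTAL, sid])))

    sh = shares(fixture).set_index(["outcome", "scenario", "group"])["share_pct"]
    add("CVD share of BAU deaths (%)", 58.5, float(sh["deaths", "BAU", "cardiovascular"]))
    add(
        "diabetes share of BAU deaths (%)",
        18.6,
        float(sh["deaths", "BAU", "type2_diabetes"]),
    )
    return pd.DataFrame(checks)
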