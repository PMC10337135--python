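"""Aggregation layer on the published fixture and on synthetic runs."""
import numpy as np
import pandas as pd
import pytest

from bmiburden.datatypes import DISEASES, TOTAL, TOTAL_CANCER
from bmiburden.reporting import (
    DEFAULT_GROUPING,
    aggregate_totals,
    averted,
    shares,
    trend_series,
    verify_reported_identities,
)


@pytest.fixture(scope="module")
def fixture_totals(reported):
    return aggregate_totals(reported).set_index(["outcome", "scenario", "disease_id"])[
        "value"
    ]


def test_fixture_totals_match_printed_headlines(fixture_totals):
    assert fixture_totals["cases", "BAU", TOTAL] == 669100
    assert fixture_totals["deaths", "S3", TOTAL] == 112275
    assert fixture_totals["deaths", "BAU", TOTAL_CANCER] == 6739


def test_aggregation_is_order_independent_and_idempotent(reported):
    shuffled = reported.sample(frac=1.0, random_state=3)
    a = aggregate_totals(reported).sort_values(
        ["outcome", "scenario", "disease_id"]
    ).reset_index(drop=True)
    b = aggregate_totals(shuffled).sort_values(
        ["outcome", "scenario", "disease_id"]
    ).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)


def test_missing_disease_is_an_aggregation_error(reported):
    broken = reported[reported.disease_id != "stroke"]
    with pytest.raises(ValueError, match="stroke"):
        aggregate_totals(broken)


def test_fixture_averted_matches_printed_reductions(reported):
    av = averted(reported).set_index(["outcome", "disease_id", "scenario"])["averted"]
    assert av["cases", TOTAL, "S3"] == 24965
    assert av["cases", TOTAL, "S1"] == 7125
    assert av["cases", TOTAL, "S2"] == 10090
    assert av["deaths", TOTAL, "S1"] == 1451
    assert av["deaths", TOTAL, "S2"] == 2069
    assert av["deaths", TOTAL, "S3"] == 5073
    assert (av.xs("BAU", level="scenario") == 0).all()


def test_averted_requires_a_bau_partner(reported):
    with pytest.raises(ValueError, match="BAU"):
        averted(reported[reported.scenario != "BAU"])


def test_fixture_shares_match_printed_percentages(reported):
    sh = shares(reported).set_index(["outcome", "scenario", "group"])["share_pct"]
    assert sh["deaths", "BAU", "cardiovascular"] == 58.5
    assert sh["deaths", "BAU", "type2_diabetes"] == 18.6


def test_single_group_partition_is_all_of_it(reported):
    sh = shares(reported, {"all": DISEASES})
    assert (sh["share_pct"] == 100.0).all()


def test_non_partition_grouping_raises(reported):
    with pytest.raises(ValueError, match="partition"):
        shares(reported, {"cvd": ("stroke",)})


def test_partition_shares_sum_to_one_hundred(reported):
    sh = shares(reported, DEFAULT_GROUPING)
    sums = sh.groupby(["outcome", "scenario"])["share_pct"].sum()
    np.testing.assert_allclose(sums, 100.0, atol=0.1)


def test_every_identity_of_the_published_tables_holds(reported):
    table = verify_reported_identities(reported)
    assert table["ok"].all(), table[~table.ok]


class TestTrendsOnSyntheticRuns:
    def test_cumulative_series_nondecreasing(self, scenario_runs):
        burden = pd.concat([r.burden for r in scenario_runs.values()])
        trend = trend_series(burden)
        for _, sub in trend.groupby(["outcome", "scenario_id"]):
            values = sub.sort_values("year")["value"].to_numpy()
            assert (np.diff(values) >= -1e-9).all()

    def test_scenarios_identical_before_shortest_lag(self, scenario_runs):
        burden = pd.concat([r.burden for r in scenario_runs.values()])
        trend = trend_series(burden, cumulative=False)
        early = trend[trend.year <= 2024].pivot_table(
            index=["outcome", "year"], columns="scenario_id", values="value"
        )
        for sid in ("S1", "S2", "S3"):
            np.testing.assert_allclose(early[sid], early["BAU"], rtol=1e-9)

    def test_scenario_ordering_after_lag(self, scenario_runs):
        burden = pd.concat([r.burden for r in scenario_runs.values()])
        trend = trend_series(burden).query("year == 2030")
        wide = trend.pivot_table(
            index="outcome", columns="scenario_id", values="value"
        )
        for outcome in ("cases", "deaths"):
            row = wide.loc[outcome]
            assert row["BAU"] > row["S1"] > row["S2"] > row["S3"]
            # S1 closest to BAU, S3 the deepest reduction
            assert row["BAU"] - row["S1"] < row["BAU"] - row["S2"] < row["BAU"] - row["S3"]
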