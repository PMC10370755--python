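"""Fiscal-year assignment, deduplication, inflation, and cost aggregates."""

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from exclink import (
    CPISeries,
    LagPolicy,
    assign_project_year,
    dedupe,
    inflation_adjust,
    lag_sensitivity,
    load_universe,
    run_pipeline,
    simulate_universe,
    SimConfig,
)
from exclink.attribute import AttributionError, attribute_project_years


@pytest.mark.parametrize(
    "pub_year, first_fy, last_fy, expected",
    [
        (2012, 2005, 2010, 2010),  # 2 years after end -> last funded year
        (2003, 2005, 2010, None),  # pre-funding -> excluded
        (2015, 2005, 2010, None),  # lag 5 exceeds the 4-year window
        (2007, 2005, 2010, 2007),  # inside the funded span -> own year
        (2014, 2005, 2010, 2010),  # exactly max_lag years after -> included
    ],
)
def test_assignment_rule(pub_year, first_fy, last_fy, expected):
    assert assign_project_year(pub_year, first_fy, last_fy, LagPolicy(4)) == expected


def test_inverted_span_is_a_data_error():
    with pytest.raises(AttributionError):
        assign_project_year(2010, 2012, 2008)


def test_pre_funding_assignment_when_exclusion_disabled():
    policy = LagPolicy(4, pre_funding_exclude=False)
    assert assign_project_year(2003, 2005, 2010, policy) == 2005


@given(
    pub_year=st.integers(1990, 2030),
    first_fy=st.integers(2000, 2019),
    span=st.integers(0, 10),
    max_lag=st.integers(0, 10),
)
@settings(deadline=None)
def test_assignment_is_total_and_in_span(pub_year, first_fy, span, max_lag):
    last_fy = first_fy + span
    fy = assign_project_year(pub_year, first_fy, last_fy, LagPolicy(max_lag))
    if fy is not None:
        assert first_fy <= fy <= last_fy


def test_dedupe_merges_pmids_on_same_project_year():
    rows = pd.DataFrame(
        {
            "core_project_number": ["G1", "G1", "G1"],
            "fiscal_year": [2012, 2012, 2013],
            "pmid": ["P1", "P2", "P3"],
            "research_class": ["basic", "applied", "basic"],
        }
    )
    out = dedupe(rows)
    assert len(out) == 2
    merged = out.loc[out["fiscal_year"] == 2012].iloc[0]
    assert merged["supporting_pmids"] == frozenset({"P1", "P2"})
    assert merged["research_class"] == "applied"  # any applied publication wins
    assert out.loc[out["fiscal_year"] == 2013, "research_class"].iloc[0] == "basic"


def test_dedupe_is_idempotent():
    rows = pd.DataFrame(
        {
            "core_project_number": ["G1", "G1", "G2"],
            "fiscal_year": [2012, 2012, 2012],
            "pmid": ["P1", "P2", "P1"],
            "research_class": ["basic", "basic", "applied"],
        }
    )
    once = dedupe(rows)
    twice = dedupe(once)
    pd.testing.assert_frame_equal(once, twice)


def test_inflation_adjustment():
    cpi = CPISeries({2000: 200.0, 2018: 250.0}, base_year=2018)
    assert inflation_adjust(100_000, 2018, cpi) == 100_000  # base-year identity
    assert inflation_adjust(100_000, 2000, cpi) == 125_000  # 1000 * 250/200
    with pytest.raises(KeyError, match="1999"):
        inflation_adjust(100_000, 1999, cpi)


@given(cents=st.integers(0, 10**12), idx=st.floats(50.0, 260.0))
@settings(deadline=None)
def test_inflation_round_trip_within_a_cent(cents, idx):
    cpi = CPISeries({2010: idx, 2018: 260.0}, base_year=2018)
    back = CPISeries({2010: 260.0, 2018: idx}, base_year=2018)
    adjusted = inflation_adjust(cents, 2010, cpi)
    recovered = inflation_adjust(adjusted, 2010, back)
    assert abs(recovered - cents) <= 1


def test_cost_aggregates_small_worked_example(small_inputs):
    # G1 funded 2010-2011, attributed 2010 & 2011; G2 funded 2012-2013,
    # attributed 2012 & 2013; G3 funded 2005 only, P5 (2014) lags 9 years
    # past it and is excluded, so G3 contributes nothing.
    universe = load_universe(small_inputs)
    result = run_pipeline(universe)
    block = result.all_research
    assert block.project_years.total == 4
    assert block.projects.total == 2
    assert block.pmids.total == 4
    assert block.project_year_cost_cents.total == (100 + 150 + 200 + 250) * 100
    assert block.total_project_cost_cents.total == block.project_year_cost_cents.total


def test_attributed_year_missing_from_cost_table_is_fatal(tmp_path):
    from .conftest import write_tables

    # G1 funded only 2010 and 2012 (a gap); P2 published 2011 would be
    # attributed to 2011, which has no cost record.
    d = write_tables(
        tmp_path,
        {
            "projects.csv": "core_project_number,fiscal_year,cost_usd\n"
            "G1,2010,100.00\nG1,2012,100.00\nG2,2012,200.00\nG2,2013,250.00\n"
            "G3,2005,300.00\n"
        },
    )
    universe = load_universe(d)
    with pytest.raises(AttributionError, match="cost table"):
        attribute_project_years(universe)


def test_class_additivity_to_the_cent_on_synthetic_universe():
    universe, _ = simulate_universe(SimConfig(seed=21, n_projects=120))
    result = run_pipeline(universe)
    for block in (result.all_research, result.patent_linked):
        for name in ("pmids", "project_years", "project_year_cost_cents", "projects", "total_project_cost_cents"):
            cv = getattr(block, name)
            assert cv.total == cv.applied + cv.basic


def test_project_year_counts_monotone_in_lag_window():
    universe, _ = simulate_universe(SimConfig(seed=22, n_projects=120))
    counts = lag_sensitivity(universe, max_lags=range(0, 5))
    values = [counts[lag] for lag in range(0, 5)]
    assert values == sorted(values)
    assert values[-1] > values[0]  # the lag branch is actually exercised
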