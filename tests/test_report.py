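"""Percentage rendering, ledger assembly, consistency, and determinism."""

import pandas as pd
import pytest

from exclink import (
    RunConfig,
    SimConfig,
    percent,
    read_ledger,
    run_pipeline,
    simulate_universe,
    write_ledger,
)
from exclink.report import LedgerError, render_table2, render_table3


@pytest.mark.parametrize(
    "num, den, kwargs, rendered",
    [
        (34, 313, {"decimals": 1}, "10.9%"),
        (119, 3644, {"decimals": 1}, "3.3%"),
        (769, 341375, {"sig": 2}, "0.23%"),
        (7, 7, {"decimals": 0}, "100%"),
        (546, 4030, {"decimals": 0}, "14%"),  # 13.548 rounds half-away to 14
        (0, 100, {"sig": 2}, "0.00%"),
        (0, 0, {"decimals": 1}, "NA"),
    ],
)
def test_percent_rendering(num, den, kwargs, rendered):
    raw, cell = percent(num, den, **kwargs)
    assert cell == rendered
    if den:
        assert raw == pytest.approx(100 * num / den)
    else:
        assert raw is None


def test_percent_requires_exactly_one_precision_mode():
    with pytest.raises(ValueError):
        percent(1, 2)
    with pytest.raises(ValueError):
        percent(1, 2, decimals=1, sig=2)


def test_every_rendered_cell_recomputes_from_its_own_marginals():
    # Ledger self-consistency on a random universe: each percentage cell
    # equals percent() of the numerator and denominator cells beside it.
    universe, _ = simulate_universe(SimConfig(seed=17, n_projects=150, p_cite=0.15))
    ledger = run_pipeline(universe).ledger
    t2 = render_table2(ledger)
    for _, row in t2.iterrows():
        if row["quantity"] == "searches":
            continue
        num_a, num_b = float(row["applied_raw"]), float(row["basic_raw"])
        _, cell_a = percent(num_a, num_a + num_b, decimals=0)
        _, cell_b = percent(num_b, num_a + num_b, decimals=0)
        assert row["applied_pct"] == cell_a
        assert row["basic_pct"] == cell_b
    t3 = render_table3(ledger)
    cents = {
        "project_year_cost_musd": "project_year_cost_cents",
        "total_project_cost_musd": "total_project_cost_cents",
    }
    for _, row in t3.iterrows():
        field = cents.get(row["quantity"], row["quantity"])
        num = getattr(ledger.patent_linked, field).get(row["slice"])
        den = getattr(ledger.all_research, field).get(row["slice"])
        _, cell = percent(num, den, sig=2)
        assert row["pct"] == cell


def test_ledger_rejects_inconsistent_blocks(fixture_result):
    import dataclasses

    from exclink import build_tables

    good = fixture_result.ledger
    counts = {
        "n_drugs_total": good.n_drugs_total,
        "n_drugs_in_patent_db": good.n_drugs_in_patent_db,
        "n_drugs_with_citation": good.n_drugs_with_citation,
        "n_cited_patents": good.n_cited_patents,
        "n_nih_cited_patents_any": good.n_nih_cited_patents_any,
        "n_drugs_matched_any": good.n_drugs_matched_any,
        "n_drugs_matched_linked": good.n_drugs_matched_linked,
    }
    # patent-linked larger than all-research must be rejected
    with pytest.raises(LedgerError, match="exceeds"):
        build_tables(counts, good.patent_linked, dataclasses.replace(
            good.patent_linked,
            pmids=dataclasses.replace(good.patent_linked.pmids, applied=10**9),
        ))


def test_ledger_write_is_byte_deterministic_and_round_trips(tmp_path, fixture_result):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_ledger(fixture_result.ledger, d1)
    write_ledger(fixture_result.ledger, d2)
    for name in ("table1.csv", "table2.csv", "table3.csv"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
    assert read_ledger(d1) == fixture_result.ledger


def test_empty_universe_renders_na_percentages(tmp_path):
    from .conftest import write_tables
    from exclink import load_universe

    d = write_tables(
        tmp_path,
        {
            "publications.csv": "pmid,pub_year,matched_drug_ids,matched_target_ids\n",
            "links.csv": "pmid,core_project_number\n",
            "patents.csv": "patent_number,core_project_number\n",
            "citations.csv": "drug_id,patent_number,source\n",
        },
    )
    ledger = run_pipeline(load_universe(d)).ledger
    t3 = render_table3(ledger)
    assert set(t3["pct"]) == {"NA"}
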