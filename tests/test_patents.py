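"""Exclusivity-patent joins in both modes and the patent-linked funding block."""

import pandas as pd
import pytest

from exclink import (
    JoinMode,
    SimConfig,
    join_exclusivity_patents,
    normalize_patent_number,
    run_pipeline,
    simulate_universe,
)

STRESS = dict(p_cite=0.15)  # citation rate raised so joins are non-trivial


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("US7654321B2", "7654321"),
        (" 7,654,321 ", "7654321"),
        ("us7654321", "7654321"),
        ("NP001", "NP001"),  # non-numeric identifiers survive intact
    ],
)
def test_patent_number_normalization(raw, expected):
    assert normalize_patent_number(raw) == expected


def test_empty_intersection_is_a_valid_result():
    patents = pd.DataFrame(
        {"patent_number": ["111"], "core_project_number": ["G1"]}
    )
    citations = pd.DataFrame(
        {"drug_id": ["D1"], "patent_number": ["999"], "source": ["orange_book"]}
    )
    result = join_exclusivity_patents(patents, citations, JoinMode.ANY_REPORT)
    assert result.matched_patents == frozenset()
    assert result.matched_drugs == frozenset()


def test_join_matches_across_formatting_differences():
    patents = pd.DataFrame(
        {"patent_number": ["US7654321B2"], "core_project_number": ["G1"]}
    )
    citations = pd.DataFrame(
        {"drug_id": ["D1"], "patent_number": ["7,654,321"], "source": ["orange_book"]}
    )
    result = join_exclusivity_patents(patents, citations, JoinMode.ANY_REPORT)
    assert result.matched_patents == frozenset({"7654321"})
    assert result.matched_drugs == frozenset({"D1"})


@pytest.mark.parametrize("seed", range(1, 6))
def test_publication_linked_is_subset_of_any_report(seed):
    universe, _ = simulate_universe(SimConfig(seed=seed, n_projects=150, **STRESS))
    result = run_pipeline(universe)
    assert result.join_linked.matched_patents <= result.join_any.matched_patents
    assert result.join_linked.matched_drugs <= result.join_any.matched_drugs
    assert result.join_linked.n_drugs <= result.join_any.n_drugs


def test_matched_drugs_are_all_in_patent_database():
    universe, _ = simulate_universe(SimConfig(seed=8, n_projects=150, **STRESS))
    result = run_pipeline(universe)
    in_db = set(universe.drugs.loc[universe.drugs["in_patent_db"], "drug_id"])
    assert set(result.join_any.matched_drugs) <= in_db


def test_patent_linked_block_never_exceeds_universe_block():
    # Brute-force bound: the patent-linked block is a filter-and-sum of the
    # all-research block, so every cell is bounded by its universe twin.
    for seed in range(3, 8):
        universe, _ = simulate_universe(SimConfig(seed=seed, n_projects=100, **STRESS))
        result = run_pipeline(universe)
        for name in (
            "pmids",
            "project_years",
            "project_year_cost_cents",
            "projects",
            "total_project_cost_cents",
        ):
            linked = getattr(result.patent_linked, name)
            full = getattr(result.all_research, name)
            assert linked.applied <= full.applied
            assert linked.basic <= full.basic


def test_fully_matched_single_project_equals_its_own_aggregate(fixture_result):
    # In the marginal fixture every linked project owns a matched patent, so
    # the patent-linked block coincides with the all-research block.
    assert (
        fixture_result.patent_linked.project_year_cost_cents
        == fixture_result.all_research.project_year_cost_cents
    )
    assert fixture_result.patent_linked.projects == fixture_result.all_research.projects


def test_audit_trail_links_patent_to_projects_and_drugs(tmp_path):
    from exclink import run, write_simulation

    universe, gt = simulate_universe(SimConfig(seed=13, n_projects=150, **STRESS))
    write_simulation(universe, gt, tmp_path / "in")
    result = run(tmp_path / "in", tmp_path / "out")
    audit = pd.read_csv(tmp_path / "out" / "matched_patents.csv", dtype=str)
    linked = audit.loc[audit["mode"] == "publication_linked"]
    assert set(linked["patent_number"]) == set(result.join_linked.matched_patents)
    for _, row in linked.iterrows():
        assert row["core_project_numbers"]  # every matched patent names its projects
        assert row["class"] in {"applied", "basic"}
        assert row["drug_ids"]
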