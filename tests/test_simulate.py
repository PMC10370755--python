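"""Synthetic-universe generator: seed contract, degenerate configs,
distributional sanity, and exact ground-truth recovery."""

import hashlib
import math
from pathlib import Path

import numpy as np
import pytest

from exclink import (
    RunConfig,
    SimConfig,
    load_universe,
    run_pipeline,
    simulate_universe,
    write_simulation,
)


def _dir_hashes(directory: Path) -> list[str]:
    return [
        hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(directory.iterdir())
    ]


def test_same_seed_gives_identical_files(tmp_path):
    for sub in ("a", "b"):
        universe, gt = simulate_universe(SimConfig(seed=1, n_projects=80))
        write_simulation(universe, gt, tmp_path / sub)
    assert _dir_hashes(tmp_path / "a") == _dir_hashes(tmp_path / "b")


def test_different_seeds_differ(tmp_path):
    u1, _ = simulate_universe(SimConfig(seed=1, n_projects=80))
    u2, _ = simulate_universe(SimConfig(seed=2, n_projects=80))
    assert not u1.publications.equals(u2.publications)


def test_generated_universe_satisfies_load_invariants(tmp_path):
    universe, gt = simulate_universe(SimConfig(seed=4, n_projects=80, p_cite=0.15))
    write_simulation(universe, gt, tmp_path)
    reloaded = load_universe(tmp_path)  # raises on any violated invariant
    assert reloaded.counts() == universe.counts()


def test_zero_patent_rate_gives_all_zero_patent_block():
    cfg = SimConfig(
        seed=5, patent_rate_applied=0, patent_rate_basic=0, patent_rate_unlinked=0
    )
    universe, gt = simulate_universe(cfg)
    assert len(universe.patents) == 0
    assert gt.patent_linked_py_cost_pct() == 0.0
    result = run_pipeline(universe)
    assert result.patent_linked.project_years.total == 0
    assert result.patent_linked.patents.total == 0


def test_zero_drug_match_probability_gives_all_basic():
    universe, gt = simulate_universe(SimConfig(seed=6, p_drug_match=0.0))
    result = run_pipeline(universe)
    assert gt.all_research.pmids.applied == 0
    assert result.all_research.pmids.applied == 0
    assert result.all_research.project_year_cost_cents.applied == 0
    assert result.all_research.projects.applied == 0


def test_infeasible_config_rejected():
    with pytest.raises(ValueError, match="infeasible"):
        simulate_universe(SimConfig(n_projects=0, pubs_per_project_year=1.0))


def test_exact_ground_truth_recovery_across_seeds():
    # The pipeline is deterministic accounting, so recovery is exact, not
    # approximate: every per-class count, cost sum, and matched-patent set
    # must equal the generator's independent bookkeeping.
    for seed in range(1, 11):
        cfg = SimConfig(seed=seed, n_projects=150, p_cite=0.15)
        universe, gt = simulate_universe(cfg)
        result = run_pipeline(universe, RunConfig(max_lag_years=cfg.max_lag_years))
        assert result.all_research == gt.all_research
        assert result.patent_linked == gt.patent_linked
        assert result.join_any.matched_patents == gt.matched_patents_any
        assert result.join_linked.matched_patents == gt.matched_patents_linked
        assert result.join_any.n_drugs == gt.n_drugs_matched_any
        assert result.join_linked.n_drugs == gt.n_drugs_matched_linked


def test_excluded_fraction_matches_lag_tail_mass():
    # Single-year projects make the funded year equal the final year, so a
    # link is excluded exactly when its lag exceeds max_lag_years; over many
    # seeds the excluded fraction must sit within 3 Monte-Carlo standard
    # errors of the configured tail mass.
    cfg_base = dict(
        n_drugs=60,
        n_projects=120,
        project_duration_mean=1.0,
        project_start_range=(2000, 2012),
        p_second_link=0.0,
    )
    tail = sum(SimConfig().lag_probs[SimConfig().max_lag_years + 1 :])
    excluded = total = 0
    for seed in range(100, 121):
        _, gt = simulate_universe(SimConfig(seed=seed, **cfg_base))
        excluded += gt.n_links_excluded
        total += gt.n_links
    frac = excluded / total
    se = math.sqrt(tail * (1 - tail) / total)
    assert abs(frac - tail) <= 3 * se


def test_applied_share_recovers_drug_match_probability():
    q = 0.3
    counts = np.zeros(2)
    for seed in range(200, 215):
        _, gt = simulate_universe(SimConfig(seed=seed, p_drug_match=q, n_projects=100))
        counts += (gt.all_research.pmids.applied, gt.all_research.pmids.total)
    share = counts[0] / counts[1]
    se = math.sqrt(q * (1 - q) / counts[1])
    # attribution drops a class-independent subset of publications, so the
    # applied share of surviving publications estimates q
    assert abs(share - q) <= 4 * se
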