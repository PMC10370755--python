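"""Deterministic reference fixture reproducing the study's printed marginals.

:func:`make_marginal_fixture` builds a small synthetic universe whose
aggregate marginals reproduce, through the full pipeline, the published
summary counts of the 2010-2019 drug-approval funding study at the count
level: 356 approved drugs of which 313 appear in the patent database and
297 carry at least one cited patent; 3,644 cited patents of which 119 are
NIH-funded (104 reachable through drug/target publications) protecting
34 (respectively 29) drugs; and the full patent-linked funding block
(104 patents split 61/43 applied/basic, 4,030 publications, 769 project
years, $954.0M project-year costs, 120 projects, $1,142.3M total costs).

The universe is synthetic: its drug, project, and patent identifiers are
invented, and its CPI series is flat (index 100 every year) so that the
dollar amounts encoded at table granularity pass through inflation
adjustment unchanged.

:func:`published_marginals` carries the study-scale printed summary
counts (350k publications, $164B project-year costs, ...) as reference
input data; those totals derive from licensed databases and are not
reproducible record-by-record, so they enter percentage computations as
numerators/denominators only.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import io as uio
from .model import ClassedValues, CPISeries, ResearchBlock, Universe

#: Printed study-scale marginal counts, used as inputs to percentage cells.
PUBLISHED_TABLE1_COUNTS: dict[str, int] = {
    "n_drugs_total": 356,
    "n_drugs_in_patent_db": 313,
    "n_drugs_with_citation": 297,
    "n_cited_patents": 3644,
    "n_nih_cited_patents_any": 119,
    "n_drugs_matched_any": 34,
    "n_drugs_matched_linked": 29,
}

_M = 100_000_000  # cents per million dollars


def published_marginals() -> tuple[ResearchBlock, ResearchBlock]:
    """(all-research, patent-linked) blocks of printed study-scale counts."""
    all_research = ResearchBlock(
        pmids=ClassedValues(33_048, 316_749),
        project_years=ClassedValues(45_200, 296_175),
        project_year_cost_cents=ClassedValues(28_553 * _M, 135_325 * _M),
        projects=ClassedValues(26_872, 118_569),
        total_project_cost_cents=ClassedValues(114_882 * _M, 225_097 * _M),
    )
    patent_linked = ResearchBlock(
        pmids=ClassedValues(546, 3_484),
        project_years=ClassedValues(242, 527),
        project_year_cost_cents=ClassedValues(4_367 * _M // 10, 5_173 * _M // 10),
        projects=ClassedValues(61, 59),
        total_project_cost_cents=ClassedValues(9_400 * _M // 10, 2_024 * _M // 10),
        patents=ClassedValues(61, 43),
    )
    return all_research, patent_linked


def _distribute(total_cents: int, n: int) -> list[int]:
    """Split a cent total into n parts differing by at most one cent."""
    base, rem = divmod(total_cents, n)
    return [base + 1 if i < rem else base for i in range(n)]


def make_marginal_fixture() -> Universe:
    """Build the deterministic fixture universe (no randomness involved)."""
    # Drugs: 356 approved, first 313 in the patent database, one target each.
    drug_rows = []
    for i in range(1, 357):
        drug_rows.append(
            {
                "drug_id": f"D{i:03d}",
                "name": f"drug-{i}",
                "approval_year": 2010 + (i - 1) % 10,
                "target_ids": frozenset([f"T{i:03d}"]),
                "in_patent_db": i <= 313,
            }
        )
    # Publication matches point at a drug approved in 2019 so every
    # publication year in the fixture satisfies the search-window rule.
    match_drug = "D010"
    match_target = "T010"

    applied_projects = [f"A{k:02d}" for k in range(1, 62)]
    basic_projects = [f"B{k:02d}" for k in range(1, 60)]
    nopub_projects = [f"Q{k:02d}" for k in range(1, 16)]

    # Attributed project years: 242 applied and 527 basic (350 of the basic
    # years sit on applied projects, 177 on basic projects).
    applied_py: list[tuple[str, int]] = []
    basic_py: list[tuple[str, int]] = []
    extra_year: dict[str, int] = {}
    for idx, pid in enumerate(applied_projects):
        n_applied = 4 if idx < 59 else 3
        n_basic = 6 if idx < 45 else 5
        years = list(range(2000, 2000 + n_applied + n_basic))
        applied_py += [(pid, y) for y in years[:n_applied]]
        basic_py += [(pid, y) for y in years[n_applied:]]
        extra_year[pid] = years[-1] + 1
    for pid in basic_projects:
        basic_py += [(pid, y) for y in range(2000, 2003)]
        extra_year[pid] = 2003

    assert len(applied_py) == 242 and len(basic_py) == 527

    # Costs, in cents, matching the printed patent-linked cost cells:
    # $436.7M applied + $517.3M basic project-year costs; totals of
    # $939.95M (applied projects) and $202.35M (basic projects) so the
    # rendered millions reproduce 940.0 / 202.4 / 1142.3.
    applied_py_cost = _distribute(43_670_000_000, len(applied_py))
    basic_on_applied = [py for py in basic_py if py[0].startswith("A")]
    basic_on_basic = [py for py in basic_py if py[0].startswith("B")]
    basic_a_cost = _distribute(41_730_000_000, len(basic_on_applied))
    basic_b_cost = _distribute(10_000_000_000, len(basic_on_basic))
    extra_a_cost = _distribute(93_995_000_000 - 85_400_000_000, len(applied_projects))
    extra_b_cost = _distribute(20_235_000_000 - 10_000_000_000, len(basic_projects))

    project_rows = []
    for (pid, fy), cents in (
        list(zip(applied_py, applied_py_cost))
        + list(zip(basic_on_applied, basic_a_cost))
        + list(zip(basic_on_basic, basic_b_cost))
        + [((pid, extra_year[pid]), c) for pid, c in zip(applied_projects, extra_a_cost)]
        + [((pid, extra_year[pid]), c) for pid, c in zip(basic_projects, extra_b_cost)]
    ):
        project_rows.append(
            {"core_project_number": pid, "fiscal_year": fy, "cost_cents": cents}
        )
    for pid in nopub_projects:
        project_rows.append(
            {"core_project_number": pid, "fiscal_year": 2010, "cost_cents": 100_000_000}
        )

    # Publications: 546 applied spread over the applied project years,
    # 3,484 basic over the basic project years; publication year equals the
    # attributed fiscal year (in-window attribution, lag zero).
    pub_rows = []
    link_rows = []

    def add_pubs(py_list, counts, prefix, applied):
        counter = 0
        for (pid, fy), k in zip(py_list, counts):
            for _ in range(k):
                counter += 1
                pmid = f"{prefix}{counter:04d}"
                pub_rows.append(
                    {
                        "pmid": pmid,
                        "pub_year": fy,
                        "matched_drug_ids": frozenset([match_drug]) if applied else frozenset(),
                        "matched_target_ids": frozenset() if applied else frozenset([match_target]),
                    }
                )
                link_rows.append({"pmid": pmid, "core_project_number": pid})
        return counter

    n_app = add_pubs(
        applied_py, [3 if i < 62 else 2 for i in range(242)], "PA", applied=True
    )
    n_bas = add_pubs(
        basic_py, [7 if i < 322 else 6 for i in range(527)], "PB", applied=False
    )
    assert n_app == 546 and n_bas == 3484

    # NIH patents: 104 reachable through publications (61 applied-owned,
    # 43 basic-owned; 16 of the basic patents are co-owned so that 120
    # projects carry the 104 patents), plus 15 on projects without
    # publications (reachable in any-report mode only).
    patent_rows = []
    for i in range(1, 105):
        pnum = f"NP{i:03d}"
        owner = applied_projects[i - 1] if i <= 61 else basic_projects[i - 62]
        patent_rows.append({"patent_number": pnum, "core_project_number": owner})
    for offset, pid in enumerate(basic_projects[43:59]):
        patent_rows.append(
            {"patent_number": f"NP{62 + offset:03d}", "core_project_number": pid}
        )
    for j in range(1, 16):
        patent_rows.append(
            {"patent_number": f"NB{j:03d}", "core_project_number": nopub_projects[j - 1]}
        )

    # Exclusivity citations: the 104 publication-linked patents protect
    # drugs 1-29, the 15 any-report-only patents drugs 30-34, and 3,525
    # background (non-NIH) patents cover all 297 cited drugs.
    citation_rows = []
    for i in range(1, 105):
        citation_rows.append(
            {
                "drug_id": f"D{(i - 1) % 29 + 1:03d}",
                "patent_number": f"NP{i:03d}",
                "source": "orange_book",
            }
        )
    for j in range(1, 16):
        citation_rows.append(
            {
                "drug_id": f"D{30 + (j - 1) % 5:03d}",
                "patent_number": f"NB{j:03d}",
                "source": "orange_book",
            }
        )
    for k in range(1, 3526):
        citation_rows.append(
            {
                "drug_id": f"D{(k - 1) % 297 + 1:03d}",
                "patent_number": f"BG{k:04d}",
                "source": "orange_book",
            }
        )

    cpi = CPISeries({y: 100.0 for y in range(2000, 2020)}, base_year=2018)

    return Universe(
        drugs=pd.DataFrame(
            drug_rows, columns=["drug_id", "name", "approval_year", "target_ids", "in_patent_db"]
        ),
        publications=pd.DataFrame(
            pub_rows, columns=["pmid", "pub_year", "matched_drug_ids", "matched_target_ids"]
        ),
        projects=pd.DataFrame(
            project_rows, columns=["core_project_number", "fiscal_year", "cost_cents"]
        ),
        links=pd.DataFrame(link_rows, columns=["pmid", "core_project_number"]),
        patents=pd.DataFrame(patent_rows, columns=["patent_number", "core_project_number"]),
        citations=pd.DataFrame(citation_rows, columns=["drug_id", "patent_number", "source"]),
        cpi=cpi,
    )


def write_marginal_fixture(directory: str | Path) -> None:
    uio.write_universe(make_marginal_fixture(), directory)
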