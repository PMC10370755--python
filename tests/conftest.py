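from pathlib import Path

import pytest

from exclink import RunConfig, make_marginal_fixture, run_pipeline

# Canonical small input bundle used by loader tests: 2 drugs, 5 publications,
# 3 projects, with every cross-reference resolving.
SMALL_TABLES = {
    "drugs.csv": (
        "drug_id,name,approval_year,target_ids,in_patent_db\n"
        "D1,alpha,2015,T1;T2,true\n"
        "D2,beta,2019,T3,false\n"
    ),
    "publications.csv": (
        "pmid,pub_year,matched_drug_ids,matched_target_ids\n"
        "P1,2010,D1,\n"
        "P2,2011,,T1\n"
        "P3,2012,,T2\n"
        "P4,2013,D1,T1\n"
        "P5,2014,,T3\n"
    ),
    "projects.csv": (
        "core_project_number,fiscal_year,cost_usd\n"
        "G1,2010,100.00\n"
        "G1,2011,150.00\n"
        "G2,2012,200.00\n"
        "G2,2013,250.00\n"
        "G3,2005,300.00\n"
    ),
    "links.csv": (
        "pmid,core_project_number\n"
        "P1,G1\n"
        "P2,G1\n"
        "P3,G2\n"
        "P4,G2\n"
        "P5,G3\n"
    ),
    "patents.csv": "patent_number,core_project_number\nU1,G1\nU2,G3\n",
    "citations.csv": "drug_id,patent_number,source\nD1,U1,orange_book\n",
    "cpi.csv": "year,index\n"
    + "".join(f"{y},100.0\n" for y in range(2000, 2020)),
}


def write_tables(directory: Path, overrides: dict[str, str] | None = None) -> Path:
    tables = dict(SMALL_TABLES)
    if overrides:
        tables.update(overrides)
    directory.mkdir(parents=True, exist_ok=True)
    for name, text in tables.items():
        (directory / name).write_text(text)
    return directory


@pytest.fixture
def small_inputs(tmp_path: Path) -> Path:
    return write_tables(tmp_path / "inputs")


@pytest.fixture(scope="session")
def fixture_universe():
    return make_marginal_fixture()


@pytest.fixture(scope="session")
def fixture_result(fixture_universe):
    return run_pipeline(fixture_universe, RunConfig())
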