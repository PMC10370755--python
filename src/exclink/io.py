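"""Reading and writing the six input tables and the CPI series.

All tables are UTF-8 comma-separated files with a mandatory header row and
RFC-4180 quoting, one record type per file, mirroring the flat-file style of
NIH ExPORTER distributions:

``drugs.csv``
    drug_id, name, approval_year, target_ids (``;``-joined), in_patent_db
``publications.csv``
    pmid, pub_year, matched_drug_ids, matched_target_ids (``;``-joined)
``projects.csv``
    core_project_number, fiscal_year, cost_usd  (long format)
``links.csv``
    pmid, core_project_number
``patents.csv``
    patent_number, core_project_number  (long format)
``citations.csv``
    drug_id, patent_number, source
``cpi.csv``
    year, index

Costs are parsed from decimal dollars into integer cents (column
``cost_cents``) so that every downstream sum is exact.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .model import MIN_PUB_YEAR, CPISeries, Universe

FILENAMES: dict[str, str] = {
    "drugs": "drugs.csv",
    "publications": "publications.csv",
    "projects": "projects.csv",
    "links": "links.csv",
    "patents": "patents.csv",
    "citations": "citations.csv",
    "cpi": "cpi.csv",
}

_COLUMNS: dict[str, list[str]] = {
    "drugs": ["drug_id", "name", "approval_year", "target_ids", "in_patent_db"],
    "publications": ["pmid", "pub_year", "matched_drug_ids", "matched_target_ids"],
    "projects": ["core_project_number", "fiscal_year", "cost_usd"],
    "links": ["pmid", "core_project_number"],
    "patents": ["patent_number", "core_project_number"],
    "citations": ["drug_id", "patent_number", "source"],
    "cpi": ["year", "index"],
}


class UniverseError(ValueError):
    """Base class for fatal input problems."""


class SchemaError(UniverseError):
    """A table is missing or its header does not match the declared dialect."""


class IntegrityError(UniverseError):
    """A referential-integrity or uniqueness invariant is violated."""


def _split_ids(cell: str) -> frozenset[str]:
    if not cell or pd.isna(cell):
        return frozenset()
    return frozenset(part for part in str(cell).split(";") if part)


def _join_ids(ids: Iterable[str]) -> str:
    return ";".join(sorted(ids))


def _read_table(path: Path, name: str) -> pd.DataFrame:
    if not path.is_file():
        raise SchemaError(f"missing input file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = _COLUMNS[name]
    if list(df.columns) != expected:
        raise SchemaError(
            f"{path}: header {list(df.columns)} does not match expected {expected}"
        )
    return df


def _require_unique(df: pd.DataFrame, cols: list[str], table: str) -> None:
    dup = df.duplicated(subset=cols)
    if dup.any():
        offenders = df.loc[dup, cols].astype(str).agg("/".join, axis=1).head(10).tolist()
        raise IntegrityError(f"{table}: duplicate key on {cols}: {offenders}")


def _require_subset(values: pd.Series, known: set[str], what: str) -> None:
    missing = values[~values.isin(known)]
    if len(missing):
        sample = sorted(set(missing.astype(str)))[:10]
        raise IntegrityError(f"dangling reference: {what}: {sample}")


def load_universe(
    directory: str | os.PathLike[str],
    *,
    base_year: int = 2018,
    paths: Mapping[str, str | os.PathLike[str]] | None = None,
) -> Universe:
    """Load, parse, and cross-validate the full input bundle.

    Parameters
    ----------
    directory:
        Directory containing the seven standard files (see module docstring).
    base_year:
        Base year for the CPI series (must be present in ``cpi.csv``).
    paths:
        Optional per-table path overrides keyed by table name.

    Raises
    ------
    SchemaError
        Missing file or wrong header.
    IntegrityError
        Duplicate primary key, dangling foreign key, or violated record
        invariant (listing at most the first 10 offenders).
    """
    directory = Path(directory)
    resolved = {
        name: Path(paths[name]) if paths and name in paths else directory / fname
        for name, fname in FILENAMES.items()
    }
    raw = {name: _read_table(path, name) for name, path in resolved.items()}

    drugs = raw["drugs"].copy()
    drugs["approval_year"] = drugs["approval_year"].astype(int)
    drugs["target_ids"] = drugs["target_ids"].map(_split_ids)
    drugs["in_patent_db"] = drugs["in_patent_db"].str.lower().map(
        {"true": True, "false": False}
    )
    if drugs["in_patent_db"].isna().any():
        raise IntegrityError("drugs: in_patent_db must be 'true' or 'false'")
    _require_unique(drugs, ["drug_id"], "drugs")
    bad_years = drugs.loc[~drugs["approval_year"].between(2010, 2019), "drug_id"]
    if len(bad_years):
        raise IntegrityError(
            f"drugs: approval_year outside 2010-2019: {bad_years.head(10).tolist()}"
        )

    pubs = raw["publications"].copy()
    pubs["pub_year"] = pubs["pub_year"].astype(int)
    pubs["matched_drug_ids"] = pubs["matched_drug_ids"].map(_split_ids)
    pubs["matched_target_ids"] = pubs["matched_target_ids"].map(_split_ids)
    _require_unique(pubs, ["pmid"], "publications")
    empty = pubs.loc[
        (pubs["matched_drug_ids"].map(len) == 0)
        & (pubs["matched_target_ids"].map(len) == 0),
        "pmid",
    ]
    if len(empty):
        raise IntegrityError(
            f"publications: no drug or target match: {empty.head(10).tolist()}"
        )
    early = pubs.loc[pubs["pub_year"] < MIN_PUB_YEAR, "pmid"]
    if len(early):
        raise IntegrityError(
            f"publications: pub_year before {MIN_PUB_YEAR}: {early.head(10).tolist()}"
        )

    projects = raw["projects"].copy()
    projects["fiscal_year"] = projects["fiscal_year"].astype(int)
    cost = pd.to_numeric(projects["cost_usd"], errors="raise")
    if (cost < 0).any():
        bad = projects.loc[cost < 0, "core_project_number"].head(10).tolist()
        raise IntegrityError(f"projects: negative cost for {bad}")
    projects["cost_cents"] = (cost * 100).round().astype("int64")
    projects = projects.drop(columns=["cost_usd"])
    _require_unique(projects, ["core_project_number", "fiscal_year"], "projects")

    links = raw["links"].copy()
    _require_unique(links, ["pmid", "core_project_number"], "links")

    patents = raw["patents"].copy()
    _require_unique(patents, ["patent_number", "core_project_number"], "patents")

    citations = raw["citations"].copy()
    _require_unique(citations, ["drug_id", "patent_number"], "citations")
    bad_source = citations.loc[
        ~citations["source"].isin({"orange_book", "dpw_extra"}), "source"
    ]
    if len(bad_source):
        raise IntegrityError(
            f"citations: unknown source values: {sorted(set(bad_source))[:10]}"
        )

    cpi_df = raw["cpi"].copy()
    cpi_df["year"] = cpi_df["year"].astype(int)
    cpi_df["index"] = cpi_df["index"].astype(float)
    _require_unique(cpi_df, ["year"], "cpi")
    cpi = CPISeries(dict(zip(cpi_df["year"], cpi_df["index"])), base_year=base_year)

    # Referential closure.
    drug_ids = set(drugs["drug_id"])
    target_ids = set().union(*drugs["target_ids"]) if len(drugs) else set()
    pmids = set(pubs["pmid"])
    project_ids = set(projects["core_project_number"])

    _require_subset(links["pmid"], pmids, "links.pmid not in publications")
    _require_subset(
        links["core_project_number"], project_ids, "links.core_project_number not in projects"
    )
    _require_subset(
        patents["core_project_number"],
        project_ids,
        "patents.core_project_number not in projects",
    )
    _require_subset(citations["drug_id"], drug_ids, "citations.drug_id not in drugs")

    unknown_drug = pubs.loc[
        pubs["matched_drug_ids"].map(lambda s: not s <= drug_ids), "pmid"
    ]
    if len(unknown_drug):
        raise IntegrityError(
            f"publications: matched_drug_ids not in drugs: {unknown_drug.head(10).tolist()}"
        )
    unknown_target = pubs.loc[
        pubs["matched_target_ids"].map(lambda s: not s <= target_ids), "pmid"
    ]
    if len(unknown_target):
        raise IntegrityError(
            f"publications: matched_target_ids not in any drug: {unknown_target.head(10).tolist()}"
        )

    # Exclusivity citations are only meaningful for drugs carried by the
    # patent database listing.
    in_db = set(drugs.loc[drugs["in_patent_db"], "drug_id"])
    not_in_db = citations.loc[~citations["drug_id"].isin(in_db), "drug_id"]
    if len(not_in_db):
        raise IntegrityError(
            "citations: drug not flagged in_patent_db: "
            f"{sorted(set(not_in_db))[:10]}"
        )

    # Publication-window rule: a publication must not postdate the first
    # approval of any drug it is attributed to (directly or via its target).
    approval = dict(zip(drugs["drug_id"], drugs["approval_year"]))
    target_owner_approval: dict[str, int] = {}
    for _, row in drugs.iterrows():
        for t in row["target_ids"]:
            prev = target_owner_approval.get(t)
            yr = row["approval_year"]
            target_owner_approval[t] = yr if prev is None else max(prev, yr)

    def _window_ok(row: pd.Series) -> bool:
        years = [approval[d] for d in row["matched_drug_ids"]]
        years += [target_owner_approval[t] for t in row["matched_target_ids"]]
        return all(row["pub_year"] <= y for y in years)

    if len(pubs):
        late = pubs.loc[~pubs.apply(_window_ok, axis=1), "pmid"]
        if len(late):
            raise IntegrityError(
                f"publications: pub_year after drug approval: {late.head(10).tolist()}"
            )

    return Universe(
        drugs=drugs.reset_index(drop=True),
        publications=pubs.reset_index(drop=True),
        projects=projects.reset_index(drop=True),
        links=links.reset_index(drop=True),
        patents=patents.reset_index(drop=True),
        citations=citations.reset_index(drop=True),
        cpi=cpi,
    )


def write_universe(universe: Universe, directory: str | os.PathLike[str]) -> None:
    """Write a universe back to the seven standard CSV files.

    Output is deterministic (stable row order as stored, fixed formatting),
    and ``load_universe(write_universe(u)) == u`` up to dtypes.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    drugs = universe.drugs.copy()
    drugs["target_ids"] = drugs["target_ids"].map(_join_ids)
    drugs["in_patent_db"] = drugs["in_patent_db"].map({True: "true", False: "false"})
    drugs.to_csv(directory / FILENAMES["drugs"], index=False, lineterminator="\n")

    pubs = universe.publications.copy()
    pubs["matched_drug_ids"] = pubs["matched_drug_ids"].map(_join_ids)
    pubs["matched_target_ids"] = pubs["matched_target_ids"].map(_join_ids)
    pubs.to_csv(directory / FILENAMES["publications"], index=False, lineterminator="\n")

    projects = universe.projects.copy()
    projects["cost_usd"] = projects["cost_cents"].map(lambda c: f"{c / 100:.2f}")
    projects[["core_project_number", "fiscal_year", "cost_usd"]].to_csv(
        directory / FILENAMES["projects"], index=False, lineterminator="\n"
    )

    universe.links.to_csv(directory / FILENAMES["links"], index=False, lineterminator="\n")
    universe.patents.to_csv(
        directory / FILENAMES["patents"], index=False, lineterminator="\n"
    )
    universe.citations.to_csv(
        directory / FILENAMES["citations"], index=False, lineterminator="\n"
    )

    cpi = pd.DataFrame(
        sorted(universe.cpi.index.items()), columns=["year", "index"]
    )
    cpi["index"] = cpi["index"].map(lambda v: f"{v:.4f}")
    cpi.to_csv(directory / FILENAMES["cpi"], index=False, lineterminator="\n")
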