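"""End-to-end run: load → classify → attribute → join → summarize.

Also owns the on-disk run layout: audit intermediates
(``project_years.csv``, ``matched_patents.csv``), the three summary tables,
and ``run_manifest.json`` (configuration echo plus input checksums).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as uio
from .attribute import (
    aggregate_costs,
    attribute_project_years,
    project_class_map,
)
from .classify import classify_publications
from .model import (
    DEFAULT_BASE_YEAR,
    DEFAULT_WINDOW,
    JoinMode,
    LagPolicy,
    PatentJoinResult,
    ResearchBlock,
    Universe,
)
from .patents import (
    join_exclusivity_patents,
    matched_projects,
    normalize_patent_number,
    patent_linked_funding,
)
from .report import LedgerSummary, build_tables, write_ledger


@dataclass(frozen=True)
class RunConfig:
    max_lag_years: int = 4
    pre_funding_exclude: bool = True
    window: tuple[int, int] = DEFAULT_WINDOW
    base_year: int = DEFAULT_BASE_YEAR

    @property
    def lag_policy(self) -> LagPolicy:
        return LagPolicy(self.max_lag_years, self.pre_funding_exclude)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in data.items() if k in known}
        if "window" in kwargs:
            kwargs["window"] = tuple(kwargs["window"])
        return cls(**kwargs)


@dataclass(frozen=True)
class PipelineResult:
    universe: Universe
    pub_classes: pd.Series
    attributed: pd.DataFrame
    all_research: ResearchBlock
    patent_linked: ResearchBlock
    join_any: PatentJoinResult
    join_linked: PatentJoinResult
    ledger: LedgerSummary
    log: dict


def run_pipeline(universe: Universe, config: RunConfig = RunConfig()) -> PipelineResult:
    """Execute the full deterministic accounting pipeline in memory."""
    pub_classes = classify_publications(universe.publications)
    attributed, log = attribute_project_years(
        universe, config.lag_policy, config.window, pub_classes
    )
    proj_classes = project_class_map(attributed)
    linked_projects = set(proj_classes.index)

    all_research = aggregate_costs(
        attributed, universe.projects, pub_classes, universe.cpi, config.window
    )
    join_any = join_exclusivity_patents(
        universe.patents, universe.citations, JoinMode.ANY_REPORT
    )
    join_linked = join_exclusivity_patents(
        universe.patents,
        universe.citations,
        JoinMode.PUBLICATION_LINKED,
        linked_projects=linked_projects,
        project_classes=proj_classes,
    )
    patent_linked = patent_linked_funding(
        join_linked,
        universe.patents,
        attributed,
        universe.projects,
        pub_classes,
        universe.cpi,
        config.window,
    )

    cited_norm = universe.citations["patent_number"].map(normalize_patent_number)
    table1_counts = {
        "n_drugs_total": len(universe.drugs),
        "n_drugs_in_patent_db": int(universe.drugs["in_patent_db"].sum()),
        "n_drugs_with_citation": universe.citations["drug_id"].nunique(),
        "n_cited_patents": int(cited_norm.nunique()),
        "n_nih_cited_patents_any": join_any.n_patents,
        "n_drugs_matched_any": join_any.n_drugs,
        "n_drugs_matched_linked": join_linked.n_drugs,
    }
    attributed_pmids = set().union(*attributed["supporting_pmids"]) if len(attributed) else set()
    pubs = universe.publications
    kept = pubs.loc[pubs["pmid"].isin(attributed_pmids)]
    searches = (
        len(set().union(*kept["matched_drug_ids"])) if len(kept) else 0,
        len(set().union(*kept["matched_target_ids"])) if len(kept) else 0,
    )
    ledger = build_tables(table1_counts, all_research, patent_linked, searches)

    log.update(
        {
            "patents_matched_any_report": join_any.n_patents,
            "patents_matched_publication_linked": join_linked.n_patents,
            "drugs_matched_any_report": join_any.n_drugs,
            "drugs_matched_publication_linked": join_linked.n_drugs,
        }
    )
    return PipelineResult(
        universe=universe,
        pub_classes=pub_classes,
        attributed=attributed,
        all_research=all_research,
        patent_linked=patent_linked,
        join_any=join_any,
        join_linked=join_linked,
        ledger=ledger,
        log=log,
    )


def _write_project_years(result: PipelineResult, path: Path) -> None:
    df = result.attributed.copy()
    df["n_pmids"] = df["supporting_pmids"].map(len)
    df["cost_nominal"] = df["cost_nominal_cents"].map(lambda c: f"{c / 100:.2f}")
    df["cost_2018"] = df["cost_adjusted_cents"].map(lambda c: f"{c / 100:.2f}")
    df = df.sort_values(["core_project_number", "fiscal_year"]).reset_index(drop=True)
    df[
        ["core_project_number", "fiscal_year", "research_class", "n_pmids", "cost_nominal", "cost_2018"]
    ].rename(columns={"research_class": "class"}).to_csv(
        path, index=False, lineterminator="\n"
    )


def _write_matched_patents(result: PipelineResult, path: Path) -> None:
    rows = []
    pat = result.universe.patents.copy()
    pat["patent_norm"] = pat["patent_number"].map(normalize_patent_number)
    cit = result.universe.citations.copy()
    cit["patent_norm"] = cit["patent_number"].map(normalize_patent_number)
    drug_map = cit.groupby("patent_norm")["drug_id"].agg(lambda s: ";".join(sorted(set(s))))
    proj_map = pat.groupby("patent_norm")["core_project_number"].agg(
        lambda s: ";".join(sorted(set(s)))
    )
    for join in (result.join_linked, result.join_any):
        for patent in sorted(join.matched_patents):
            cls = join.patent_classes.get(patent)
            rows.append(
                {
                    "patent_number": patent,
                    "mode": join.mode.value,
                    "class": cls.value if cls is not None else "NA",
                    "drug_ids": drug_map.get(patent, ""),
                    "core_project_numbers": proj_map.get(patent, ""),
                }
            )
    pd.DataFrame(
        rows, columns=["patent_number", "mode", "class", "drug_ids", "core_project_numbers"]
    ).to_csv(path, index=False, lineterminator="\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(
    inputs_dir: str | Path,
    out_dir: str | Path,
    config: RunConfig = RunConfig(),
) -> PipelineResult:
    """Run the pipeline from an input directory, writing the run directory."""
    inputs_dir = Path(inputs_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    universe = uio.load_universe(inputs_dir, base_year=config.base_year)
    result = run_pipeline(universe, config)

    _write_project_years(result, out_dir / "project_years.csv")
    _write_matched_patents(result, out_dir / "matched_patents.csv")
    write_ledger(result.ledger, out_dir)

    manifest = {
        "config": {
            "max_lag_years": config.max_lag_years,
            "pre_funding_exclude": config.pre_funding_exclude,
            "window": list(config.window),
            "base_year": config.base_year,
        },
        "inputs": {
            name: _sha256(inputs_dir / fname)
            for name, fname in sorted(uio.FILENAMES.items())
        },
        "log": result.log,
    }
    (out_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return result
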