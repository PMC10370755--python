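"""Joining project-derived patents against drug exclusivity citations.

Two join modes mirror the two ways an NIH-funded patent can be counted:

``any_report``
    every loaded project-patent record participates, whether or not the
    owning project is reachable through drug/target publications;
``publication_linked``
    restricted to patents whose owning projects have at least one attributed
    project year, i.e. patents on projects that demonstrably funded
    published research on the drugs or their targets.

By construction the publication-linked match set is a subset of the
any-report set. Research classes are meaningful only in publication-linked
mode (a patent without associated publications has no class).
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping

import pandas as pd

from .classify import classify_entity
from .model import JoinMode, PatentJoinResult, ResearchBlock, ResearchClass

_NUMERIC_PATENT = re.compile(r"^(?:US)?(\d+)(?:[A-Z]\d?)?$")


def normalize_patent_number(raw: str) -> str:
    """Canonical patent-number form used on both sides of the join.

    Strips whitespace and commas, uppercases, drops a ``US`` prefix and a
    trailing kind code (e.g. ``B2``) from purely numeric patent numbers.
    Identifiers that are not of that shape are returned cleaned but intact.
    """
    cleaned = re.sub(r"[\s,]+", "", str(raw)).upper()
    m = _NUMERIC_PATENT.match(cleaned)
    return m.group(1) if m else cleaned


def join_exclusivity_patents(
    patents: pd.DataFrame,
    citations: pd.DataFrame,
    mode: JoinMode | str,
    *,
    linked_projects: Iterable[str] | None = None,
    project_classes: Mapping[str, str] | pd.Series | None = None,
) -> PatentJoinResult:
    """Intersect project-patent records with exclusivity citations.

    Parameters
    ----------
    patents:
        Long table (patent_number, core_project_number).
    citations:
        Exclusivity citations (drug_id, patent_number, source).
    mode:
        Join mode; in publication-linked mode ``linked_projects`` (projects
        with >=1 attributed project year) and ``project_classes`` must be
        supplied so patents can be restricted and classified.
    """
    mode = JoinMode(mode)
    pat = patents.copy()
    pat["patent_norm"] = pat["patent_number"].map(normalize_patent_number)
    cit = citations.copy()
    cit["patent_norm"] = cit["patent_number"].map(normalize_patent_number)

    if mode is JoinMode.PUBLICATION_LINKED:
        if linked_projects is None:
            raise ValueError("publication_linked mode requires linked_projects")
        linked = set(linked_projects)
        pat = pat.loc[pat["core_project_number"].isin(linked)]

    merged = pat.merge(cit, on="patent_norm", how="inner")
    matched_patents = frozenset(merged["patent_norm"])
    matched_drugs = frozenset(merged["drug_id"])

    patent_classes: dict[str, ResearchClass] = {}
    if mode is JoinMode.PUBLICATION_LINKED and matched_patents:
        if project_classes is None:
            raise ValueError("publication_linked mode requires project_classes")
        cls = (
            project_classes
            if isinstance(project_classes, Mapping)
            else project_classes.to_dict()
        )
        owners = pat.loc[pat["patent_norm"].isin(matched_patents)]
        for patent, group in owners.groupby("patent_norm"):
            patent_classes[str(patent)] = classify_entity(
                cls[p] for p in group["core_project_number"]
            )

    return PatentJoinResult(
        mode=mode,
        matched_patents=matched_patents,
        matched_drugs=matched_drugs,
        patent_classes=patent_classes,
    )


def matched_projects(result: PatentJoinResult, patents: pd.DataFrame) -> set[str]:
    """Projects owning at least one matched patent."""
    norm = patents["patent_number"].map(normalize_patent_number)
    mask = norm.isin(result.matched_patents)
    return set(patents.loc[mask, "core_project_number"])


def patent_counts(result: PatentJoinResult):
    """Per-class patent counts for the publication-linked block."""
    from .model import ClassedValues

    return ClassedValues(
        applied=result.class_count(ResearchClass.APPLIED),
        basic=result.class_count(ResearchClass.BASIC),
    )


def patent_linked_funding(
    result: PatentJoinResult,
    patents: pd.DataFrame,
    attributed: pd.DataFrame,
    projects: pd.DataFrame,
    pub_classes: pd.Series,
    cpi,
    window: tuple[int, int] | None = None,
) -> ResearchBlock:
    """Funding block restricted to projects owning a matched patent.

    This is the lower, patent-linked half of the funding summary: project
    years, costs, projects, and publications of the projects whose patents
    are cited as exclusivity barriers, with the matched patents themselves
    counted per class. Only projects that both own a matched patent and have
    at least one attributed project year contribute.
    """
    from .attribute import aggregate_costs
    from .model import DEFAULT_WINDOW

    if result.mode is not JoinMode.PUBLICATION_LINKED:
        raise ValueError("patent_linked_funding requires publication_linked mode")
    window = window or DEFAULT_WINDOW
    owners = matched_projects(result, patents)
    block = aggregate_costs(
        attributed,
        projects,
        pub_classes,
        cpi,
        window=window,
        restrict_projects=owners,
    )
    return ResearchBlock(
        pmids=block.pmids,
        project_years=block.project_years,
        project_year_cost_cents=block.project_year_cost_cents,
        projects=block.projects,
        total_project_cost_cents=block.total_project_cost_cents,
        patents=patent_counts(result),
    )
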