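"""Fiscal-year attribution of publications to project funding, with
deduplication, inflation adjustment, and the two cost aggregates.

Each publication linked to a project is attributed to exactly one fiscal
year of that project: its own year when it falls inside the funded span, the
final funded year when it appears up to ``max_lag_years`` afterwards
(publication lag), and nothing at all when it predates the first funded year
or exceeds the lag window. The unit of accounting is the unique
(project, fiscal year) pair; costs are summed in integer cents of base-year
dollars.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .classify import classify_publications
from .model import (
    DEFAULT_WINDOW,
    ClassedValues,
    CPISeries,
    LagPolicy,
    ResearchBlock,
    ResearchClass,
    Universe,
)

APPLIED = ResearchClass.APPLIED.value
BASIC = ResearchClass.BASIC.value


class AttributionError(ValueError):
    pass


def round_half_away_from_zero(x: float) -> int:
    """Round to the nearest integer with ties away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def inflation_adjust(cost_cents: int, year: int, cpi: CPISeries) -> int:
    """Convert nominal cents of ``year`` into base-year cents.

    adjusted = nominal x index(base_year) / index(year), rounded to the cent.
    """
    return round_half_away_from_zero(cost_cents * cpi.factor(year))


def assign_project_year(
    pub_year: int, first_fy: int, last_fy: int, policy: LagPolicy = LagPolicy()
) -> int | None:
    """Fiscal year a publication is attributed to, or None if excluded.

    Within the funded span the publication keeps its own year; 1 to
    ``max_lag_years`` years after the final funded year it is assigned to
    that final year; earlier than the first funded year it is excluded
    (unless ``pre_funding_exclude`` is off, in which case it is assigned the
    first funded year); beyond the lag window it is excluded.
    """
    if first_fy > last_fy:
        raise AttributionError(f"first_fy {first_fy} > last_fy {last_fy}")
    if pub_year < first_fy:
        return None if policy.pre_funding_exclude else first_fy
    if pub_year <= last_fy:
        return pub_year
    if pub_year <= last_fy + policy.max_lag_years:
        return last_fy
    return None


def clip_projects(
    projects: pd.DataFrame, window: tuple[int, int] = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Drop project fiscal years outside the study window."""
    lo, hi = window
    mask = projects["fiscal_year"].between(lo, hi)
    return projects.loc[mask].reset_index(drop=True)


def adjust_project_costs(projects: pd.DataFrame, cpi: CPISeries) -> pd.DataFrame:
    """Add a ``cost_adjusted_cents`` column of base-year cents."""
    out = projects.copy()
    factors = out["fiscal_year"].map(cpi.factor).to_numpy(dtype=float)
    cents = out["cost_cents"].to_numpy(dtype=float)
    out["cost_adjusted_cents"] = np.floor(cents * factors + 0.5).astype("int64")
    return out


def dedupe(rows: pd.DataFrame) -> pd.DataFrame:
    """Collapse attributed rows to unique (project, fiscal year) pairs.

    Accepts either per-publication rows (a ``pmid`` column) or already
    collapsed rows (a ``supporting_pmids`` column of sets); the operation is
    idempotent. Supporting publication sets are unioned and the research
    class re-folded (any applied publication makes the project year applied).
    """
    if rows.empty:
        return pd.DataFrame(
            columns=[
                "core_project_number",
                "fiscal_year",
                "supporting_pmids",
                "research_class",
            ]
        )
    work = rows.copy()
    if "pmid" in work.columns:
        work["supporting_pmids"] = work["pmid"].map(lambda p: frozenset([p]))

    def _merge(group: pd.DataFrame) -> pd.Series:
        pmids = frozenset().union(*group["supporting_pmids"])
        cls = APPLIED if (group["research_class"] == APPLIED).any() else BASIC
        return pd.Series({"supporting_pmids": pmids, "research_class": cls})

    out = (
        work.groupby(["core_project_number", "fiscal_year"], sort=True)
        .apply(_merge, include_groups=False)
        .reset_index()
    )
    return out[
        ["core_project_number", "fiscal_year", "supporting_pmids", "research_class"]
    ]


def attribute_project_years(
    universe: Universe,
    policy: LagPolicy = LagPolicy(),
    window: tuple[int, int] = DEFAULT_WINDOW,
    pub_classes: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run attribution over every (publication, project) link.

    Returns the deduplicated attributed-project-year table with adjusted
    costs, plus a small log of link counts (attributed / excluded).

    Raises
    ------
    AttributionError
        If an assigned fiscal year has no cost record in the project's
        (window-clipped) funding history — a gap in the inputs.
    """
    if pub_classes is None:
        pub_classes = classify_publications(universe.publications)

    projects = adjust_project_costs(clip_projects(universe.projects, window), universe.cpi)
    spans = (
        projects.groupby("core_project_number")["fiscal_year"]
        .agg(first_fy="min", last_fy="max")
        .reset_index()
    )

    pubs = universe.publications[["pmid", "pub_year"]].copy()
    pubs["research_class"] = pubs["pmid"].map(pub_classes)
    linked = universe.links.merge(pubs, on="pmid", how="left").merge(
        spans, on="core_project_number", how="left"
    )

    log = {"links_total": len(linked)}
    # Projects with no in-window funding years cannot receive attributions.
    no_span = linked["first_fy"].isna()
    log["links_project_outside_window"] = int(no_span.sum())
    linked = linked.loc[~no_span].copy()

    fy = [
        assign_project_year(py, int(f), int(l), policy)
        for py, f, l in zip(linked["pub_year"], linked["first_fy"], linked["last_fy"])
    ]
    linked["fiscal_year"] = [v if v is not None else -1 for v in fy]
    excluded = linked["fiscal_year"] == -1
    log["links_excluded_by_lag_or_prefunding"] = int(excluded.sum())
    linked = linked.loc[~excluded]
    log["links_attributed"] = len(linked)

    unique = dedupe(
        linked[["core_project_number", "fiscal_year", "pmid", "research_class"]]
    )
    log["project_years_unique"] = len(unique)

    costed = unique.merge(
        projects[["core_project_number", "fiscal_year", "cost_cents", "cost_adjusted_cents"]],
        on=["core_project_number", "fiscal_year"],
        how="left",
    )
    missing = costed["cost_cents"].isna()
    if missing.any():
        bad = (
            costed.loc[missing, ["core_project_number", "fiscal_year"]]
            .astype(str)
            .agg("/".join, axis=1)
            .head(10)
            .tolist()
        )
        raise AttributionError(
            f"attributed year absent from the project's cost table: {bad}"
        )
    costed["cost_nominal_cents"] = costed.pop("cost_cents").astype("int64")
    costed["cost_adjusted_cents"] = costed["cost_adjusted_cents"].astype("int64")
    return costed, log


def project_class_map(attributed: pd.DataFrame) -> pd.Series:
    """Research class per project, folded over its attributed project years.

    Equivalent to folding over the project's attributed publications: any
    applied publication yields an applied project year, hence an applied
    project.
    """
    if attributed.empty:
        return pd.Series(dtype=object, name="research_class")
    is_applied = (
        attributed.assign(applied=attributed["research_class"] == APPLIED)
        .groupby("core_project_number")["applied"]
        .any()
    )
    out = is_applied.map({True: APPLIED, False: BASIC})
    out.name = "research_class"
    return out


def _classed(by_class: Mapping[str, int]) -> ClassedValues:
    return ClassedValues(
        applied=int(by_class.get(APPLIED, 0)), basic=int(by_class.get(BASIC, 0))
    )


def aggregate_costs(
    attributed: pd.DataFrame,
    projects: pd.DataFrame,
    pub_classes: pd.Series,
    cpi: CPISeries,
    window: tuple[int, int] = DEFAULT_WINDOW,
    restrict_projects: Iterable[str] | None = None,
) -> ResearchBlock:
    """Compute the funding block over (optionally restricted) projects.

    Project-year costs sum adjusted costs of attributed (project, year)
    pairs; total project costs sum adjusted costs of *all* in-window fiscal
    years of every project with at least one attributed year, each project
    once. Per-class splits follow each unit's own class: publications by
    their search provenance, project years by folding their publications,
    projects (and hence total costs) by folding over all their attributed
    publications.
    """
    work = attributed
    if restrict_projects is not None:
        keep = set(restrict_projects)
        work = attributed.loc[attributed["core_project_number"].isin(keep)]

    if work.empty:
        zero = ClassedValues(0, 0)
        return ResearchBlock(zero, zero, zero, zero, zero)

    # Publications: distinct PMIDs supporting >=1 attributed year, by the
    # publication's own class.
    pmids = (
        work[["supporting_pmids"]]
        .explode("supporting_pmids")["supporting_pmids"]
        .dropna()
        .unique()
    )
    pmid_cls = pd.Series(pmids).map(pub_classes)
    pmid_counts = pmid_cls.value_counts().to_dict()

    py_counts = work["research_class"].value_counts().to_dict()
    py_costs = work.groupby("research_class")["cost_adjusted_cents"].sum().to_dict()

    proj_cls = project_class_map(work)
    proj_counts = proj_cls.value_counts().to_dict()

    clipped = adjust_project_costs(clip_projects(projects, window), cpi)
    totals = (
        clipped.loc[clipped["core_project_number"].isin(proj_cls.index)]
        .groupby("core_project_number")["cost_adjusted_cents"]
        .sum()
    )
    total_costs = totals.groupby(proj_cls.loc[totals.index]).sum().to_dict()

    block = ResearchBlock(
        pmids=_classed(pmid_counts),
        project_years=_classed(py_counts),
        project_year_cost_cents=_classed(py_costs),
        projects=_classed(proj_counts),
        total_project_cost_cents=_classed(total_costs),
    )
    _check_block(block, work)
    return block


def _check_block(block: ResearchBlock, work: pd.DataFrame) -> None:
    # Per-project sanity: attributed years are a subset of funded years, so
    # project-year costs can never exceed total project costs.
    if block.project_year_cost_cents.total > block.total_project_cost_cents.total:
        raise AttributionError(
            "project-year costs exceed total project costs: "
            f"{block.project_year_cost_cents.total} > {block.total_project_cost_cents.total}"
        )
    if block.project_years.total != len(work):
        raise AttributionError("project-year partition mismatch")


def lag_sensitivity(
    universe: Universe,
    max_lags: Iterable[int] = range(0, 5),
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> dict[int, int]:
    """Unique attributed project-year count as a function of the lag cap.

    Widening the lag window can only admit more links, so counts are
    monotone non-decreasing in ``max_lag_years``.
    """
    pub_classes = classify_publications(universe.publications)
    out: dict[int, int] = {}
    for lag in max_lags:
        attributed, _ = attribute_project_years(
            universe, LagPolicy(max_lag_years=lag), window, pub_classes
        )
        out[lag] = len(attributed)
    return out
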