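"""Domain types for the funding-to-exclusivity linkage pipeline.

The analysis links five kinds of records: FDA-approved drugs and their
molecular targets, publications matched by drug-name or target searches,
NIH-style grants ("projects") with per-fiscal-year costs, project-to-patent
records, and (drug, patent) exclusivity citations of the Orange Book kind.
Record collections are carried as pandas DataFrames inside a validated
:class:`Universe` bundle; the dataclasses here document the row contracts
and hold the few scalar/aggregate objects the pipeline passes around.

Monetary amounts are stored as integer cents throughout to keep sums exact;
rendering back to dollars happens only at report time.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

#: Study funding window: NIH funding is identified for fiscal years 2000-2019.
DEFAULT_WINDOW: tuple[int, int] = (2000, 2019)

#: Base year for inflation adjustment of costs.
DEFAULT_BASE_YEAR: int = 2018

#: Earliest publication year admitted by the literature search window.
MIN_PUB_YEAR: int = 1960


class ResearchClass(str, enum.Enum):
    """Binary research-focus label.

    ``APPLIED``: the publication was found by searching for the drug itself.
    ``BASIC``: found by searching for the drug's target but not the drug.
    """

    APPLIED = "applied"
    BASIC = "basic"


class JoinMode(str, enum.Enum):
    """Which project-patent records participate in the exclusivity join.

    ``PUBLICATION_LINKED`` restricts to patents whose owning projects have at
    least one attributed project year (i.e. are reachable through drug/target
    publications); ``ANY_REPORT`` uses every loaded project-patent record.
    """

    PUBLICATION_LINKED = "publication_linked"
    ANY_REPORT = "any_report"


class CitationSource(str, enum.Enum):
    ORANGE_BOOK = "orange_book"
    DPW_EXTRA = "dpw_extra"


@dataclass(frozen=True)
class CPISeries:
    """Annual-average consumer price index keyed by calendar year."""

    index: Mapping[int, float]
    base_year: int = DEFAULT_BASE_YEAR

    def __post_init__(self) -> None:
        if self.base_year not in self.index:
            raise ValueError(f"CPI series lacks base year {self.base_year}")
        bad = [y for y, v in self.index.items() if not v > 0]
        if bad:
            raise ValueError(f"CPI index values must be > 0; bad years: {sorted(bad)[:10]}")

    def factor(self, year: int) -> float:
        """Multiplier taking nominal dollars of ``year`` to base-year dollars."""
        if year not in self.index:
            raise KeyError(f"CPI series has no entry for year {year}")
        return self.index[self.base_year] / self.index[year]


@dataclass(frozen=True)
class LagPolicy:
    """Rules assigning a publication to one fiscal year of a linked project.

    A publication dated within the project's funded span is attributed to its
    own year; one dated up to ``max_lag_years`` after the final funded year is
    attributed to that final year; anything earlier than the first funded year
    (when ``pre_funding_exclude``) or beyond the lag window is excluded.
    """

    max_lag_years: int = 4
    pre_funding_exclude: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.max_lag_years <= 10:
            raise ValueError("max_lag_years must be in [0, 10]")


@dataclass(frozen=True)
class ClassedValues:
    """An applied/basic pair of counts or cent sums; total is their sum."""

    applied: int
    basic: int

    @property
    def total(self) -> int:
        return self.applied + self.basic

    def get(self, slice_name: str) -> int:
        if slice_name == "total":
            return self.total
        if slice_name == "applied":
            return self.applied
        if slice_name == "basic":
            return self.basic
        raise KeyError(slice_name)


@dataclass(frozen=True)
class ResearchBlock:
    """One block of the funding summary: counts and cost sums by class.

    Mirrors the row structure of the funding tables: unique publications,
    attributed project years, project-year costs, projects with at least one
    attributed year, and total (all in-window fiscal years) project costs.
    ``patents`` is populated only for the patent-linked block.
    """

    pmids: ClassedValues
    project_years: ClassedValues
    project_year_cost_cents: ClassedValues
    projects: ClassedValues
    total_project_cost_cents: ClassedValues
    patents: ClassedValues | None = None

    def cost_aggregate(
        self, slice_name: str = "total", window: tuple[int, int] = DEFAULT_WINDOW
    ) -> "CostAggregate":
        return CostAggregate(
            n_pmids=self.pmids.get(slice_name),
            n_project_years=self.project_years.get(slice_name),
            n_projects=self.projects.get(slice_name),
            project_year_cost_cents=self.project_year_cost_cents.get(slice_name),
            total_project_cost_cents=self.total_project_cost_cents.get(slice_name),
            window=window,
        )


@dataclass(frozen=True)
class CostAggregate:
    """The two cost totals with their unit counts, per research class slice.

    ``project_year_cost_cents`` sums adjusted costs over attributed
    (project, fiscal year) pairs only; ``total_project_cost_cents`` sums
    adjusted costs over every in-window fiscal year of each project that has
    at least one attributed year, each project counted once.
    """

    n_pmids: int
    n_project_years: int
    n_projects: int
    project_year_cost_cents: int
    total_project_cost_cents: int
    window: tuple[int, int] = DEFAULT_WINDOW


@dataclass(frozen=True)
class PatentJoinResult:
    """Outcome of joining project-derived patents with exclusivity citations."""

    mode: JoinMode
    matched_patents: frozenset[str]
    matched_drugs: frozenset[str]
    #: patent -> research class; populated only in publication-linked mode.
    patent_classes: Mapping[str, ResearchClass] = field(default_factory=dict)

    @property
    def n_patents(self) -> int:
        return len(self.matched_patents)

    @property
    def n_drugs(self) -> int:
        return len(self.matched_drugs)

    def class_count(self, cls: ResearchClass) -> int:
        return sum(1 for c in self.patent_classes.values() if c is cls)


@dataclass(frozen=True)
class Universe:
    """Immutable bundle of the six input tables plus the CPI series.

    Frames use the column contracts of :mod:`exclink.io`; referential
    integrity has been checked at load time, so downstream stages may merge
    without re-validating.
    """

    drugs: pd.DataFrame
    publications: pd.DataFrame
    projects: pd.DataFrame  # long: one row per (core_project_number, fiscal_year)
    links: pd.DataFrame
    patents: pd.DataFrame  # long: one row per (patent_number, core_project_number)
    citations: pd.DataFrame
    cpi: CPISeries

    def counts(self) -> dict[str, int]:
        return {
            "drugs": len(self.drugs),
            "publications": len(self.publications),
            "project_years": len(self.projects),
            "projects": self.projects["core_project_number"].nunique(),
            "links": len(self.links),
            "patent_records": len(self.patents),
            "citations": len(self.citations),
        }
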