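"""Seedable synthetic research-funding ecosystems with ground truth.

The generator emulates the statistical structure the linkage analysis
assumes: approved drugs each mapped to one or more targets; grants funded
over contiguous fiscal-year spans with log-normal annual costs;
publications arising from funded years with a lag (including lags long
enough to be excluded by the attribution rule); drug-name versus
target-only search provenance; patents produced at a class-dependent rate
(applied projects patent more often than basic ones); and sparse citation
of patents as exclusivity barriers, on top of a background of non-NIH
cited patents.

Alongside the six input tables it produces an independent
:class:`GroundTruth`: per-class counts and cost sums computed by
generator-side bookkeeping (plain Python loops over the records it just
emitted), so pipeline output can be checked for exact recovery. The
bookkeeping shares only the attribution rule and the cent-rounding
inflation formula with the pipeline; all set construction and summation is
separate.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as uio
from .attribute import assign_project_year, inflation_adjust
from .model import (
    DEFAULT_BASE_YEAR,
    DEFAULT_WINDOW,
    ClassedValues,
    CPISeries,
    LagPolicy,
    ResearchBlock,
    Universe,
)

APPLIED = "applied"
BASIC = "basic"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic ecosystem.

    Defaults are sized for a desk-scale universe that preserves the study's
    structural ratios: ~9% of publications drug-matched (applied), patenting
    concentrated in applied projects, and citation of patents as exclusivity
    barriers rare (about 5 per thousand NIH patents, the order observed for
    real exclusivity-cited patents). Costs are log-normal with a median near
    $480k per project year, the magnitude implied by dividing the study's
    project-year cost total by its project-year count.
    """

    n_drugs: int = 30
    mean_targets_per_drug: float = 1.5
    p_drug_in_patent_db: float = 0.88
    n_projects: int = 300
    project_duration_mean: float = 4.0
    project_start_range: tuple[int, int] = (2000, 2016)
    cost_lognorm_mu: float = math.log(480_000.0)
    cost_lognorm_sigma: float = 0.8
    pubs_per_project_year: float = 1.0
    #: P(lag = i) for publication year = funded year + i; support deliberately
    #: extends beyond max_lag_years so the exclusion branch is exercised.
    lag_probs: tuple[float, ...] = (0.35, 0.25, 0.15, 0.10, 0.07, 0.04, 0.04)
    p_drug_match: float = 0.09
    p_second_link: float = 0.10
    patent_rate_applied: float = 0.40
    patent_rate_basic: float = 0.10
    patent_rate_unlinked: float = 0.05
    p_cite: float = 0.005
    background_cited_patents_per_drug: float = 12.0
    cpi_drift: float = 0.02
    max_lag_years: int = 4
    window: tuple[int, int] = DEFAULT_WINDOW
    base_year: int = DEFAULT_BASE_YEAR
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "p_drug_in_patent_db": self.p_drug_in_patent_db,
            "p_drug_match": self.p_drug_match,
            "p_second_link": self.p_second_link,
            "p_cite": self.p_cite,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        rates = {
            "pubs_per_project_year": self.pubs_per_project_year,
            "patent_rate_applied": self.patent_rate_applied,
            "patent_rate_basic": self.patent_rate_basic,
            "patent_rate_unlinked": self.patent_rate_unlinked,
            "background_cited_patents_per_drug": self.background_cited_patents_per_drug,
        }
        for name, r in rates.items():
            if r < 0:
                raise ValueError(f"{name} must be >= 0, got {r}")
        if abs(sum(self.lag_probs) - 1.0) > 1e-9:
            raise ValueError("lag_probs must sum to 1")
        if self.n_projects == 0 and self.pubs_per_project_year > 0:
            raise ValueError("infeasible: zero projects with nonzero publication rate")
        if self.n_drugs <= 0:
            raise ValueError("need at least one drug")

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in data.items() if k in known}
        for key in ("project_start_range", "window", "lag_probs"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass(frozen=True)
class GroundTruth:
    """Generator-side bookkeeping of what the pipeline should recover."""

    all_research: ResearchBlock
    patent_linked: ResearchBlock
    matched_patents_any: frozenset[str]
    matched_patents_linked: frozenset[str]
    n_drugs_matched_any: int
    n_drugs_matched_linked: int
    # link-level accounting for distributional checks
    n_publications: int
    n_links: int
    n_links_excluded: int

    def patent_linked_py_cost_pct(self, slice_name: str = "total") -> float | None:
        """Patent-linked share of project-year costs, in percent."""
        den = self.all_research.project_year_cost_cents.get(slice_name)
        if den == 0:
            return None
        return 100.0 * self.patent_linked.project_year_cost_cents.get(slice_name) / den

    def to_json_dict(self) -> dict:
        def block(b: ResearchBlock) -> dict:
            out = {
                name: {"applied": getattr(b, name).applied, "basic": getattr(b, name).basic}
                for name in (
                    "pmids",
                    "project_years",
                    "project_year_cost_cents",
                    "projects",
                    "total_project_cost_cents",
                )
            }
            if b.patents is not None:
                out["patents"] = {"applied": b.patents.applied, "basic": b.patents.basic}
            return out

        return {
            "all_research": block(self.all_research),
            "patent_linked": block(self.patent_linked),
            "matched_patents_any": sorted(self.matched_patents_any),
            "matched_patents_linked": sorted(self.matched_patents_linked),
            "n_drugs_matched_any": self.n_drugs_matched_any,
            "n_drugs_matched_linked": self.n_drugs_matched_linked,
            "n_publications": self.n_publications,
            "n_links": self.n_links,
            "n_links_excluded": self.n_links_excluded,
        }


def _classed(counter: dict[str, int | np.integer]) -> ClassedValues:
    return ClassedValues(int(counter.get(APPLIED, 0)), int(counter.get(BASIC, 0)))


def simulate_universe(config: SimConfig) -> tuple[Universe, GroundTruth]:
    """Generate one universe and its ground truth. Same config → same output."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_drugs, rng_projects, rng_pubs, rng_patents, rng_cite = (
        np.random.default_rng(s) for s in streams
    )
    lo, hi = config.window

    # --- drugs and targets -------------------------------------------------
    drugs = []
    target_counter = 0
    for i in range(config.n_drugs):
        n_targets = 1 + int(rng_drugs.poisson(max(config.mean_targets_per_drug - 1, 0)))
        targets = [f"TGT{target_counter + k:04d}" for k in range(n_targets)]
        target_counter += n_targets
        drugs.append(
            {
                "drug_id": f"DRG{i + 1:04d}",
                "name": f"drug-{i + 1}",
                "approval_year": 2010 + int(rng_drugs.integers(0, 10)),
                "target_ids": frozenset(targets),
                "in_patent_db": bool(rng_drugs.random() < config.p_drug_in_patent_db),
            }
        )
    approvals = {d["drug_id"]: d["approval_year"] for d in drugs}
    by_approval = sorted(drugs, key=lambda d: (d["approval_year"], d["drug_id"]))
    in_db_drugs = [d["drug_id"] for d in drugs if d["in_patent_db"]]

    # --- projects: contiguous funded spans with log-normal annual costs ----
    start_lo, start_hi = config.project_start_range
    project_rows = []
    spans: dict[str, tuple[int, int]] = {}
    year_cost: dict[tuple[str, int], int] = {}
    for j in range(config.n_projects):
        pid = f"PRJ{j + 1:05d}"
        start = int(rng_projects.integers(start_lo, start_hi + 1))
        duration = 1 + int(rng_projects.poisson(max(config.project_duration_mean - 1, 0)))
        end = min(start + duration - 1, hi)
        spans[pid] = (start, end)
        for fy in range(start, end + 1):
            dollars = rng_projects.lognormal(config.cost_lognorm_mu, config.cost_lognorm_sigma)
            cents = int(round(dollars * 100))
            year_cost[(pid, fy)] = cents
            project_rows.append(
                {"core_project_number": pid, "fiscal_year": fy, "cost_cents": cents}
            )
    project_ids = sorted(spans)

    # --- CPI: smooth drift, rounded at source so files are lossless --------
    years = range(min(lo, config.base_year), max(hi, config.base_year) + 1)
    cpi = CPISeries(
        {y: round(100.0 * (1.0 + config.cpi_drift) ** (y - config.base_year), 4) for y in years},
        base_year=config.base_year,
    )

    # --- publications with lag and search provenance -----------------------
    pub_rows = []
    link_rows: list[tuple[str, str]] = []
    pub_info: dict[str, tuple[int, str]] = {}  # pmid -> (pub_year, class)
    n_lags = len(config.lag_probs)
    pmid_counter = 0
    for pid in project_ids:
        start, end = spans[pid]
        for fy in range(start, end + 1):
            for _ in range(int(rng_pubs.poisson(config.pubs_per_project_year))):
                lag = int(rng_pubs.choice(n_lags, p=config.lag_probs))
                pub_year = fy + lag
                eligible = [d for d in by_approval if d["approval_year"] >= pub_year]
                if not eligible:
                    continue  # post-approval research is outside the search window
                drug = eligible[int(rng_pubs.integers(len(eligible)))]
                is_applied = rng_pubs.random() < config.p_drug_match
                pmid_counter += 1
                pmid = f"PM{pmid_counter:07d}"
                if is_applied:
                    matched_drugs: frozenset[str] = frozenset([drug["drug_id"]])
                    matched_targets: frozenset[str] = frozenset()
                else:
                    targets = sorted(drug["target_ids"])
                    matched_drugs = frozenset()
                    matched_targets = frozenset(
                        [targets[int(rng_pubs.integers(len(targets)))]]
                    )
                pub_rows.append(
                    {
                        "pmid": pmid,
                        "pub_year": pub_year,
                        "matched_drug_ids": matched_drugs,
                        "matched_target_ids": matched_targets,
                    }
                )
                pub_info[pmid] = (pub_year, APPLIED if is_applied else BASIC)
                link_rows.append((pmid, pid))
                if config.n_projects > 1 and rng_pubs.random() < config.p_second_link:
                    other = pid
                    while other == pid:
                        other = project_ids[int(rng_pubs.integers(len(project_ids)))]
                    link_rows.append((pmid, other))

    # --- ground-truth attribution (bookkeeping, not the pipeline) ----------
    policy = LagPolicy(max_lag_years=config.max_lag_years)
    py_pmids: dict[tuple[str, int], set[str]] = {}
    n_links_excluded = 0
    for pmid, pid in link_rows:
        pub_year, _cls = pub_info[pmid]
        first, last = spans[pid]
        fy = assign_project_year(pub_year, first, last, policy)
        if fy is None:
            n_links_excluded += 1
        else:
            py_pmids.setdefault((pid, fy), set()).add(pmid)

    py_class = {
        key: (APPLIED if any(pub_info[p][1] == APPLIED for p in pmids) else BASIC)
        for key, pmids in py_pmids.items()
    }
    project_pmids: dict[str, set[str]] = {}
    for (pid, _fy), pmids in py_pmids.items():
        project_pmids.setdefault(pid, set()).update(pmids)
    project_class = {
        pid: (APPLIED if any(pub_info[p][1] == APPLIED for p in pmids) else BASIC)
        for pid, pmids in project_pmids.items()
    }

    adj = {
        (pid, fy): inflation_adjust(cents, fy, cpi) for (pid, fy), cents in year_cost.items()
    }

    def block_over(projects_subset: set[str] | None) -> ResearchBlock:
        keys = [
            k for k in py_pmids if projects_subset is None or k[0] in projects_subset
        ]
        pmid_set: set[str] = set().union(*(py_pmids[k] for k in keys)) if keys else set()
        pmid_counts: dict[str, int] = {}
        for p in pmid_set:
            pmid_counts[pub_info[p][1]] = pmid_counts.get(pub_info[p][1], 0) + 1
        py_counts: dict[str, int] = {}
        py_costs: dict[str, int] = {}
        for k in keys:
            cls = py_class[k]
            py_counts[cls] = py_counts.get(cls, 0) + 1
            py_costs[cls] = py_costs.get(cls, 0) + adj[k]
        proj_set = {k[0] for k in keys}
        proj_counts: dict[str, int] = {}
        total_costs: dict[str, int] = {}
        for pid in proj_set:
            cls = project_class[pid]
            proj_counts[cls] = proj_counts.get(cls, 0) + 1
            first, last = spans[pid]
            total_costs[cls] = total_costs.get(cls, 0) + sum(
                adj[(pid, fy)] for fy in range(first, last + 1)
            )
        return ResearchBlock(
            pmids=_classed(pmid_counts),
            project_years=_classed(py_counts),
            project_year_cost_cents=_classed(py_costs),
            projects=_classed(proj_counts),
            total_project_cost_cents=_classed(total_costs),
        )

    all_research = block_over(None)

    # --- patents: class-dependent rates, drawn after attribution -----------
    patent_rows = []
    patent_owner: dict[str, str] = {}
    patent_counter = 0
    for pid in project_ids:
        cls = project_class.get(pid)
        if cls == APPLIED:
            rate = config.patent_rate_applied
        elif cls == BASIC:
            rate = config.patent_rate_basic
        else:
            rate = config.patent_rate_unlinked
        for _ in range(int(rng_patents.poisson(rate))):
            patent_counter += 1
            pnum = f"PAT{patent_counter:05d}"
            patent_rows.append({"patent_number": pnum, "core_project_number": pid})
            patent_owner[pnum] = pid

    # --- exclusivity citations: sparse NIH hits plus non-NIH background ----
    citation_rows = []
    cited_nih: dict[str, str] = {}  # patent -> drug
    if in_db_drugs:
        for pnum in sorted(patent_owner):
            if rng_cite.random() < config.p_cite:
                drug_id = in_db_drugs[int(rng_cite.integers(len(in_db_drugs)))]
                cited_nih[pnum] = drug_id
                citation_rows.append(
                    {"drug_id": drug_id, "patent_number": pnum, "source": "orange_book"}
                )
        bg_counter = 0
        for drug_id in in_db_drugs:
            for _ in range(int(rng_cite.poisson(config.background_cited_patents_per_drug))):
                bg_counter += 1
                citation_rows.append(
                    {
                        "drug_id": drug_id,
                        "patent_number": f"BGP{bg_counter:05d}",
                        "source": "orange_book",
                    }
                )

    matched_any = frozenset(cited_nih)
    linked_projects = set(project_pmids)
    matched_linked = frozenset(
        p for p in matched_any if patent_owner[p] in linked_projects
    )
    patent_cls_counts: dict[str, int] = {}
    for p in matched_linked:
        cls = project_class[patent_owner[p]]
        patent_cls_counts[cls] = patent_cls_counts.get(cls, 0) + 1
    owners_with_matched = {patent_owner[p] for p in matched_linked}
    linked_block = block_over(owners_with_matched)
    patent_linked = ResearchBlock(
        pmids=linked_block.pmids,
        project_years=linked_block.project_years,
        project_year_cost_cents=linked_block.project_year_cost_cents,
        projects=linked_block.projects,
        total_project_cost_cents=linked_block.total_project_cost_cents,
        patents=_classed(patent_cls_counts),
    )

    ground_truth = GroundTruth(
        all_research=all_research,
        patent_linked=patent_linked,
        matched_patents_any=matched_any,
        matched_patents_linked=matched_linked,
        n_drugs_matched_any=len({cited_nih[p] for p in matched_any}),
        n_drugs_matched_linked=len({cited_nih[p] for p in matched_linked}),
        n_publications=len(pub_rows),
        n_links=len(link_rows),
        n_links_excluded=n_links_excluded,
    )

    universe = Universe(
        drugs=pd.DataFrame(
            drugs, columns=["drug_id", "name", "approval_year", "target_ids", "in_patent_db"]
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
    return universe, ground_truth


def write_simulation(
    universe: Universe, ground_truth: GroundTruth, directory: str | Path
) -> None:
    """Emit the six universe files, cpi.csv, and ground_truth.json."""
    directory = Path(directory)
    uio.write_universe(universe, directory)
    (directory / "ground_truth.json").write_text(
        json.dumps(ground_truth.to_json_dict(), indent=2, sort_keys=True) + "\n"
    )
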