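"""Summary-table assembly: counts, costs, and percentage cells.

The ledger is the machine-readable twin of the study's three summary
tables:

* table 1 — drug and patent counts with their shares;
* table 2 — publications, project years, costs, and projects by research
  class, once for all research and once restricted to patent-linked
  projects;
* table 3 — the patent-linked share of each quantity, per class.

Percentage cells follow the tables' mixed conventions: whole percents for
the large class-share cells, one decimal for drug/patent shares, and two
significant figures for the sub-1% patent-linked shares. Rendering uses
round-half-away-from-zero; the raw unrounded ratio is always emitted next
to the rendered cell so any cell can be audited.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .model import ClassedValues, ResearchBlock

_SLICES = ("total", "applied", "basic")


def percent(
    numerator: float,
    denominator: float,
    *,
    decimals: int | None = None,
    sig: int | None = None,
) -> tuple[float | None, str]:
    """Percentage ratio as (raw value, rendered cell).

    Exactly one of ``decimals`` (fixed decimal places) or ``sig``
    (significant figures) selects the rendering precision; ties round half
    away from zero. A zero denominator renders as ``"NA"`` with raw None.
    """
    if (decimals is None) == (sig is None):
        raise ValueError("specify exactly one of decimals= or sig=")
    if denominator == 0:
        return None, "NA"
    ratio = decimal.Decimal(100) * decimal.Decimal(numerator) / decimal.Decimal(denominator)
    if sig is not None:
        if ratio == 0:
            places = 2
        else:
            places = max(sig - 1 - int(abs(ratio).log10().to_integral_value("ROUND_FLOOR")), 0)
    else:
        places = decimals
    quant = decimal.Decimal(1).scaleb(-places)
    rendered = ratio.quantize(quant, rounding=decimal.ROUND_HALF_UP)
    return float(ratio), f"{rendered}%"


@dataclass(frozen=True)
class LedgerSummary:
    """All cells of the three summary tables, in exact (unrounded) units."""

    # table 1 scalars
    n_drugs_total: int
    n_drugs_in_patent_db: int
    n_drugs_with_citation: int
    n_cited_patents: int
    n_nih_cited_patents_any: int
    n_drugs_matched_any: int
    n_drugs_matched_linked: int
    # table 2 search row (counts only, no percentage cells)
    n_searches_drug: int
    n_searches_target: int
    # table 2 blocks (table 3 is fully derived from these two)
    all_research: ResearchBlock
    patent_linked: ResearchBlock

    @property
    def n_nih_cited_patents_linked(self) -> int:
        patents = self.patent_linked.patents
        return patents.total if patents is not None else 0


class LedgerError(ValueError):
    pass


def _check_ledger(ledger: LedgerSummary) -> None:
    lab = "ledger consistency"
    if ledger.n_nih_cited_patents_linked > ledger.n_nih_cited_patents_any:
        raise LedgerError(
            f"{lab}: publication-linked patents exceed any-report patents "
            f"(table 1, NIH-funded patent rows)"
        )
    if ledger.n_drugs_matched_linked > ledger.n_drugs_matched_any:
        raise LedgerError(f"{lab}: linked drug count exceeds any-report drug count")
    if ledger.n_drugs_with_citation > ledger.n_drugs_in_patent_db:
        raise LedgerError(f"{lab}: drugs with citations exceed drugs in patent database")
    for name in (
        "pmids",
        "project_years",
        "project_year_cost_cents",
        "projects",
        "total_project_cost_cents",
    ):
        linked: ClassedValues = getattr(ledger.patent_linked, name)
        full: ClassedValues = getattr(ledger.all_research, name)
        if linked.total > full.total:
            raise LedgerError(
                f"{lab}: patent-linked {name} total exceeds all-research total "
                f"(table 3 row {name})"
            )
    for block_name in ("all_research", "patent_linked"):
        block: ResearchBlock = getattr(ledger, block_name)
        if block.project_year_cost_cents.total > block.total_project_cost_cents.total:
            raise LedgerError(
                f"{lab}: project-year costs exceed total project costs in {block_name}"
            )


def build_tables(
    table1_counts: dict[str, int],
    all_research: ResearchBlock,
    patent_linked: ResearchBlock,
    searches: tuple[int, int] = (0, 0),
) -> LedgerSummary:
    """Assemble and validate the ledger from pipeline outputs.

    ``table1_counts`` carries the drug/patent scalars (keys matching the
    LedgerSummary field names without the ``n_`` prefix is not required;
    exact field-name keys are expected). Raises :class:`LedgerError` naming
    the offending cell if any internal invariant fails.
    """
    if patent_linked.patents is None:
        raise LedgerError("patent-linked block must carry patent counts")
    ledger = LedgerSummary(
        n_drugs_total=table1_counts["n_drugs_total"],
        n_drugs_in_patent_db=table1_counts["n_drugs_in_patent_db"],
        n_drugs_with_citation=table1_counts["n_drugs_with_citation"],
        n_cited_patents=table1_counts["n_cited_patents"],
        n_nih_cited_patents_any=table1_counts["n_nih_cited_patents_any"],
        n_drugs_matched_any=table1_counts["n_drugs_matched_any"],
        n_drugs_matched_linked=table1_counts["n_drugs_matched_linked"],
        n_searches_drug=searches[0],
        n_searches_target=searches[1],
        all_research=all_research,
        patent_linked=patent_linked,
    )
    _check_ledger(ledger)
    return ledger


def _musd(cents: int) -> str:
    """Render cents as millions of base-year dollars, one decimal."""
    value = decimal.Decimal(cents) / decimal.Decimal(100_000_000)
    return str(value.quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP))


def _usd(cents: int) -> str:
    return f"{cents / 100:.2f}"


def render_table1(ledger: LedgerSummary) -> pd.DataFrame:
    rows = []

    def add(row, value, num=None, den=None):
        raw, cell = (None, "") if num is None else percent(num, den, decimals=1)
        rows.append(
            {
                "row": row,
                "value": value,
                "pct": cell,
                "pct_raw": "" if raw is None else repr(raw),
            }
        )

    add("drugs_approved", ledger.n_drugs_total)
    add("drugs_in_patent_db", ledger.n_drugs_in_patent_db)
    add("drugs_with_at_least_one_patent", ledger.n_drugs_with_citation)
    add("cited_patents", ledger.n_cited_patents)
    add(
        "nih_funded_cited_patents_any_report",
        ledger.n_nih_cited_patents_any,
        ledger.n_nih_cited_patents_any,
        ledger.n_cited_patents,
    )
    add(
        "nih_funded_cited_patents_publication_linked",
        ledger.n_nih_cited_patents_linked,
        ledger.n_nih_cited_patents_linked,
        ledger.n_cited_patents,
    )
    add(
        "drugs_with_nih_patent_any_report",
        ledger.n_drugs_matched_any,
        ledger.n_drugs_matched_any,
        ledger.n_drugs_in_patent_db,
    )
    add(
        "drugs_with_nih_patent_publication_linked",
        ledger.n_drugs_matched_linked,
        ledger.n_drugs_matched_linked,
        ledger.n_drugs_in_patent_db,
    )
    return pd.DataFrame(rows, columns=["row", "value", "pct", "pct_raw"])


_TABLE2_ROWS = [
    ("pmids", "count"),
    ("project_years", "count"),
    ("project_year_cost_cents", "cost"),
    ("projects", "count"),
    ("total_project_cost_cents", "cost"),
]


def render_table2(ledger: LedgerSummary) -> pd.DataFrame:
    rows = []
    rows.append(
        {
            "block": "all_research",
            "quantity": "searches",
            "total": "",
            "applied": str(ledger.n_searches_drug),
            "applied_pct": "",
            "basic": str(ledger.n_searches_target),
            "basic_pct": "",
            "applied_raw": str(ledger.n_searches_drug),
            "basic_raw": str(ledger.n_searches_target),
            "pct_raw_applied": "",
            "pct_raw_basic": "",
        }
    )
    for block_name in ("all_research", "patent_linked"):
        block: ResearchBlock = getattr(ledger, block_name)
        quantities = list(_TABLE2_ROWS)
        if block.patents is not None:
            quantities = [("patents", "count")] + quantities
        for name, kind in quantities:
            cv: ClassedValues = getattr(block, name)
            fmt = _musd if kind == "cost" else str
            label = name.replace("_cents", "_musd") if kind == "cost" else name
            raw_a, pct_a = percent(cv.applied, cv.total, decimals=0)
            raw_b, pct_b = percent(cv.basic, cv.total, decimals=0)
            rows.append(
                {
                    "block": block_name,
                    "quantity": label,
                    "total": fmt(cv.total),
                    "applied": fmt(cv.applied),
                    "applied_pct": pct_a,
                    "basic": fmt(cv.basic),
                    "basic_pct": pct_b,
                    "applied_raw": _usd(cv.applied) if kind == "cost" else str(cv.applied),
                    "basic_raw": _usd(cv.basic) if kind == "cost" else str(cv.basic),
                    "pct_raw_applied": "" if raw_a is None else repr(raw_a),
                    "pct_raw_basic": "" if raw_b is None else repr(raw_b),
                }
            )
    return pd.DataFrame(rows)


def render_table3(ledger: LedgerSummary) -> pd.DataFrame:
    """Patent-linked share of each quantity, per class (2 significant figures)."""
    rows = []
    for name, kind in _TABLE2_ROWS:
        if name == "projects":
            continue  # the printed share table reports the four flow quantities
        linked: ClassedValues = getattr(ledger.patent_linked, name)
        full: ClassedValues = getattr(ledger.all_research, name)
        fmt = _musd if kind == "cost" else str
        label = name.replace("_cents", "_musd") if kind == "cost" else name
        for slice_name in _SLICES:
            raw, cell = percent(linked.get(slice_name), full.get(slice_name), sig=2)
            rows.append(
                {
                    "quantity": label,
                    "slice": slice_name,
                    "patent_linked": fmt(linked.get(slice_name)),
                    "all_research": fmt(full.get(slice_name)),
                    "pct": cell,
                    "pct_raw": "" if raw is None else repr(raw),
                }
            )
    return pd.DataFrame(rows)


def write_ledger(ledger: LedgerSummary, directory: str | Path) -> None:
    """Write table1/2/3 CSVs; byte-identical for identical ledgers."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    render_table1(ledger).to_csv(directory / "table1.csv", index=False, lineterminator="\n")
    render_table2(ledger).to_csv(directory / "table2.csv", index=False, lineterminator="\n")
    render_table3(ledger).to_csv(directory / "table3.csv", index=False, lineterminator="\n")


def _cents(raw: str) -> int:
    return int(round(float(raw) * 100))


def read_ledger(directory: str | Path) -> LedgerSummary:
    """Reconstruct a ledger from its written tables (inverse of write_ledger)."""
    directory = Path(directory)
    t1 = pd.read_csv(directory / "table1.csv", dtype=str, keep_default_na=False)
    t2 = pd.read_csv(directory / "table2.csv", dtype=str, keep_default_na=False)
    v1 = dict(zip(t1["row"], t1["value"].astype(int)))

    def block_from(frame: pd.DataFrame, block_name: str) -> ResearchBlock:
        sub = frame.loc[frame["block"] == block_name].set_index("quantity")

        def classed(label: str, cost: bool) -> ClassedValues:
            row = sub.loc[label]
            conv = _cents if cost else int
            return ClassedValues(conv(row["applied_raw"]), conv(row["basic_raw"]))

        patents = None
        if "patents" in sub.index:
            patents = classed("patents", cost=False)
        return ResearchBlock(
            pmids=classed("pmids", False),
            project_years=classed("project_years", False),
            project_year_cost_cents=classed("project_year_cost_musd", True),
            projects=classed("projects", False),
            total_project_cost_cents=classed("total_project_cost_musd", True),
            patents=patents,
        )

    searches = t2.loc[t2["quantity"] == "searches"].iloc[0]
    return LedgerSummary(
        n_drugs_total=v1["drugs_approved"],
        n_drugs_in_patent_db=v1["drugs_in_patent_db"],
        n_drugs_with_citation=v1["drugs_with_at_least_one_patent"],
        n_cited_patents=v1["cited_patents"],
        n_nih_cited_patents_any=v1["nih_funded_cited_patents_any_report"],
        n_drugs_matched_any=v1["drugs_with_nih_patent_any_report"],
        n_drugs_matched_linked=v1["drugs_with_nih_patent_publication_linked"],
        n_searches_drug=int(searches["applied_raw"]),
        n_searches_target=int(searches["basic_raw"]),
        all_research=block_from(t2, "all_research"),
        patent_linked=block_from(t2, "patent_linked"),
    )
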