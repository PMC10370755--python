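# Methods

## The accounting model

`exclink` treats research funding attribution as deterministic accounting,
not estimation. Given six record tables — drugs with approval years and
targets, publications with search provenance, grants with per-fiscal-year
costs, publication–grant links, grant–patent records, and drug–patent
exclusivity citations — every output cell is a count or an exact cent sum
over sets defined by fixed rules. There is no fitting, sampling, or
smoothing anywhere in the pipeline; all randomness lives in the synthetic
generator.

### Classification

A publication is **applied** research if it was found by a drug-name
search (its `matched_drug_ids` is non-empty), and **basic** if it was found
only by a target search. A drug match dominates a simultaneous target
match. The label propagates by an all-or-nothing fold: a project year,
project, or patent is basic iff *every* publication in its evidence set is
basic. A consequence worth noting: the per-class splits of project years
and of projects are computed at different units, so a project year can be
basic while its project is applied. The per-class *project-year* cost sums
therefore need not be bounded by the per-class *total project* cost sums —
only the totals (and each project individually) satisfy
project-year ≤ total. A patent owned by projects with conflicting classes
is classed applied, the same fold applied to the patent's full evidence
set.

### Attribution and lag

Each (publication, grant) link is attributed to one fiscal year of that
grant: the publication year itself when it lies inside the funded span
[first, last]; the last funded year when the publication appears 1 to
`max_lag_years` (default 4, inclusive) years after funding ends; excluded
when it predates the first funded year or exceeds the lag window. The lag
cap is a tunable `LagPolicy`; widening it is monotone — it can only add
attributed project years — which the lag-sensitivity harness
(`lag_sensitivity`) verifies over `max_lag ∈ {0..4}`. The
`pre_funding_exclude` switch (default on) exists for sensitivity analysis;
turning it off assigns pre-funding publications to the first funded year.

Fiscal years are treated as calendar years: a publication dated 2012 maps
to fiscal year 2012. The US federal October–September fiscal-year offset
is deliberately not modelled; with annual-resolution inputs the
reconciliation is unidentifiable, and the attribution rule is stated in
whole years. The switch point is `assign_project_year`, the single total
function of (publication year, first, last) that any alternative
convention would replace.

### Deduplication and costs

The unit of cost accounting is the unique (grant, fiscal year) pair.
Duplicate attributions (several publications landing on the same pair)
are merged by unioning the supporting publication sets; `dedupe` is
idempotent. Costs are stored as integer cents end-to-end, so class
additivity (applied + basic = total) holds to the cent by construction.

Two aggregates are reported. **Project-year costs** sum the adjusted costs
of attributed pairs only. **Total project costs** sum every in-window
fiscal year of each grant with ≥ 1 attributed year, each grant counted
once. Funding histories are clipped to the 2000–2019 study window *before*
any span or sum is computed; an attributed year with no cost record (a gap
in a funding history) is a fatal input inconsistency rather than a silent
zero.

Inflation adjustment multiplies nominal cents by
`index(base_year) / index(year)` (base year 2018) and rounds half away
from zero to the cent. The same rounding is used everywhere money is
rounded.

### The exclusivity join

Patent numbers are normalised before joining (whitespace/comma stripping,
uppercasing, removal of a `US` prefix and trailing kind code from numeric
numbers; non-numeric identifiers pass through). Two modes:

- **any-report** — every grant–patent record participates; no class is
  reported because patents on grants without attributed publications have
  no evidence set to classify.
- **publication-linked** — restricted to patents whose owning grants have
  ≥ 1 attributed project year; always a subset of any-report. Patent
  classes fold over the linked owning grants.

The patent-linked funding block restricts the aggregates to grants owning
≥ 1 matched patent (and having attributed years), giving the lower half of
the funding table and, divided by the all-research block, the share table.

### Rendering

Percentage cells mimic the published tables' mixed conventions: whole
percents for the large class-share cells, one decimal for drug/patent
shares, two significant figures for the sub-1% patent-linked shares, all
rounded half away from zero via exact decimal arithmetic. The raw
unrounded ratio is emitted beside every rendered cell so any cell can be
audited; a zero denominator renders `NA`. One known quirk this exposes:
the patent-linked share of project-year costs renders 0.58% from its own
marginals (954.0 / 163,878) while the source study's abstract prints
0.59%, presumably computed from unrounded costs; the ledger reports the
raw ratio and makes no attempt to force either rendering. Ledger writing
is byte-deterministic and invertible (`read_ledger`).

## The synthetic generator

`simulate_universe` emulates the *structure* the analysis assumes, not any
real database: drugs (approvals uniform over 2010–2019, ~88% listed in the
patent database) each with ≥ 1 target; grants with contiguous funded spans
(uniform start, 1 + Poisson duration, mean 4 years) and log-normal annual
costs (median ≈ $480k/project-year, the magnitude implied by dividing the
study-scale project-year cost total by its project-year count; σ = 0.8);
publications per funded year (Poisson, rate 1.0) with a lag distribution
over 0–6 years whose support deliberately exceeds the 4-year cap so the
exclusion branch is exercised; a 9% drug-match (applied) probability
matching the study-scale applied share; a 10% chance of a second grant
link (which also exercises pre-funding exclusion); patents at
class-dependent Poisson rates (0.40 applied / 0.10 basic / 0.05 for grants
without attributed publications — the applied/basic asymmetry the data
exhibit, with the overall mean near the study's patents-per-project
ratio); and sparse exclusivity citation of NIH patents (0.5%, the order of
the study's 119/22,360) over a background of ~12 non-NIH cited patents per
listed drug. CPI drifts at 2%/year and is rounded to 4 decimals at source
so files round-trip losslessly.

Randomness uses one `SeedSequence` split into five fixed-order child
streams (drugs, projects, publications, patents, citations), so extending
a later stage cannot perturb an earlier one.

Ground truth is computed by generator-side bookkeeping — plain Python
loops over the records just emitted — sharing only the attribution rule
and the cent-rounding inflation formula with the pipeline; all set
construction and summation is independent of the pandas implementation.
Because the pipeline is deterministic accounting, recovery tests demand
*exact* equality of every per-class count, cent sum, and matched-patent
set, across seeds.

What the generator does **not** emulate: real search sensitivity and
specificity (match sets are inputs, never derived from text), multi-year
publication support, sub-projects of multi-component awards, patent
families or expiry arithmetic, and correlations between drug importance
and funding volume. Passing recovery tests therefore certifies the
accounting, not the realism of any particular input database.

## The marginal fixture

`make_marginal_fixture` builds a deterministic universe whose
aggregates reproduce, through the full pipeline, the published count-level
marginals: 356/313/297 drugs, 3,644 cited patents, 119 NIH-funded cited
patents of which 104 are publication-linked (protecting 34 and 29 drugs
respectively), and the entire patent-linked funding block (61/43 patents,
546/3,484 publications, 242/527 project years, $436.7M/$517.3M
project-year costs, 61/59 projects, $939.95M/$202.35M total costs — the
last pair chosen so the rendered millions reproduce the printed
940.0/202.4/1,142.3 cells, whose printed sum reflects pre-rounding
arithmetic). Its CPI is flat (index 100 every year) so encoded dollar
amounts survive adjustment unchanged, and publication matches point at a
2019-approval drug so every publication year satisfies the search-window
invariant. The study-scale upper-block totals (349,797 publications,
$163,878M project-year costs, …) derive from licensed databases and are
not reproducible record-by-record at this scale; they are carried as
printed marginal counts (`published_marginals`) and enter only as
numerators and denominators of percentage cells.

## Problem sizes and determinism

Tests and the acceptance script run the generator at 100–300 grants and
20–21 seeds — large enough that every branch (lag inclusion, lag
exclusion, pre-funding exclusion, multi-grant links, both join modes,
class conflicts) is exercised on every seed, while the whole suite
completes in seconds. Recovery checks use an elevated citation probability
(0.15) so the patent-linked block is non-trivial on every seed; the
default 0.005 reflects realistic sparsity and is exercised separately.
Everything downstream of the generator is deterministic; ledger and
universe writers are byte-stable, which the determinism tests assert by
hashing.

## Known limitations

- Calendar-year fiscal treatment (above) is an approximation with no
  ground truth available at annual resolution.
- A publication linked to k grants creates up to k attributed project
  years; no attempt is made to split a publication's "credit" across
  grants, and a multi-class project year's full cost is assigned to its
  folded class (whole-unit assignment, matching the additive structure of
  the published tables).
- Per-drug cost breakdowns are out of scope: multi-drug project years are
  counted once at universe level.
- The loader enforces the publication window (1960 ≤ year ≤ approval of
  every matched drug, including via targets); records violating it are
  rejected rather than silently filtered, so upstream search artifacts
  must be cleaned before loading.
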