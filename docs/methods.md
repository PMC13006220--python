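# Methods

## Data model and ingestion

FAERS quarters are `$`-delimited ASCII tables (DEMO, DRUG, REAC, OUTC,
THER, INDI) joined on a report-level PRIMARYID. The dialect has no quoting;
a line whose field count disagrees with the header is logged and skipped
rather than guessed at. Dates arrive as YYYYMMDD digit strings but often
carry only YYYY or YYYYMM; they are parsed into `PartialDate` values with
an explicit precision instead of being dropped, so that each analysis can
impose its own resolution requirement (deduplication orders on whatever
precision exists; time-to-onset demands day precision and excludes the
rest, with the exclusions counted).

A case resubmitted to the FDA appears under one CASEID with several
CASEVERSIONs. Deduplication keeps, per case, the row maximising
(`fda_dt`, `caseversion`, `primaryid`) lexicographically — "latest version
wins", with the receipt date first so that a corrected version filed later
always supersedes, and the remaining components making the choice
deterministic under ties. The operation is idempotent and its output is
sorted by case id. Rows of other tables whose primaryid has no surviving
DEMO row (typically rows belonging to superseded versions) are counted as
orphans and never attached.

## Cohort construction

Seven fixed-dose products are targeted (five dual LABA/LAMA, two triple
ICS/LABA/LAMA). A report enters the cohort when one of its
**primary-suspect** (role `PS`) drug records matches a product: after
normalisation (uppercase, punctuation except `/` collapsed to spaces), a
dictionary name must be a substring of `drugname` or `prod_ai`, or every
component of a generic name must appear in one of those fields regardless
of order. When several products match the same record, the match with the
larger matched component set wins — a name spelling out a triple
combination necessarily contains the component set of the dual product
nested inside it (BUDESONIDE/GLYCOPYRROLATE/FORMOTEROL contains
formoterol+glycopyrrolate), and treating that as ambiguity would silently
discard most triple-therapy reports. Only a tie at equal specificity is a
genuine ambiguity; such reports are excluded and logged, keeping the
per-product 2×2 tables disjoint. Each product has a search window from its
market-entry quarter to 2024 Q3; the report's quarter is derived from the
FDA receipt date, the field the quarterly packaging is keyed on.

A **cardiac adverse event (CAE) case** is a cohort report with at least one
reaction PT whose primary SOC is Cardiac disorders. PTs are counted once
per report. PTs absent from the dictionary go to an `unmapped` bucket —
never to cardiac — and are tallied. The shipped PT→SOC map is a small
synthetic mock with invented codes (real MedDRA is licensed); any TSV with
columns `pt_name, pt_code, soc_name, soc_code` can replace it.

Outcome severity uses the fixed total order DE > LT > DS > CA > HO > RI >
OT (death first, per the FDA outcome-code convention); a case is summarised
by its most severe code. The characteristics table reports outcomes both
per case (most-severe rule) and per cardiac-PT occurrence (each PT inherits
its case's most severe outcome), because published tables mix the two
denominators. Percentages are rounded half-up to two decimals.

## Disproportionality statistics

The counting unit is the report; the background is every other report in
the supplied dataset. For a pair (drug, PT): a = drug reports with the PT,
b = without, c = other reports with it, d = without; n = a+b+c+d.

- ROR = (a·d)/(b·c), CI = exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)), z = 1.96
  (normal approximation). Zero cells leave the estimate undefined — no
  continuity correction is added, because pairs that rare are handled by
  the a-count threshold and by BCPNN, and a patched odds ratio would
  silently change the screen's operating characteristics.
- PRR = [a/(a+b)]/[c/(c+d)], CI = exp(ln PRR ± z·√(1/a − 1/(a+b) + 1/c −
  1/(c+d))).
- χ² = n·(|ad−bc| − n/2)²/[(a+b)(c+d)(a+c)(b+d)], clamped to 0 when
  |ad−bc| ≤ n/2. The Yates correction is the package default and a config
  switch (`yates=False` gives the uncorrected statistic).
- BCPNN information component, closed-form Bayesian estimate with
  hyperparameters α₁ = β₁ = 1, α = β = 2, γ₁₁ = 1 and
  γ = γ₁₁(n+α)(n+β)/[(a+b+α₁)(a+c+β₁)]:
  IC = log₂[(a+γ₁₁)(n+α)(n+β) / ((n+γ)(a+b+α₁)(a+c+β₁))], with the
  matching delta-method variance and IC025 = IC − 2√V. The hyperparameters
  are exposed in `BcpnnParams`.

The combined signal rule requires, simultaneously: a ≥ 3 ("more than two
reports", implemented on integer counts), ROR lower 95% bound > 1, PRR
lower 95% bound > 1, PRR ≥ 2, χ² ≥ 4. Undefined metrics fail closed with
an "insufficient data" reason. Signal intensity is graded from IC025 —
weak ≤ 1.5 < moderate ≤ 3 < strong — which is this package's convention
for turning the Bayesian bound into three bands; the thresholds live in
one function (`grade_intensity`) and are documented here deliberately,
since grading conventions vary between groups. Pairs observed at least
once but below the a-threshold go to a companion table evaluated with
BCPNN only (IC025 > 0 as its flag), which is the estimator that remains
defined at such counts. No multiple-testing adjustment is applied;
disproportionality screens conventionally report unadjusted signals, and
the null-pair false-flag rate is instead quantified by simulation (below).

## Subgroup analyses

**Time to onset** is the whole-day difference from therapy start (earliest
day-precision THER start among the matched drug's sequences) to the
report's event date. The receipt date is never substituted for a missing
event date — that would pile artificial mass near zero. Onsets are binned
as {0}, 1–30, 31–90, 91–180, 181–365, 366–730, ≥731 days: the partition
that reproduces every boundary quoted for this kind of analysis (day 0,
months 1/3/6/12, years 1/2). Exclusions (missing or sub-day-precision
dates; negative onsets) are counted so that included + excluded equals the
CAE case count. The cumulative curve is computed over unique onset days at
case level and is non-decreasing, ending at exactly 1. Stratified
compositions (by sex, or age above/below a threshold — 70.5 years as the
cohort-mean convention, 80 for the very elderly) report percentages
summing to 100 within each bin, with missing values as their own category.

**Death subset**: reports with outcome DE, per product: cardiac PT ranking
(descending, alphabetical tie-break), mean/median age over non-missing
ages, missingness fraction, and Welch two-sample t-tests (scipy) of each
product's ages against the pooled ages; groups under two observations are
skipped.

**Co-reported events**: among CAE cases, non-cardiac PTs and their SOCs
are ranked with one count per case; the headline share is the fraction of
CAE cases with at least one mapped non-cardiac PT, which equals one minus
the pure-cardiac fraction.

Ages with explicit non-year units are converted to years; values over 120
years are treated as missing.

## Synthetic data generator

The generator emulates the statistical structure the pipeline must detect,
not the clinical texture of real FAERS:

- Each report draws each vocabulary PT independently with its background
  rate; an injected (product, PT) pair multiplies the rate by a reporting
  ratio R (capped at 1; a configuration where rate·R > 1 is rejected). A
  report drawing nothing receives one fallback PT sampled from its own
  effective rates — conditioning that keeps reports non-empty without
  diluting injected dependence. `expected_table` gives the exact
  closed-form cell expectations including the fallback term, and is checked
  against Monte-Carlo means in the tests.
- Because R multiplies a probability, the ROR estimates the odds ratio,
  which exceeds R by roughly 1/(1−R·rate); at the default rates (≤ 0.012
  for cardiac PTs) the gap is within a few percent, and the recovery
  studies use rate 0.005 where it is negligible.
- Demographics: age ~ Normal(70.5, 12²) truncated to [19, 110], 32%
  missing; 44% female with 13% missing sex; categorical countries and
  reporter occupations. These are the marginals of the cardiac cohort the
  package was built around.
- Onset: a 20% point mass at day 0 plus a log-normal tail (median 90 days,
  σ = 1.2) rounded to whole days. The event date is placed uniformly in the
  product's search window, the therapy start back-dated by the onset, and
  the receipt date follows the event by up to 60 days. 20% of therapy
  starts are omitted and 15% of the rest truncated to month precision, so
  roughly a third of cases drop out of the onset analysis, as happens in
  real data. (Back-dating can place a therapy start slightly before a
  product's market entry; the analyses never consume the start date's
  calendar position, only the difference to the event date.)
- 10% of cases receive an extra earlier DEMO version (lower caseversion,
  receipt date 35 days earlier) with its own DRUG/REAC rows, exercising
  deduplication and orphan accounting; 5% of target reports carry the
  target drug in a non-primary role, exercising the PS filter.
- The default ("paperlike") scale is ~3,120 target reports over seven
  products against a 20,000-report background — the cohort-to-background
  ratio is orders of magnitude larger than in the real database, which is
  why real-database signal values are not reproducible here and the
  package's claims are calibration claims (below).

Everything is driven by one `numpy` generator seeded from the config;
outputs are byte-identical across runs. The ground-truth manifest exports
the realized per-pair 2×2 tables, injected ratios, and per-case onsets.

What passing tests show, and what they do not: recovery of injected
multiplicative dependence under independent-PT reporting says the
estimators and thresholds are implemented correctly and calibrated (CI
coverage 94–96%, null pairs flagged well under 7%); it says nothing about
confounding, duplicate reports that survive FDA deduplication, stimulated
reporting, or PT co-occurrence structure in real spontaneous data, none of
which the generator models.

## Numerical and design choices

- Rounding of printed percentages: decimal half-up at 2 places (banker's
  rounding would disagree with published tables on .005 boundaries).
- Dedup ties: resolved by the stated lexicographic key; no randomness.
- All ranked outputs break ties alphabetically for determinism.
- The pipeline asserts stage-count conservation (reports in = retained +
  excluded at match, window, extraction and onset stages) and fails rather
  than report inconsistent tallies.
- Analysis stages are deterministic; randomness is confined to the
  generator and simulation utilities.
- Screen sizes in the calibration tests (e.g. 3,000 target reports against
  20,000 background at rate 0.005, 100–200 replicate seeds) were chosen to
  put expected a ≥ 30 in every injected pair, the regime where the
  log-normal CI approximations hold.

## Known limitations

- The report-level counting unit means a PT occurring twice in one report
  counts once; PT-occurrence denominators (used for the outcome table) are
  reported alongside, since the two conventions differ by a few counts.
- The normal-approximation CIs and the IC delta-method variance are
  asymptotic; below a ≈ 20 their coverage degrades, which is precisely why
  the combined rule gates on a and low counts are routed to BCPNN.
- The mock SOC map covers the analysis vocabulary only; real MedDRA
  hierarchies (SMQs, multi-axial secondary SOCs) are out of scope — each
  PT maps to exactly one primary SOC.
- INDI is parsed and retained for schema completeness but unused by the
  analyses, mirroring the screen's design.
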