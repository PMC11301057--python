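# Methods

## Data model and ingestion

FAERS quarterly extracts are seven `$`-delimited ASCII tables with one
header line and no quoting (the source format cannot produce an embedded
`$`). The reader is header-driven: column order comes from the file, the
schema only requires that its minimum column set be present, and unknown
extra columns are preserved but ignored, because the FAERS column sets
drift across quarters. A line whose field count disagrees with the header
is a hard error carrying the line number — the parser never repairs or
drops rows. No field content (dates, ages, codes) is interpreted at this
layer; all coercion happens downstream where failures become explicit
statuses rather than lost rows. Files are decoded as UTF-8 with a latin-1
fallback, matching the encodings seen in real quarters.

The PT→SOC table (MedDRA preferred term → system organ class) must be
user-supplied as a two-column CSV/TSV because the dictionary is licensed.
Keys are whitespace-collapsed and case-folded; a PT mapped to two
different SOCs is a hard error, and a PT missing from the map is carried
through the analysis with SOC `UNMAPPED` and tallied, never dropped.

## Deduplication and cohort

Cases recur across quarterly releases under one CASEID with new PRIMARYIDs
and FDA receipt dates. One report per CASEID is kept: latest FDA_DT, ties
broken by the highest PRIMARYID. PRIMARYIDs compare numerically when both
are digit strings and lexicographically otherwise (FAERS ids are numeric
in practice; the fallback is defined so malformed data cannot crash the
rule). An unparseable FDA_DT sorts below every valid date, so a dated
version always beats an undated one. The operation is idempotent and
order-insensitive; output is sorted by ascending caseid.

Cohort membership requires at least one drug row whose name matches a
target term with a role in the role filter (default: primary suspect
only). Matching is substring containment after stripping case,
punctuation and spacing, so `LONSURF 20MG TABLET`, `TAS-102` and
`TRIFLURIDINE\TIPIRACIL` all match their respective terms. Substring
matching (not equality) is deliberate: FAERS drugname strings embed dose
and form text. No spelling correction or ingredient normalization is
attempted.

## Descriptive summary

Percentages are 100·count/denominator rounded half-up to two decimals,
computed in exact decimal arithmetic. The denominator is the cohort size
for every section — a report with several outcome codes contributes to
each outcome row, and outcomes are treated as a set, not enforced
exclusive — except indications, where the denominator is the total number
of indication entries (a report lists one indication per suspect drug, so
the report count is not a natural base). Ages are converted to years with
calendar factors (YR 1, DEC 10, MON 1/12, WK 1/52.18, DY 1/365.25,
HR 1/8766); missing or unconvertible ages fall into an explicit missing
bin. Default age bands are <18, 18–<65, ≥65.

## Contingency tables

The counting unit is the unique (report, term) pair: a report contributes
each of its PTs once, regardless of repetition in REAC. At SOC level a
report counts once per organ class. Tables are built over the full
deduplicated database (cohort + background); N and the cohort margin a+b
are therefore identical across terms at a level. Only terms with a ≥ 1
are screened. Zero cells get no Haldane-style correction: ROR and PRR are
simply non-evaluable there (their flags are false), which the a ≥ 3
criterion would gate out anyway.

## The four statistics

*ROR and PRR.* Standard forms: ROR = ad/bc with the Woolf log-normal CI
using the conventional 1.96 multiplier; PRR = [a/(a+b)]/[c/(c+d)] with
the Pearson χ² of the 2×2. The χ² is uncorrected by default with a Yates
switch, since published screens differ on this and the switch makes the
choice auditable.

*BCPNN.* The information component uses the closed posterior form of
Bate et al. (1998) with the standard weakly-informative hyperparameters
(uniform Beta(1,1) margins; joint prior calibrated so E[p11] = E[p1]E[p2]
a priori):

    γ = (N+2)² / [(a+b+1)(a+c+1)]
    E(IC) = log₂ [(a+1)(N+2)² / ((N+γ)(a+b+1)(a+c+1))]
    IC025 = E(IC) − 2√V(IC)

with V(IC) the delta-method variance of the same posterior. The closed
form approximates the posterior-mean IC with an O(1/a) gap (about
0.72/(a+1) bits); Monte-Carlo cross-checks in the test suite run at case
counts a ≥ 20 where the gap is below 0.05 bits. Below a ≈ 14 the closed
form overstates the posterior mean by more than that — irrelevant for
retention decisions, which require IC025 > 0 and in practice fire at
larger counts, but worth knowing when reading raw IC values for sparse
terms.

*MGPS.* The observed count a is modelled as Poisson(λE) with
λ ~ w·Gamma(α₁,β₁) + (1−w)·Gamma(α₂,β₂) (shape/rate). The five
hyperparameters are fitted by maximizing the summed log
negative-binomial mixture marginal across all tables at a level. The
optimizer is L-BFGS-B on a log/logit transform (positivity and the [0,1]
weight box hold by construction), multi-started from DuMouchel's
published point (0.2, 0.1, 2, 4, 1/3) plus four jittered starts drawn
from a fixed-seed generator; the best final value wins, making the fit
deterministic. Objective tolerance 1e-8. With single-gamma truth the
two-component fit typically parks a small-weight spike component on the
low-count cells; the dominant component still recovers the generating
(α, β) (verified to 25% at 500 cells in the tests). When the data
contain only a handful of signal cells with nearly identical
observed-to-expected ratios — common in small synthetic vocabularies,
rare in a real database with thousands of heterogeneous terms — the
maximum-likelihood fit can collapse a component to a near-point mass at
that common ratio; every matching cell is then shrunk to essentially the
same EBGM. This is the honest ML solution, not a failure mode: retention
decisions (EB05 > 2) are unaffected, but per-cell EBGM spread is lost in
that regime. Degenerate inputs (all a = 0) are an error, not a silent
fallback.

Given the fitted prior, the posterior over λ is again a two-gamma
mixture with components Gamma(αⱼ+a, βⱼ+E) and weights proportional to
the prior weight times the negative-binomial marginal.
EBGM = 2^{E[log₂ λ]} via the digamma function; EB05 is the 5th posterior
percentile by Brent root-finding on the mixture CDF (absolute tolerance
1e-8 in λ, bracket [1e-12, max(10·EBGM, 10)], expanded if needed).

## Retention

Default criteria: ROR — a ≥ 3 and CI lower bound > 1; PRR — a ≥ 3,
PRR ≥ 2, χ² ≥ 4; BCPNN — IC025 > 0; MGPS — EB05 > 2. A term is retained
when all four hold; "significant in ≥ k of 4" is available because the
all-four reading of a combined-criteria screen is a convention choice,
not a mathematical one. A non-evaluable statistic always yields a false
flag. The same criteria apply at PT and SOC level. Output is ordered by
SOC, then descending case count, then term.

## Subgroups

Subgroup screening restricts the *entire* database — cohort and
background — to one stratum (sex or age band), rebuilds the tables and
reruns the screen, so each stratum's expected counts come from its own
background. Strata below a configurable cohort floor (default 10
reports) are excluded with an explicit notice rather than screened,
because disproportionality on a handful of reports is noise; the missing
stratum is treated like any other, so the strata partition the database
and their a-cells add exactly to the overall screen's.

## Time to onset

TTO is the calendar-day difference from the target drug's therapy start
(THER.START_DT) to the event date (DEMO.EVENT_DT), with the start date
as day 0 (2020-01-01 → 2020-02-14 is 44 days). Both dates must be full
valid YYYYMMDD: blank dates exclude the record as missing, 4/6-digit or
calendar-invalid dates as partial, and an event before the start under
its own status — one status per report, nothing silently dropped. When a
report has several target-drug start dates, the earliest valid one is
used (first initiation), one interval per report. Quantiles use the
linear-interpolation (type-7) convention, stated because median/IQR
values depend on it. The default day bins are [0,30], [31,60], [61,90],
[91,180], [181,365], [366,∞): closed intervals expressing "within the
first month" through "beyond one year", configurable.

## Synthetic databases

The generator emulates the FAERS structure with one seeded RNG, so a
seed fixes the file set byte-for-byte. Drug and event marginals are
Zipf(s = 1.5 by default) over configurable vocabularies — spontaneous
reporting databases are heavy-tailed. A report names the target drug as
primary suspect with probability 0.1; events per report follow a
truncated geometric with mean 2.5. Implanted signals multiply the
sampling *odds* of chosen events by a relative risk ρ within target
reports (optionally only within one age stratum), which keeps the event
distribution proper for any ρ and reduces to the null at ρ = 1. Onset
days are log-normal with median 44 and σ_log = 1.17 (so the quartiles
sit near 20 and 97 days); event-date corruption (5% partial, 30%
missing by default) is applied after the truth is recorded. Five percent
of cases are emitted twice — half with a later FDA date, half tying on
the date so both dedup rules are exercised — and the intended survivor
set is part of the ground truth. Demographic and outcome rates default
to the vicinity of published colorectal-cancer pharmacovigilance
cohorts (57% male, mean age 62, 42% death outcome, 25% age missing).

What the generator does *not* model: drug co-prescription correlation,
reporter/country effects on event profiles, PT co-occurrence structure
within a report, secular reporting trends. Passing recovery and
calibration tests on this generator therefore show the statistical
machinery is correct under heavy-tailed, duplicate-ridden,
partially-dated data — not that real-database confounding (e.g.
indication bias) is handled; disproportionality never measures risk.

A separate hand-written 12-case fixture exercises every edge case —
both dedup tie rules, a secondary-suspect-only target report, an
unmapped PT, a partial date, an event before start, a multi-outcome
report — with hand-enumerated expected outputs (survivors, contingency
tables, TTO statuses) frozen as golden files, plus a byte-compared
golden output bundle.

## Problem sizes in the validation studies

The null-calibration study screens 100 databases of 5,000 reports with
no implanted signals and checks that the four-way conjunction retains at
most 1% of screened terms; the recovery study uses 100 databases of
12,000 reports with three events implanted at ρ = 10, chosen at
vocabulary ranks (25, 35, 45) so their case counts land above 30, and
checks retention in ≥ 95% of seeds with the median ROR within ±20% of ρ.
At these counts the ROR estimates the implanted odds multiplier with a
small downward attenuation from within-report event-set collapse and
weight renormalization (measured medians ≈ 9.4–10.3).

## Determinism and outputs

Analysis stages contain no randomness; the only seeds are the
generator's and the MGPS jitter starts, both fixed in configuration.
Output bundles (CSVs + JSON manifest) are byte-stable: identical config
and inputs produce identical bytes, which the tests enforce. Wall-clock
information is logged to stderr and never written into the bundle; the
manifest echoes analysis parameters but not filesystem paths. The
manifest's count algebra (reports read − duplicates removed =
deduplicated; cohort + background = deduplicated; every cohort report
classified in the TTO audit) is asserted in the tests.

## Known limitations

- No probabilistic record linkage beyond the CASEID rule; true
  duplicates filed under different CASEIDs survive.
- No covariate-adjusted or regression-based disproportionality and no
  stratified MGPS; subgrouping is by cohort restriction only.
- PT→SOC is a flat two-column mapping; no higher MedDRA hierarchy.
- Indication percentages depend on a denominator convention (entry
  total); other publications sometimes use report counts, so compare
  with care.
- The BCPNN closed form's small-count bias discussed above.
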