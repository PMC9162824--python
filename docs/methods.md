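# Methods

## Problem and data model

Spontaneous reporting systems (SRS) such as FAERS collect voluntary
adverse-event reports.  Each report (a *case*) may be submitted repeatedly
as amended versions, names drugs as free text with a role code (primary
suspect PS, secondary suspect SS, concomitant C, interacting I), codes
reactions as MedDRA preferred terms (PTs), and links indications and
therapy episodes to specific drugs.  The package models one extract as six
typed tables (DEMO, DRUG, REAC, INDI, THER, OUTC) in the FDA quarterly
"$"-delimited ASCII dialect: no quoting, empty string for missing values,
dates as `YYYY`/`YYYYMM`/`YYYYMMDD` digit strings kept as *partial dates*
(year, optional month, optional day) rather than being coerced or dropped.

Pipeline stages:

1. **Deduplication** — for each case identifier keep the record with the
   highest version, breaking ties by latest receipt date, then largest
   primary id (the SRS convention that the latest version supersedes).
   Children of dropped versions are dropped.  Cross-case probabilistic
   duplicate detection (the same patient reported under two case ids) is
   out of scope.
2. **Vocabulary normalization** — verbatim drug names are upper-cased,
   whitespace-collapsed and iteratively stripped of dose/formulation/salt
   suffixes before a synonym lookup; indication text is bucketed into nine
   prophylaxis categories by case-insensitive substring match with a
   generic-"prophylaxis" fallback to *Prophylaxis (NEC)*; PTs map to their
   system organ class (SOC).  All lookups are total (unknown → `other` /
   `Unmapped`).  The shipped maps are deliberately small fixtures; licensed
   RxNorm/SNOMED-CT/MedDRA content replaces them via two-column CSVs.
3. **Cohort selection** — a case enters the cohort when the target drug
   appears with role PS or SS *and* that same drug entry links to a
   prophylaxis-category indication.  The counting unit everywhere is the
   distinct case: repeated PT mentions within a case never inflate counts,
   and a case with several prophylaxis indications belongs to each
   indication stratum independently (strata are not disjoint).
4. **Screening** — per (indication stratum, PT) pair, the 2×2 table uses
   the stratum as the exposed row and *every other deduplicated case in
   the database* as the comparator, the standard SRS convention.
5. **Descriptives** — onset binning, SOC distribution, demographics,
   outcome-by-indication counts, indication shares.

## The four algorithms and their conventions

All four statistics are deterministic functions of (a, b, c, d); see the
README for the formulas.  Conventions that were genuinely open and are
fixed here:

- **χ²** is the four-cell Pearson statistic Σ(O−E)²/E over the whole
  table, without Yates correction.  (A one-cell version would not match
  standard PRR practice.)
- **IC dispersion**: the BCPNN literature derives the IC interval from a
  Dirichlet posterior; the screening criterion used here is the simpler
  `IC − 2sd > 0` form, and we take sd from the delta method on the log₂
  relative report rate: sd = √(1/a+1/b+1/c+1/d)/ln 2.  This keeps the
  bound well-defined for IC ≤ 0 (a log-scale interval exponentiated around
  IC is not, since IC can be negative).
- **EBGM** here is the *unshrunk* relative report rate aN/((a+b)(a+c)) —
  the observed/expected ratio — so EBGM = 2^IC identically.  EBGM05 is the
  one-sided 95% lower bound exp(ln EBGM − 1.645·se) with the same se.  Full
  gamma-Poisson (MGPS) hyperparameter estimation is intentionally out of
  scope: with its shrinkage the EBGM05 ≥ 2 criterion would behave
  differently, and the unshrunk form is the declared convention of this
  package, not a reproduction of any specific MGPS fit.
- **Zero cells** leave the affected statistics undefined (never an
  exception; the row carries `undefined_reason` and flags false).  An
  optional Haldane–Anscombe correction (+0.5 to every cell) can be enabled
  explicitly; it is off by default.
- **Ranking**: signal rows sort by case count n descending with
  alphabetical PT tie-break.  Screening is per-indication by default (the
  natural match to indication-stratified reporting); `--pooled` collapses
  the strata first.
- z-values are the conventional 1.96 / 1.645, not Φ⁻¹ at full precision.

Useful algebraic facts (enforced as tests): when ad = bc, ROR = PRR =
EBGM = 1 and IC = 0 exactly; when ad ≥ bc, ROR ≥ PRR ≥ EBGM with equality
iff ad = bc; ROR is strictly monotone in each cell.

No multiple-comparison correction is applied across pairs: the screen is a
hypothesis-generating triage, and its false-positive behaviour is instead
characterized empirically (null CI coverage and the PRR-criterion
false-positive rate are part of the acceptance checks).

## Descriptive conventions

- A month is 365.25/12 = 30.4375 days; ages normalize to years with
  1 month = 1/12 yr, 1 day = 1/365.25 yr, never negative.
- Time to onset = event date − earliest complete therapy start date of the
  target drug, falling back to an explicit therapy duration when dates are
  incomplete; negative onsets become unknown with a warning.  Onset bins
  are half-open: [0,1), [1,3), [3,6), [6,9), [9,12), [12,24), [24,60),
  [60,∞) months; unknown onsets are excluded from bins but reported as an
  Unknown row.  The overall mean onset is case-weighted across indication
  strata: Σ(meanᵢ·nᵢ)/Σnᵢ.
- Age bands are closed-open: [0,18), [18,45), [45,65), [65,75), [75,∞).
- Region is a pure function of country via a ~50-country fixture; unmapped
  countries → Unknown.  Region percents print to 2 decimals, other
  demographic percents to 1 (matching common reporting practice in this
  literature).
- A case counts once per SOC it touches and once per outcome code it
  carries, so SOC counts and outcome row sums may exceed the case total;
  percent denominators are always total distinct cases.

## The synthetic generator

`default_paper_config()` encodes a published aspirin-prophylaxis FAERS
cohort (858 deduplicated cases, 2004Q1–2021Q2) as generation parameters,
taken from `pvsignal.datasets`:

- demographic marginals (sex 45.9/46.7/7.3%, region 64.34% Europe, 21.91%
  Americas, reporter and reporting-year distributions, age bands) —
  sampled i.i.d. per report;
- indication mix (48% Prophylaxis (NEC), 38% thrombosis prophylaxis, 5/4/4%
  for the cardiovascular/cerebrovascular/ischemic categories, the residual
  1% split over the four rare categories);
- per-indication onset models: lognormal with the published mean days
  (471.0 … 1637.6) and a common σ = ln 2 — chosen because the published
  pooled standard deviation (1498.9) far exceeds the pooled mean (871.1),
  indicating strong right skew; therapy start dates are only emitted for
  ≈48.4% of reports (the published share with known duration);
- per-indication outcome distributions from the published
  indication-by-outcome counts;
- injected signals: the 20 published top-10 pairs with true relative risk
  λ set to each row's relative report rate (EBGM), the natural λ analogue.

Mechanism: each report is a cohort report with probability
`cohort_fraction` (default 0.40 — large enough that both 2×2 margins have
usable counts at the default 20 000-report size).  Events occur
independently per report: probability `p_k` (background) outside the
cohort, `min(1, λ·p_k)` for an injected pair's stratum; a report with no
event draws one from the background distribution so every report has ≥ 1
reaction.  The default vocabulary's background probabilities sum to ≈ 1.3
(gastrointestinal PTs at 0.02 each, mirroring GI dominance), so the
per-report reaction count is approximately truncated-Poisson(1.3).
Duplicates are exact payload copies with version 2, a new primary id and a
receipt date 30 days later — exactly what the dedup stage must collapse.
Ground truth (per-case duplicate flag, cohort membership, indication, the
primary id that should survive dedup, and every injected λ) is exported
beside the tables.

What the generator does **not** emulate, and hence what green tests do not
show about real FAERS data: reporting-trend dynamics over time, correlated
events within a report (events are conditionally independent), free-text
misspellings beyond the fixture synonym list, cross-case duplicates with
distinct case ids, and the real corpus's scale (≈3.4 M reports).  Injected
relative risks are recovered as *empirical* RRs whose sampling error at
the default sizes is roughly ±15%; the acceptance band [4, 6] for λ = 5
reflects that.

## Problem sizes

Tests and the acceptance script run at deliberately modest sizes — 500 and
1 000-report databases for stage contracts, 20 000 reports for signal
recovery, 100 000 for marginal-fidelity checks, 300–1 000 replicates for
coverage/false-positive/ordering properties — sizes at which the checked
quantities are already stable to well within their tolerances.

## Known limitations

- The headline counts of the published screen (4 237 retrieved pairs, 108
  positive pairs, 858 cases) require the full FAERS corpus plus licensed
  MedDRA and cannot be recomputed here; what is reproduced is the in-table
  arithmetic and the criteria logic on the published statistics.
- Published IC−2sd and EBGM05 values cannot be re-derived from the printed
  case counts alone (b, c, d are unpublished); this package's bounds are
  its own declared conventions and are validated against their definitions,
  not against those printed values.
- The pre-2012 LAERS dialect and XML exports are not parsed; embedded "$"
  in free text is not representable in the quarterly dialect.
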