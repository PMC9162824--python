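# pvsignal

Disproportionality signal screening for spontaneous adverse-event report
databases, built around the aspirin-prophylaxis use case: given FAERS-style
quarterly extracts, find adverse events reported disproportionately often
for a drug of interest relative to the rest of the database.

It is aimed at pharmacovigilance analysts and methods researchers who want
the whole screening chain — ETL, deduplication, vocabulary normalization,
cohort construction, 2×2 screening, descriptive tabulation — as a tested,
scriptable library rather than a one-off SQL pipeline, plus a synthetic
FAERS generator with *known ground truth* so each stage can be validated
offline.

## The statistics

For each (indication stratum, MedDRA preferred term) pair the screen forms
the 2×2 table over distinct deduplicated cases

|            | event | no event |
|------------|-------|----------|
| cohort     | a     | b        |
| all others | c     | d        |

with N = a+b+c+d, and computes four disproportionality measures:

- **ROR** = ad/bc, 95% CI = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))
- **PRR** = a(c+d)/(c(a+b)), with the four-cell Pearson χ² of the table and
  95% CI = exp(ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d)))
- **IC** (BCPNN information component) = log₂[aN/((a+b)(a+c))], with lower
  bound IC − 2·sd, sd = √(1/a+1/b+1/c+1/d)/ln 2 (delta method)
- **EBGM** (relative report rate) = aN/((a+b)(a+c)), with one-sided 95%
  lower bound EBGM05 = exp(ln EBGM − 1.645·√(1/a+1/b+1/c+1/d))

A pair is a **positive signal** when *any* of the four criteria holds:

| algorithm | criterion |
|-----------|-----------|
| ROR       | ROR ≥ 1 and CI lower bound ≥ 1 |
| PRR       | PRR ≥ 2, χ² ≥ 4 and a ≥ 3 |
| BCPNN     | IC − 2sd > 0 |
| MGPS      | EBGM05 ≥ 2 |

No shrinkage or multiplicity correction is applied (see
`docs/methods.md` for why, and for the exact conventions behind the IC and
EBGM bounds).

## Worked example

Simulate a 20 000-report database with the published aspirin-prophylaxis
cohort's demographics and injected signals, then run every stage:

```bash
pvsignal run --seed 7 --n-reports 20000 --out-dir demo_out
```

prints the run manifest:

```
cases_after_dedup=20000
cohort_cases=8029
indication_strata=9
pair_instances=14259
pairs_screened=692
reports_in=22015
signals_retained=50
versions_dropped=2015
```

Reading it: 22 015 raw report versions collapse to 20 000 unique cases
(2 015 duplicate versions dropped, matching the generator's 10% duplicate
rate); 8 029 cases carry aspirin as a suspect drug with a prophylaxis
indication; their reactions form 692 distinct (indication, preferred term)
pairs, of which 50 meet at least one of the four criteria.  The ranked
signal table lands in `demo_out/signals.csv`, for example:

```
reaction                  indication         n    ROR_fmt
Urinary tract discomfort  Prophylaxis (NEC)  407  13.81 (11.36, 16.79)
Gastritis erosive         Prophylaxis (NEC)  266  2.85 (2.43, 3.34)
Mucosal erosion           Thrombosis proph.  253  3.25 (2.77, 3.81)
```

— exactly the pairs the generator injected (their configured relative risks
are the published EBGM values, e.g. 12.91 for urinary tract discomfort).
Descriptive tables (`soc.csv`, `demographics.csv`, `outcomes.csv`,
`onset.csv`, `indications.csv`) land alongside.

The same stages are available individually (`pvsignal simulate`, `clean`,
`screen`, `describe`) and as library calls:

```python
from pvsignal import (default_paper_config, generate_database,
                      deduplicate, select_cohort, screen_all_pairs)

db, truth = generate_database(default_paper_config(seed=7))
clean = deduplicate(db)
cohort = select_cohort(clean, "aspirin")
signals = screen_all_pairs(cohort, clean)   # pandas DataFrame
```

Licensed vocabularies (RxNorm, SNOMED-CT, MedDRA) plug in as two-column
CSV files via `VocabularyMap.from_csv` or the corresponding CLI flags; the
shipped fixture maps cover the aspirin cohort's terms.

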