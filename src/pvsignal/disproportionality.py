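"""Disproportionality screening of drug-event pairs on 2x2 tables.

For each (indication stratum, preferred term) pair the screen forms the
standard spontaneous-reporting 2x2 table over distinct deduplicated cases

    =============  ==========  =============
                   event       no event
    =============  ==========  =============
    cohort         a           b
    all others     c           d
    =============  ==========  =============

and computes four frequentist/Bayesian-style disproportionality statistics:

* ROR  = ad/bc, with a Woolf 95% CI on the log scale;
* PRR  = a(c+d) / (c(a+b)), with its log-scale 95% CI and the four-cell
  Pearson chi-square of the table;
* IC   = log2( a*N / ((a+b)(a+c)) ), the information component, with the
  lower bound ic - 2*sd obtained by the delta method on the log2 relative
  report rate;
* EBGM = a*N / ((a+b)(a+c)), the (unshrunk) relative report rate, with a
  one-sided 95% lower bound EBGM05 = exp(ln EBGM - 1.645*se).

A pair is a positive signal when ANY of the four published criteria holds:
ROR >= 1 with CI lower bound >= 1; PRR >= 2 with chi2 >= 4 and a >= 3;
IC - 2sd > 0; EBGM05 >= 2.

Note the deliberate conventions: IC's dispersion and EBGM05 use the common
delta-method standard error sqrt(1/a + 1/b + 1/c + 1/d); no gamma-Poisson
shrinkage is applied (EBGM here is the raw observed/expected ratio, so
EBGM = 2**IC identically).  Zero cells leave the affected statistics
undefined unless the Haldane-Anscombe 0.5 correction is requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .case_selection import Cohort
from .cleaning import CleanDatabase

Z_95_TWO_SIDED = 1.96
Z_95_ONE_SIDED = 1.645
LN2 = math.log(2.0)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 case counts for one (indication stratum, event) combination."""

    a: float  # cohort cases with the event
    b: float  # cohort cases without the event
    c: float  # comparator cases with the event
    d: float  # comparator cases without the event

    def __post_init__(self):
        for cell, v in zip("abcd", (self.a, self.b, self.c, self.d)):
            if v < 0:
                raise ValueError(f"cell {cell} is negative: {v}")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def expected_a(self) -> float:
        """Expected a-cell count under independence: (a+b)(a+c)/N."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    @property
    def observed_a(self) -> float:
        return self.a

    def haldane(self) -> "ContingencyTable":
        """The table with the Haldane-Anscombe 0.5 continuity correction."""
        return ContingencyTable(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)


@dataclass(frozen=True)
class SignalCriteria:
    """Signal thresholds for the four algorithms (published defaults)."""

    ror_min: float = 1.0
    ror_ci_min: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    a_min: int = 3
    ic_low_min: float = 0.0  # strict: flag requires ic_low > ic_low_min
    ebgm05_min: float = 2.0


@dataclass
class SignalStatistics:
    """All four algorithms' estimates, bounds and criteria flags for one pair."""

    ror: Optional[float] = None
    ror_ci_low: Optional[float] = None
    ror_ci_high: Optional[float] = None
    prr: Optional[float] = None
    prr_ci_low: Optional[float] = None
    prr_ci_high: Optional[float] = None
    chi2: Optional[float] = None
    ic: Optional[float] = None
    ic_low: Optional[float] = None
    ebgm: Optional[float] = None
    ebgm05: Optional[float] = None
    flag_ror: bool = False
    flag_prr: bool = False
    flag_bcpnn: bool = False
    flag_mgps: bool = False
    signal: bool = False
    undefined_reason: Optional[str] = None
    a: Optional[int] = None


def _log_se(t: ContingencyTable) -> float:
    return math.sqrt(1.0 / t.a + 1.0 / t.b + 1.0 / t.c + 1.0 / t.d)


def compute_ror(t: ContingencyTable) -> Tuple[Optional[float], Optional[float], Optional[float]]:
    """Reporting odds ratio ad/bc with Woolf 95% CI; None triple on a zero cell."""
    if min(t.a, t.b, t.c, t.d) <= 0:
        return (None, None, None)
    ror = (t.a * t.d) / (t.b * t.c)
    se = _log_se(t)
    return (
        ror,
        math.exp(math.log(ror) - Z_95_TWO_SIDED * se),
        math.exp(math.log(ror) + Z_95_TWO_SIDED * se),
    )


def compute_prr_chi2(
    t: ContingencyTable,
) -> Tuple[Optional[float], Optional[float], Optional[float], Optional[float]]:
    """PRR with its log-scale 95% CI, and the four-cell Pearson chi-square.

    chi2 = sum over all four cells of (O-E)^2/E with E the independence
    expectation; no Yates correction.
    """
    if t.c <= 0 or (t.a + t.b) <= 0 or t.a <= 0:
        return (None, None, None, None)
    prr = (t.a * (t.c + t.d)) / (t.c * (t.a + t.b))
    se = math.sqrt(
        1.0 / t.a - 1.0 / (t.a + t.b) + 1.0 / t.c - 1.0 / (t.c + t.d)
    )
    lo = math.exp(math.log(prr) - Z_95_TWO_SIDED * se)
    hi = math.exp(math.log(prr) + Z_95_TWO_SIDED * se)

    n = t.n
    row1, row2 = t.a + t.b, t.c + t.d
    col1, col2 = t.a + t.c, t.b + t.d
    chi2 = 0.0
    for obs, e in (
        (t.a, row1 * col1 / n),
        (t.b, row1 * col2 / n),
        (t.c, row2 * col1 / n),
        (t.d, row2 * col2 / n),
    ):
        if e > 0:
            chi2 += (obs - e) ** 2 / e
    return (prr, lo, hi, chi2)


def compute_ic(t: ContingencyTable) -> Tuple[Optional[float], Optional[float]]:
    """Information component log2(aN/((a+c)(a+b))) and its ic - 2sd bound.

    sd is the delta-method standard deviation of the log2 relative report
    rate, sqrt(1/a+1/b+1/c+1/d)/ln 2.
    """
    if t.a <= 0 or (t.a + t.b) <= 0 or (t.a + t.c) <= 0:
        return (None, None)
    ic = math.log2(t.a * t.n / ((t.a + t.c) * (t.a + t.b)))
    if min(t.b, t.c, t.d) <= 0:
        return (ic, None)
    sd = _log_se(t) / LN2
    return (ic, ic - 2.0 * sd)


def compute_ebgm(t: ContingencyTable) -> Tuple[Optional[float], Optional[float]]:
    """Relative report rate aN/((a+b)(a+c)) and its one-sided 95% lower bound."""
    if t.a <= 0 or (t.a + t.b) <= 0 or (t.a + t.c) <= 0:
        return (None, None)
    ebgm = t.a * t.n / ((t.a + t.b) * (t.a + t.c))
    if min(t.b, t.c, t.d) <= 0:
        return (ebgm, None)
    ebgm05 = math.exp(math.log(ebgm) - Z_95_ONE_SIDED * _log_se(t))
    return (ebgm, ebgm05)


def compute_statistics(
    t: ContingencyTable, use_haldane: bool = False
) -> SignalStatistics:
    """All four algorithms on one table; zero cells -> undefined statistics."""
    work = t.haldane() if use_haldane and min(t.a, t.b, t.c, t.d) == 0 else t
    s = SignalStatistics(a=int(round(t.a)))
    if min(work.a, work.b, work.c, work.d) <= 0:
        s.undefined_reason = "zero cell"
        # still report whatever point estimates survive a zero cell
        s.ic, s.ic_low = compute_ic(work)
        s.ebgm, s.ebgm05 = compute_ebgm(work)
        s.prr, s.prr_ci_low, s.prr_ci_high, s.chi2 = compute_prr_chi2(work)
        return s
    s.ror, s.ror_ci_low, s.ror_ci_high = compute_ror(work)
    s.prr, s.prr_ci_low, s.prr_ci_high, s.chi2 = compute_prr_chi2(work)
    s.ic, s.ic_low = compute_ic(work)
    s.ebgm, s.ebgm05 = compute_ebgm(work)
    return s


def evaluate_criteria(
    s: SignalStatistics,
    t: Optional[ContingencyTable] = None,
    crit: SignalCriteria = SignalCriteria(),
) -> SignalStatistics:
    """Apply the any-of-four positive-signal rule; undefined statistics never flag."""
    a = t.a if t is not None else (s.a if s.a is not None else 0)
    s.flag_ror = (
        s.ror is not None
        and s.ror_ci_low is not None
        and s.ror >= crit.ror_min
        and s.ror_ci_low >= crit.ror_ci_min
    )
    s.flag_prr = (
        s.prr is not None
        and s.chi2 is not None
        and s.prr >= crit.prr_min
        and s.chi2 >= crit.chi2_min
        and a >= crit.a_min
    )
    s.flag_bcpnn = s.ic_low is not None and s.ic_low > crit.ic_low_min
    s.flag_mgps = s.ebgm05 is not None and s.ebgm05 >= crit.ebgm05_min
    s.signal = s.flag_ror or s.flag_prr or s.flag_bcpnn or s.flag_mgps
    return s


def build_contingency(
    pair: Tuple[str, str], cohort: Cohort, db: CleanDatabase
) -> ContingencyTable:
    """2x2 table for one (indication, preferred term) pair.

    Cohort = the target-drug cases in that indication stratum; comparator =
    every other deduplicated case in the database.  All counts are distinct
    cases.  Raises ValueError for a pair with no cohort case (pairs must
    come from :func:`pvsignal.case_selection.enumerate_pairs`).
    """
    indication, pt = pair
    stratum = cohort.stratum_cases(indication)
    if not stratum:
        raise ValueError(f"no cohort cases for indication {indication!r}")
    event_cases = db.cases_with_event(pt)
    a = len(stratum & event_cases)
    if a == 0:
        raise ValueError(f"pair ({indication!r}, {pt!r}) has no cohort case with the event")
    b = len(stratum) - a
    c = len(event_cases - stratum)
    d = db.n_cases - len(stratum) - c
    return ContingencyTable(a, b, c, d)


def format_estimate(value: float, low: float, high: float) -> str:
    """Publication-style "X.XX (lo, hi)" with 2-decimal rounding."""
    return f"{value:.2f} ({low:.2f}, {high:.2f})"


def screen_all_pairs(
    cohort: Cohort,
    db: CleanDatabase,
    crit: SignalCriteria = SignalCriteria(),
    use_haldane: bool = False,
    top: Optional[int] = None,
    signals_only: bool = True,
    pooled: bool = False,
) -> pd.DataFrame:
    """Screen every (indication, preferred term) pair and rank the signals.

    Returns one row per pair, sorted by case count ``n`` descending with
    alphabetical preferred-term tie-break.  With ``signals_only`` (default)
    only positive signals are retained; ``top`` keeps the first k rows.
    With ``pooled`` the indication strata are merged into a single
    "All prophylaxis" stratum before screening.
    """
    from .case_selection import enumerate_pairs  # cycle-free: function level

    work_cohort = cohort.pooled() if pooled else cohort
    rows: List[Dict] = []
    for indication, pt, a in enumerate_pairs(work_cohort):
        table = build_contingency((indication, pt), work_cohort, db)
        stats = evaluate_criteria(compute_statistics(table, use_haldane), table, crit)
        rows.append(_signal_row(indication, pt, table, stats))
    frame = pd.DataFrame(
        rows,
        columns=[
            "reaction", "indication", "n", "ROR", "ROR_CI", "PRR", "PRR_CI",
            "chi2", "IC", "IC_2SD_low", "EBGM", "EBGM05",
            "ROR_fmt", "PRR_fmt", "BCPNN_fmt", "EBGM_fmt",
            "flag_ror", "flag_prr", "flag_bcpnn", "flag_mgps", "signal",
        ],
    )
    if len(frame):
        frame = frame.sort_values(
            ["n", "reaction"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    if signals_only:
        frame = frame[frame["signal"]].reset_index(drop=True)
    if top is not None:
        frame = frame.groupby("indication", sort=False, group_keys=False).head(top)
        frame = frame.reset_index(drop=True)
    return frame


def _signal_row(indication: str, pt: str, t: ContingencyTable, s: SignalStatistics) -> Dict:
    def fmt3(v, lo, hi):
        if v is None or lo is None or hi is None:
            return ""
        return format_estimate(v, lo, hi)

    return {
        "reaction": pt,
        "indication": indication,
        "n": int(t.a),
        "ROR": s.ror,
        "ROR_CI": (s.ror_ci_low, s.ror_ci_high),
        "PRR": s.prr,
        "PRR_CI": (s.prr_ci_low, s.prr_ci_high),
        "chi2": s.chi2,
        "IC": s.ic,
        "IC_2SD_low": s.ic_low,
        "EBGM": s.ebgm,
        "EBGM05": s.ebgm05,
        # publication-style formatted columns
        "ROR_fmt": fmt3(s.ror, s.ror_ci_low, s.ror_ci_high),
        "PRR_fmt": (
            f"{s.prr:.2f} ({s.prr_ci_low:.2f}, {s.prr_ci_high:.2f}, {s.chi2:.2f})"
            if None not in (s.prr, s.prr_ci_low, s.prr_ci_high, s.chi2)
            else ""
        ),
        "BCPNN_fmt": (
            f"{s.ic:.2f} ({s.ic_low:.2f})" if None not in (s.ic, s.ic_low) else ""
        ),
        "EBGM_fmt": (
            f"{s.ebgm:.2f} ({s.ebgm05:.2f})" if None not in (s.ebgm, s.ebgm05) else ""
        ),
        "flag_ror": s.flag_ror,
        "flag_prr": s.flag_prr,
        "flag_bcpnn": s.flag_bcpnn,
        "flag_mgps": s.flag_mgps,
        "signal": s.signal,
    }
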