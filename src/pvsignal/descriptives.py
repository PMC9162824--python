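"""Descriptive tabulations of an analysis cohort.

Time-to-onset binning and per-indication summaries, the system-organ-class
distribution, demographic / report-metadata tables, outcome-by-indication
counts and indication shares.  Conventions throughout: a month is
365.25/12 = 30.4375 days; percent denominators are total distinct cases of
the table's population; a case may count under several SOCs and several
outcome codes (one count per distinct code), which is why SOC and outcome
columns may sum past the case total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .case_selection import Cohort
from .records import DAYS_PER_MONTH, Database, ReportCase

logger = logging.getLogger(__name__)

#: half-open onset bins in months: [0,1), [1,3), ... [60, inf)
ONSET_BIN_EDGES_MONTHS = (0.0, 1.0, 3.0, 6.0, 9.0, 12.0, 24.0, 60.0, float("inf"))
ONSET_BIN_LABELS = (
    "0~1 month", "1~3 months", "3~6 months", "6~9 months",
    "9~12 months", "12~24 months", "24~60 months", "60~ months",
)

AGE_BAND_EDGES = (0.0, 18.0, 45.0, 65.0, 75.0, float("inf"))
AGE_BAND_LABELS = ("0 to 18", "18 to 45", "45 to 65", "65 to 75", "75 to")

#: outcome column order used in the outcome table
OUTCOME_ORDER = ("HO", "OT", "DE", "LT", "DS", "RI")


def compute_onset_days(
    case: ReportCase, therapies: Sequence, target_drug_seqs: Sequence[int]
) -> Optional[float]:
    """Days from the target drug's earliest therapy start to the event.

    Uses event_date minus the earliest complete start_date among the target
    drug's therapy episodes; when dates are incomplete it falls back to the
    earliest explicit duration, normalized to days.  A negative difference
    is treated as unknown (logged), never clamped.
    """
    seqs = set(target_drug_seqs)
    starts = [
        t.start_date.to_date()
        for t in therapies
        if t.drug_seq in seqs and t.start_date.is_complete
    ]
    event = case.event_date.to_date()
    if starts and event is not None:
        onset = (event - min(starts)).days
        if onset < 0:
            logger.warning(
                "case %d: event precedes therapy start (%d days); onset unknown",
                case.primary_id, onset,
            )
            return None
        return float(onset)
    durations = [
        t.duration_days()
        for t in therapies
        if t.drug_seq in seqs and t.duration_days() is not None
    ]
    if durations:
        return float(min(durations))
    return None


def bin_onset(days: float) -> str:
    """Onset bin label for a nonnegative onset in days."""
    if days < 0:
        raise ValueError(f"onset days must be >= 0, got {days}")
    months = days / DAYS_PER_MONTH
    for label, lo, hi in zip(
        ONSET_BIN_LABELS, ONSET_BIN_EDGES_MONTHS[:-1], ONSET_BIN_EDGES_MONTHS[1:]
    ):
        if lo <= months < hi:
            return label
    raise AssertionError("unreachable: bins partition [0, inf)")


@dataclass
class OnsetBinning:
    """Per-indication onset bin counts and summary moments."""

    bin_counts: pd.DataFrame  # index: indication, columns: bin labels
    summaries: pd.DataFrame  # index: indication, columns: n, mean_days, std_days
    overall_mean_days: float  # case-weighted over indications
    n_unknown: int = 0


def onset_summary(
    onsets_by_indication: Dict[str, Sequence[float]], n_unknown: int = 0
) -> OnsetBinning:
    """Bin counts, per-indication mean/std of onset days, and the
    case-weighted overall mean.

    Only known onsets enter; the unknown count is carried through for the
    demographic table's "Unknown" row.
    """
    bin_rows, summary_rows = {}, {}
    for indication, onsets in onsets_by_indication.items():
        arr = np.asarray(list(onsets), dtype=float)
        counts = dict.fromkeys(ONSET_BIN_LABELS, 0)
        for d in arr:
            counts[bin_onset(d)] += 1
        bin_rows[indication] = counts
        summary_rows[indication] = {
            "n": int(arr.size),
            "mean_days": float(arr.mean()) if arr.size else float("nan"),
            "std_days": float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
        }
    bins = pd.DataFrame.from_dict(bin_rows, orient="index", columns=ONSET_BIN_LABELS)
    bins["Total"] = bins.sum(axis=1)
    summaries = pd.DataFrame.from_dict(summary_rows, orient="index")
    total_n = int(summaries["n"].sum()) if len(summaries) else 0
    overall = (
        float((summaries["mean_days"] * summaries["n"]).sum() / total_n)
        if total_n
        else float("nan")
    )
    return OnsetBinning(
        bin_counts=bins, summaries=summaries, overall_mean_days=overall,
        n_unknown=n_unknown,
    )


def cohort_onsets(cohort: Cohort) -> Tuple[Dict[str, List[float]], int]:
    """Collect per-indication known onsets for a cohort; returns also the
    count of cohort cases with unknown onset."""
    db = cohort.db.db
    case_by_pid = {c.primary_id: c for c in db.cases}
    ther_by_pid: Dict[int, list] = {}
    for t in db.therapies:
        ther_by_pid.setdefault(t.primary_id, []).append(t)
    target_seqs: Dict[int, List[int]] = {}
    for d in db.drugs:
        if d.canonical_name == cohort.target_drug:
            target_seqs.setdefault(d.primary_id, []).append(d.drug_seq)

    out: Dict[str, List[float]] = {}
    unknown = 0
    for indication, pids in sorted(cohort.strata.items()):
        onsets: List[float] = []
        for pid in sorted(pids):
            days = compute_onset_days(
                case_by_pid[pid], ther_by_pid.get(pid, ()), target_seqs.get(pid, ())
            )
            if days is None:
                unknown += 1
            else:
                onsets.append(days)
        out[indication] = onsets
    return out, unknown


def soc_tabulate(cohort: Cohort) -> pd.DataFrame:
    """Distinct-case counts per system organ class.

    A case with reactions in several SOCs increments each of them, so the
    count column may sum above the case total; percents use total distinct
    cohort cases and are rounded to 1 decimal.  Sorted by count descending
    (alphabetical tie-break).
    """
    cases = cohort.case_ids
    total = len(cases)
    soc_cases: Dict[str, set] = {}
    for r in cohort.db.db.reactions:
        if r.primary_id in cases and r.soc is not None:
            soc_cases.setdefault(r.soc, set()).add(r.primary_id)
    rows = [
        {"soc": soc, "cases": len(pids), "percent": round(100.0 * len(pids) / total, 1)}
        for soc, pids in soc_cases.items()
    ]
    frame = pd.DataFrame(rows, columns=["soc", "cases", "percent"])
    if len(frame):
        frame = frame.sort_values(
            ["cases", "soc"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    return frame


def demographic_tabulate(cohort: Cohort) -> pd.DataFrame:
    """Counts and percents by region, reporter, year, sex, age band and
    therapy-duration band; missing values appear as Unknown rows.

    Region percents print to 2 decimals, the rest to 1.
    """
    db = cohort.db.db
    cases = [c for c in db.cases if c.primary_id in cohort.case_ids]
    total = len(cases)
    rows: List[dict] = []

    def block(name: str, values: Dict[str, int], decimals: int) -> None:
        for label, count in values.items():
            rows.append(
                {
                    "characteristic": name,
                    "level": label,
                    "count": count,
                    "percent": round(100.0 * count / total, decimals) if total else 0.0,
                }
            )

    region_counts: Dict[str, int] = {}
    reporter_counts: Dict[str, int] = {}
    year_counts: Dict[str, int] = {}
    sex_counts: Dict[str, int] = {}
    age_counts: Dict[str, int] = {}
    for c in cases:
        region_counts[c.region] = region_counts.get(c.region, 0) + 1
        reporter_counts[c.reporter] = reporter_counts.get(c.reporter, 0) + 1
        year = str(c.receipt_date.year) if c.receipt_date.year else "Unknown"
        year_counts[year] = year_counts.get(year, 0) + 1
        sex_label = {"F": "Female", "M": "Male", "UNK": "Unknown"}[c.sex]
        sex_counts[sex_label] = sex_counts.get(sex_label, 0) + 1
        age = c.age_years
        if age is None:
            band = "Unknown"
        else:
            band = AGE_BAND_LABELS[-1]
            for label, lo, hi in zip(AGE_BAND_LABELS, AGE_BAND_EDGES[:-1], AGE_BAND_EDGES[1:]):
                if lo <= age < hi:
                    band = label
                    break
        age_counts[band] = age_counts.get(band, 0) + 1

    onsets, n_unknown = cohort_onsets(cohort)
    duration_counts = dict.fromkeys(ONSET_BIN_LABELS, 0)
    for values in onsets.values():
        for d in values:
            duration_counts[bin_onset(d)] += 1
    duration_counts["Unknown"] = n_unknown

    block("region", dict(sorted(region_counts.items())), 2)
    block("reporter", dict(sorted(reporter_counts.items())), 1)
    block("year", dict(sorted(year_counts.items())), 1)
    block("sex", dict(sorted(sex_counts.items())), 1)
    block("age_band", dict(sorted(age_counts.items())), 1)
    block("therapy_duration", duration_counts, 2)
    return pd.DataFrame(rows, columns=["characteristic", "level", "count", "percent"])


def outcome_tabulate(cohort: Cohort) -> pd.DataFrame:
    """Indication-by-outcome distinct-case counts with a Total row.

    Column order HO, OT, DE, LT, DS, RI; a case with several outcome codes
    counts once per code.  The Total row always equals the column sums.
    """
    db = cohort.db.db
    outcomes_by_pid: Dict[int, set] = {}
    for o in db.outcomes:
        outcomes_by_pid.setdefault(o.primary_id, set()).add(o.outcome_code)
    rows = {}
    for indication, pids in sorted(cohort.strata.items()):
        counts = dict.fromkeys(OUTCOME_ORDER, 0)
        for pid in pids:
            for code in outcomes_by_pid.get(pid, ()):
                if code in counts:
                    counts[code] += 1
        rows[indication] = counts
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(OUTCOME_ORDER))
    frame.loc["Total"] = frame.sum(axis=0)
    return frame


def indication_shares(cohort: Cohort) -> Dict[str, int]:
    """Whole-percent share of cohort cases per indication category."""
    total = sum(len(pids) for pids in cohort.strata.values())
    if total == 0:
        return {}
    return {
        indication: int(round(100.0 * len(pids) / total))
        for indication, pids in sorted(cohort.strata.items())
    }


def describe_cohort(cohort: Cohort) -> Dict[str, pd.DataFrame]:
    """All descriptive tables in one call (keys: onset, soc, demographics,
    outcomes, indications)."""
    onsets, n_unknown = cohort_onsets(cohort)
    binning = onset_summary(onsets, n_unknown)
    onset_frame = binning.bin_counts.join(binning.summaries)
    shares = indication_shares(cohort)
    return {
        "onset": onset_frame,
        "soc": soc_tabulate(cohort),
        "demographics": demographic_tabulate(cohort),
        "outcomes": outcome_tabulate(cohort),
        "indications": pd.DataFrame(
            {"indication": list(shares), "percent": list(shares.values())}
        ),
    }
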