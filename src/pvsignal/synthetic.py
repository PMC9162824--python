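"""Synthetic FAERS-format databases with known ground truth.

The generator emits the six-quarterly-table record set that
:mod:`pvsignal.faers_io` reads and writes, with every downstream contract
controllable: duplicate case versions, demographic marginals, indication
mix, per-indication onset and outcome models, and — centrally — injected
drug-event association strengths.  For a report outside the cohort, each
vocabulary event occurs independently with its background probability
``p_k``; for a cohort report with indication ``i``, an injected pair
``(i, k, lambda)`` scales that to ``min(1, lambda * p_k)``.  The empirical
relative risk of an injected pair therefore converges to lambda, giving the
screening stage a known answer.

Generation is fully deterministic: the same config (including seed)
produces byte-identical table files.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import datasets
from .dates import ABSENT_DATE, PartialDate
from .records import (
    Database,
    DrugEntry,
    IndicationEntry,
    OutcomeEntry,
    ReactionEntry,
    ReportCase,
    TherapyEntry,
)
from .vocab_data import PT_TO_SOC

logger = logging.getLogger(__name__)

_REGION_COUNTRIES = {
    "Europe": ("DE", "FR", "GB", "IT", "ES"),
    "Americas": ("US", "CA", "BR"),
    "Asia": ("JP", "CN", "IN"),
    "Oceania": ("AU", "NZ"),
    "Africa": ("ZA", "EG"),
    "Unknown": ("",),
}
_AGE_BAND_RANGES = {
    "0 to 18": (1.0, 18.0),
    "18 to 45": (18.0, 45.0),
    "45 to 65": (45.0, 65.0),
    "65 to 75": (65.0, 75.0),
    "75 to": (75.0, 95.0),
    "Unknown": None,
}
_ASPIRIN_SPELLINGS = (
    "ASPIRIN", "Acetylsalicylic Acid", "ASPIRIN 81MG", "BAYER ASPIRIN", "ASA",
)
_OTHER_DRUGS = (
    "CLOPIDOGREL", "WARFARIN", "OMEPRAZOLE", "ATORVASTATIN", "METFORMIN",
    "LISINOPRIL", "AMLODIPINE", "IBUPROFEN", "PARACETAMOL", "METOPROLOL",
)
_OTHER_INDICATIONS = ("Hypertension", "Pain", "Diabetes mellitus", "Pyrexia")
_OUTCOME_CODES = datasets.OUTCOME_COLUMNS  # HO, OT, DE, LT, DS, RI


def _check_prob_map(name: str, mapping: Dict) -> None:
    total = float(sum(mapping.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} probabilities sum to {total}, not 1")
    if any(p < 0 for p in mapping.values()):
        raise ValueError(f"{name} contains a negative probability")


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults come from the published cohort tables."""

    n_reports: int = 20000
    duplicate_rate: float = 0.1
    target_drug: str = "aspirin"
    #: fraction of reports belonging to the target-drug prophylaxis cohort
    cohort_fraction: float = 0.40
    indication_mix: Dict[str, float] = field(default_factory=dict)
    #: (preferred_term, soc, background probability per report)
    event_vocabulary: List[Tuple[str, str, float]] = field(default_factory=list)
    #: (indication, preferred_term, true relative risk lambda)
    injected_signals: List[Tuple[str, str, float]] = field(default_factory=list)
    #: marginal name ("sex", "region", "reporter", "age_band", "year") -> dist
    demographic_marginals: Dict[str, Dict] = field(default_factory=dict)
    #: indication -> (mean onset days, lognormal sigma)
    onset_model: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    #: probability that a report's therapy start date is recorded
    p_onset_known: float = 1.0 - 443.0 / 858.0
    #: indication -> probabilities over outcome codes (HO, OT, DE, LT, DS, RI)
    outcome_model: Dict[str, Tuple[float, ...]] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports < 0:
            raise ValueError("n_reports must be >= 0")
        if not (0.0 <= self.duplicate_rate < 1.0):
            raise ValueError("duplicate_rate must be in [0, 1)")
        if not (0.0 < self.cohort_fraction <= 1.0):
            raise ValueError("cohort_fraction must be in (0, 1]")
        _check_prob_map("indication_mix", self.indication_mix)
        for name, dist in self.demographic_marginals.items():
            _check_prob_map(f"demographic_marginals[{name}]", dist)
        for ind, probs in self.outcome_model.items():
            _check_prob_map(f"outcome_model[{ind}]", dict(enumerate(probs)))
        for ind, pt, lam in self.injected_signals:
            if lam <= 0:
                raise ValueError(f"injected signal ({ind}, {pt}) has lambda {lam} <= 0")
        for pt, _soc, p in self.event_vocabulary:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"background probability of {pt!r} out of [0,1]: {p}")


@dataclass
class GroundTruth:
    """What the generator actually did, for oracle comparisons downstream."""

    #: (indication, preferred_term) -> true relative risk lambda
    signal_lambda: Dict[Tuple[str, str], float]
    #: case_id -> True when the case was emitted with more than one version
    is_duplicate: Dict[int, bool]
    #: case_id -> True when the case is a target-drug prophylaxis cohort case
    in_cohort: Dict[int, bool]
    #: case_id -> indication category (cohort cases only)
    indication: Dict[int, str]
    #: case_id -> primary_id of the latest (to-be-retained) version
    retained_primary_id: Dict[int, int]

    @property
    def n_unique_cases(self) -> int:
        return len(self.is_duplicate)

    @property
    def cohort_case_ids(self) -> Set[int]:
        return {cid for cid, v in self.in_cohort.items() if v}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "caseid": sorted(self.is_duplicate),
                "is_duplicate": [self.is_duplicate[c] for c in sorted(self.is_duplicate)],
                "in_cohort": [self.in_cohort[c] for c in sorted(self.is_duplicate)],
                "indication": [self.indication.get(c, "") for c in sorted(self.is_duplicate)],
                "retained_primaryid": [
                    self.retained_primary_id[c] for c in sorted(self.is_duplicate)
                ],
            }
        )

    def write_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


def default_paper_config(seed: int = 0, n_reports: int = 20000) -> SyntheticConfig:
    """A config whose marginals match the published cohort's summary tables.

    Sex, region, reporter, age-band and reporting-year distributions are the
    published demographic proportions (renormalized); the indication mix is
    the published prophylaxis shares; per-indication onset means are the
    published averages with a common lognormal sigma of ln 2 (the published
    pooled std dev exceeding the mean indicates strong right skew); outcome
    distributions are the published indication-by-outcome rows; injected
    signals are the published top-10 pairs with lambda set to each row's
    relative report rate (EBGM).
    """

    def norm(counts: Dict) -> Dict:
        total = float(sum(counts.values()))
        out = {k: v / total for k, v in counts.items()}
        # push rounding slack onto the largest entry so the map sums to 1
        top = max(out, key=lambda k: out[k])
        out[top] += 1.0 - sum(out.values())
        return out

    indication_mix = norm(datasets.INDICATION_SHARES_PCT)
    onset_model = {
        ind: (mean, math.log(2.0)) for ind, mean in datasets.ONSET_MEAN_DAYS.items()
    }
    # rare indications without a published onset row: use the pooled mean
    for ind in indication_mix:
        onset_model.setdefault(ind, (datasets.ONSET_OVERALL_MEAN_DAYS, math.log(2.0)))

    outcome_model = {}
    for ind, counts in datasets.OUTCOME_COUNTS.items():
        total = float(sum(counts))
        outcome_model[ind] = tuple(c / total for c in counts)

    # background probabilities: gastrointestinal terms dominate, mirroring
    # the published SOC distribution; the summed background of ~1.3 sets the
    # mean number of reactions per report.
    vocabulary: List[Tuple[str, str, float]] = []
    gi_terms = [pt for pt, soc in PT_TO_SOC.items() if soc == "Gastrointestinal disorders"]
    other_terms = [pt for pt, soc in PT_TO_SOC.items() if soc != "Gastrointestinal disorders"]
    for pt in gi_terms:
        vocabulary.append((pt, PT_TO_SOC[pt], 0.02))
    p_other = (1.3 - 0.02 * len(gi_terms)) / len(other_terms)
    for pt in other_terms:
        vocabulary.append((pt, PT_TO_SOC[pt], round(p_other, 6)))

    injected = [
        (row[1], row[0], row[12])  # indication, reaction, published EBGM
        for row in datasets.TOP10_SIGNAL_ROWS
    ]

    return SyntheticConfig(
        n_reports=n_reports,
        duplicate_rate=0.1,
        target_drug="aspirin",
        cohort_fraction=0.40,
        indication_mix=indication_mix,
        event_vocabulary=vocabulary,
        injected_signals=injected,
        demographic_marginals={
            "sex": norm(datasets.SEX_COUNTS),
            "region": norm(datasets.REGION_COUNTS),
            "reporter": norm(datasets.REPORTER_COUNTS),
            "age_band": norm(datasets.AGE_BAND_COUNTS),
            "year": norm(datasets.YEAR_COUNTS),
        },
        onset_model=onset_model,
        outcome_model=outcome_model,
        seed=seed,
    )


def _sample_categorical(rng: np.random.Generator, dist: Dict, size: int) -> List:
    keys = list(dist.keys())
    probs = np.asarray([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(keys), size=size, p=probs)
    return [keys[i] for i in idx]


def _partial(date: _dt.date) -> PartialDate:
    return PartialDate(date.year, date.month, date.day)


def generate_database(config: SyntheticConfig) -> Tuple[Database, GroundTruth]:
    """Generate one FAERS-format database plus its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    db = Database()
    truth = GroundTruth(
        signal_lambda={(i, pt): lam for i, pt, lam in config.injected_signals},
        is_duplicate={}, in_cohort={}, indication={}, retained_primary_id={},
    )
    if n == 0:
        return db, truth

    mix = config.indication_mix or {"Prophylaxis (NEC)": 1.0}
    marg = config.demographic_marginals
    in_cohort = rng.random(n) < config.cohort_fraction
    indications = _sample_categorical(rng, mix, n)
    sexes = _sample_categorical(rng, marg.get("sex", {"UNK": 1.0}), n)
    regions = _sample_categorical(rng, marg.get("region", {"Unknown": 1.0}), n)
    reporters = _sample_categorical(rng, marg.get("reporter", {"unknown": 1.0}), n)
    age_bands = _sample_categorical(rng, marg.get("age_band", {"Unknown": 1.0}), n)
    years = _sample_categorical(rng, marg.get("year", {2018: 1.0}), n)

    pts = [pt for pt, _soc, _p in config.event_vocabulary]
    background = np.asarray([p for _pt, _soc, p in config.event_vocabulary], dtype=float)
    pt_index = {pt: j for j, pt in enumerate(pts)}
    lam_by_ind: Dict[str, np.ndarray] = {}
    for ind, pt, lam in config.injected_signals:
        if pt not in pt_index:
            logger.warning("injected signal PT %r absent from vocabulary; skipped", pt)
            continue
        lam_by_ind.setdefault(ind, np.ones(len(pts)))[pt_index[pt]] = lam

    # per-report event probabilities, then one vectorized Bernoulli sweep
    if len(pts):
        prob = np.tile(background, (n, 1))
        for ind, lam_vec in lam_by_ind.items():
            rows = np.flatnonzero(in_cohort & (np.asarray(indications) == ind))
            if len(rows):
                scaled = background * lam_vec
                if np.any(scaled > 1.0):
                    logger.warning(
                        "indication %r: %d event probabilities clamped to 1",
                        ind, int(np.sum(scaled > 1.0)),
                    )
                prob[rows] = np.minimum(scaled, 1.0)
        occurred = rng.random((n, len(pts))) < prob
        # guarantee at least one reaction per report
        empty_rows = np.flatnonzero(~occurred.any(axis=1))
        if len(empty_rows):
            fill = rng.choice(len(pts), size=len(empty_rows), p=background / background.sum())
            occurred[empty_rows, fill] = True
    else:
        occurred = np.zeros((n, 0), dtype=bool)

    dup_flags = rng.random(n) < config.duplicate_rate
    onset_known = rng.random(n) < config.p_onset_known
    lags = rng.integers(0, 91, size=n)
    months = rng.integers(1, 13, size=n)
    days = rng.integers(1, 29, size=n)
    role_ps = rng.random(n) < 0.75
    drug_spellings = rng.integers(0, len(_ASPIRIN_SPELLINGS), size=n)
    other_drug_idx = rng.integers(0, len(_OTHER_DRUGS), size=n)
    other_ind_idx = rng.integers(0, len(_OTHER_INDICATIONS), size=n)
    concomitant = rng.random(n) < 0.4
    second_outcome = rng.random(n) < 0.2

    generic_outcome = (0.4, 0.35, 0.1, 0.08, 0.04, 0.03)

    for i in range(n):
        case_id = i + 1
        version = 1
        pid = case_id * 10 + version
        year = int(years[i])
        receipt = _dt.date(year, int(months[i]), int(days[i]))
        event = receipt - _dt.timedelta(days=int(lags[i]))
        cohort = bool(in_cohort[i])
        indication = indications[i] if cohort else _OTHER_INDICATIONS[other_ind_idx[i]]

        age_range = _AGE_BAND_RANGES.get(age_bands[i])
        if age_range is None:
            age_value, age_unit = None, ""
        else:
            age_value = float(int(rng.uniform(*age_range)))
            age_unit = "YR"
        country = _REGION_COUNTRIES[regions[i]][
            int(rng.integers(0, len(_REGION_COUNTRIES[regions[i]])))
        ]

        db.cases.append(
            ReportCase(
                primary_id=pid, case_id=case_id, case_version=version,
                receipt_date=_partial(receipt), event_date=_partial(event),
                age_value=age_value, age_unit=age_unit, sex=sexes[i],
                reporter=reporters[i], country=country,
                region=regions[i] if country else "Unknown",
            )
        )

        if cohort:
            db.drugs.append(
                DrugEntry(pid, 1, _ASPIRIN_SPELLINGS[drug_spellings[i]],
                          "PS" if role_ps[i] else "SS")
            )
            if concomitant[i]:
                db.drugs.append(DrugEntry(pid, 2, _OTHER_DRUGS[other_drug_idx[i]], "C"))
        else:
            db.drugs.append(DrugEntry(pid, 1, _OTHER_DRUGS[other_drug_idx[i]], "PS"))
        db.indications.append(IndicationEntry(pid, 1, indication))

        for j in np.flatnonzero(occurred[i]):
            db.reactions.append(ReactionEntry(pid, pts[j]))

        if onset_known[i]:
            mean, sigma = config.onset_model.get(
                indication, (400.0, math.log(2.0))
            )
            mu = math.log(mean) - sigma**2 / 2.0
            onset = max(1, int(round(rng.lognormal(mu, sigma))))
            start = event - _dt.timedelta(days=onset)
            db.therapies.append(TherapyEntry(pid, 1, _partial(start), _partial(event)))
        else:
            db.therapies.append(TherapyEntry(pid, 1, PartialDate(year=event.year)))

        out_probs = config.outcome_model.get(indication, generic_outcome) if cohort \
            else generic_outcome
        k = int(rng.choice(len(_OUTCOME_CODES), p=np.asarray(out_probs) / sum(out_probs)))
        db.outcomes.append(OutcomeEntry(pid, _OUTCOME_CODES[k]))
        if second_outcome[i]:
            k2 = (k + 1 + int(rng.integers(0, len(_OUTCOME_CODES) - 1))) % len(_OUTCOME_CODES)
            db.outcomes.append(OutcomeEntry(pid, _OUTCOME_CODES[k2]))

        truth.is_duplicate[case_id] = bool(dup_flags[i])
        truth.in_cohort[case_id] = cohort
        if cohort:
            truth.indication[case_id] = indication
        truth.retained_primary_id[case_id] = (
            case_id * 10 + 2 if dup_flags[i] else pid
        )

    _append_duplicates(db, truth, dup_flags)
    return db, truth


def _append_duplicates(db: Database, truth: GroundTruth, dup_flags: np.ndarray) -> None:
    """Emit version-2 copies (identical payload, later receipt) of flagged cases."""
    dup_case_ids = {i + 1 for i in np.flatnonzero(dup_flags)}
    if not dup_case_ids:
        return
    v1_pid = {cid: cid * 10 + 1 for cid in dup_case_ids}
    new_cases = []
    for case in db.cases:
        if case.case_id in dup_case_ids:
            receipt = case.receipt_date.to_date() + _dt.timedelta(days=30)
            new_cases.append(
                ReportCase(
                    primary_id=case.case_id * 10 + 2, case_id=case.case_id,
                    case_version=2, receipt_date=_partial(receipt),
                    event_date=case.event_date, age_value=case.age_value,
                    age_unit=case.age_unit, sex=case.sex, reporter=case.reporter,
                    country=case.country, region=case.region,
                )
            )
    db.cases.extend(new_cases)
    for attr in ("drugs", "reactions", "indications", "therapies", "outcomes"):
        extra = []
        for rec in getattr(db, attr):
            cid = rec.primary_id // 10
            if rec.primary_id == v1_pid.get(cid):
                import copy

                dup = copy.copy(rec)
                dup.primary_id = cid * 10 + 2
                extra.append(dup)
        getattr(db, attr).extend(extra)


def empirical_relative_risk(
    db: Database, truth: GroundTruth, indication: str, preferred_term: str
) -> Optional[float]:
    """Brute-force empirical RR of one pair over distinct unique cases.

    Counts each case once (latest version), compares the event rate in the
    (cohort, indication) stratum against all other cases.
    """
    retained = set(truth.retained_primary_id.values())
    stratum_pids = {
        truth.retained_primary_id[cid]
        for cid, ind in truth.indication.items()
        if ind == indication and truth.in_cohort[cid]
    }
    event_pids = {
        r.primary_id
        for r in db.reactions
        if r.primary_id in retained and r.preferred_term == preferred_term
    }
    n_stratum = len(stratum_pids)
    n_rest = len(retained) - n_stratum
    a = len(stratum_pids & event_pids)
    c = len(event_pids - stratum_pids)
    if n_stratum == 0 or n_rest == 0 or c == 0:
        return None
    return (a / n_stratum) / (c / n_rest)
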