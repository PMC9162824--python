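"""Record factories used by the acceptance script's constructed fixtures."""

from __future__ import annotations

from pvsignal.case_selection import select_cohort
from pvsignal.cleaning import deduplicate
from pvsignal.dates import parse_partial_date
from pvsignal.faers_io import region_for_country
from pvsignal.records import (
    Database,
    DrugEntry,
    IndicationEntry,
    OutcomeEntry,
    ReactionEntry,
    ReportCase,
)


def aspirin_case(
    pid,
    indication="Prophylaxis (NEC)",
    reactions=("Melaena",),
    outcomes=("HO",),
    sex="UNK",
    country="",
):
    db = Database()
    db.cases.append(
        ReportCase(
            primary_id=pid,
            case_id=pid,
            case_version=1,
            receipt_date=parse_partial_date("20180601"),
            event_date=parse_partial_date("20180501"),
            sex=sex,
            country=country,
            region=region_for_country(country),
        )
    )
    db.drugs.append(DrugEntry(pid, 1, "ASPIRIN", "PS"))
    db.indications.append(IndicationEntry(pid, 1, indication))
    for pt in reactions:
        db.reactions.append(ReactionEntry(pid, pt))
    for code in outcomes:
        db.outcomes.append(OutcomeEntry(pid, code))
    return db


def merge(*parts: Database) -> Database:
    out = Database()
    for part in parts:
        out.cases += part.cases
        out.drugs += part.drugs
        out.reactions += part.reactions
        out.indications += part.indications
        out.therapies += part.therapies
        out.outcomes += part.outcomes
    return out


def cohort_of(db: Database, drug="aspirin"):
    clean = deduplicate(db)
    return select_cohort(clean, drug), clean
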