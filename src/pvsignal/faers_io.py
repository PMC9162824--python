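"""Reader/writer for FAERS-style "$"-delimited quarterly ASCII tables.

The dialect is the one the FDA quarterly data extracts use: one header line,
"$" as the field separator, no quoting, empty string for missing values,
dates as YYYY / YYYYMM / YYYYMMDD digit strings.  Six tables make up one
extract: DEMO, DRUG, REAC, INDI, THER, OUTC.

Embedded "$" inside free text is not representable in this dialect; rows
with surplus fields are kept (extra fields dropped) with a logged warning
carrying the line number.
"""

from __future__ import annotations

import logging
import os
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from .dates import PartialDate, parse_partial_date
from .records import (
    Database,
    DrugEntry,
    IndicationEntry,
    OutcomeEntry,
    ReactionEntry,
    ReportCase,
    TherapyEntry,
)
from .vocab_data import COUNTRY_TO_REGION

logger = logging.getLogger(__name__)

TABLE_KINDS = ("DEMO", "DRUG", "REAC", "INDI", "THER", "OUTC")

_COLUMNS = {
    "DEMO": (
        "primaryid", "caseid", "caseversion", "fda_dt", "event_dt",
        "age", "age_cod", "sex", "occp_cod", "reporter_country",
    ),
    "DRUG": ("primaryid", "drug_seq", "drugname", "role_cod"),
    "REAC": ("primaryid", "pt"),
    "INDI": ("primaryid", "indi_drug_seq", "indi_pt"),
    "THER": ("primaryid", "dsg_drug_seq", "start_dt", "end_dt", "dur", "dur_cod"),
    "OUTC": ("primaryid", "outc_cod"),
}

_OCCP_TO_REPORTER = {
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other health professional",
    "HP": "other health professional",
    "CN": "consumer",
    "LW": "consumer",
    "": "unknown",
    "UNK": "unknown",
}
_REPORTER_TO_OCCP = {
    "physician": "MD",
    "pharmacist": "PH",
    "other health professional": "OT",
    "consumer": "CN",
    "unknown": "",
}


class FaersSchemaError(ValueError):
    """The file's header or a row violates the expected table schema."""


def region_for_country(country: str) -> str:
    """Reporting region for an ISO-like country code; unmapped -> Unknown."""
    return COUNTRY_TO_REGION.get(country.strip().upper(), "Unknown")


def _int(text: str) -> Optional[int]:
    text = text.strip()
    return int(text) if text else None

def _float(text: str) -> Optional[float]:
    text = text.strip()
    return float(text) if text else None

def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, PartialDate):
        return value.to_faers()
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


def read_table(path: Union[str, os.PathLike], table_kind: str) -> List:
    """Read one "$"-delimited FAERS table into typed records.

    Unknown columns are ignored; missing values become None / absent dates;
    malformed dates are kept as partial dates (rows are never dropped).

    Raises
    ------
    FaersSchemaError
        if the header lacks the primaryid key column or a required column,
        or if a row carries a code outside the FAERS code lists.
    OSError
        if the file cannot be read.
    """
    if table_kind not in TABLE_KINDS:
        raise ValueError(f"table_kind must be one of {TABLE_KINDS}, got {table_kind!r}")
    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        header = [h.strip().lower() for h in header_line.split("$")]
        if "primaryid" not in header:
            raise FaersSchemaError(f"{path}: header is missing required column 'primaryid'")
        # only the key column is mandatory; absent columns read as missing
        idx = {
            col: (header.index(col) if col in header else None)
            for col in _COLUMNS[table_kind]
        }
        records = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("$")
            if len(fields) > len(header):
                logger.warning(
                    "%s line %d: %d fields for %d columns (embedded '$'?); extras dropped",
                    path, lineno, len(fields), len(header),
                )
                fields = fields[: len(header)]
            elif len(fields) < len(header):
                fields = fields + [""] * (len(header) - len(fields))
            row = {col: (fields[i] if i is not None else "") for col, i in idx.items()}
            try:
                records.append(_ROW_PARSERS[table_kind](row))
            except (ValueError, TypeError) as exc:
                raise FaersSchemaError(f"{path} line {lineno}: {exc}") from exc
    return records


def _parse_demo(row: Dict[str, str]) -> ReportCase:
    country = row["reporter_country"].strip().upper()
    sex = row["sex"].strip().upper() or "UNK"
    if sex not in ("F", "M"):
        sex = "UNK"
    occp = row["occp_cod"].strip().upper()
    reporter = _OCCP_TO_REPORTER.get(occp)
    if reporter is None:
        logger.warning("unknown occupation code %r treated as unknown", occp)
        reporter = "unknown"
    primary_id = int(row["primaryid"])
    return ReportCase(
        primary_id=primary_id,
        case_id=_int(row["caseid"]) or primary_id,
        case_version=_int(row["caseversion"]) or 1,
        receipt_date=parse_partial_date(row["fda_dt"]),
        event_date=parse_partial_date(row["event_dt"]),
        age_value=_float(row["age"]),
        age_unit=row["age_cod"].strip().upper(),
        sex=sex,
        reporter=reporter,
        country=country,
        region=region_for_country(country),
    )

def _parse_drug(row: Dict[str, str]) -> DrugEntry:
    return DrugEntry(
        primary_id=int(row["primaryid"]),
        drug_seq=_int(row["drug_seq"]) or 1,
        verbatim_name=row["drugname"].strip(),
        role_code=row["role_cod"].strip().upper(),
    )

def _parse_reac(row: Dict[str, str]) -> ReactionEntry:
    return ReactionEntry(primary_id=int(row["primaryid"]), preferred_term=row["pt"])

def _parse_indi(row: Dict[str, str]) -> IndicationEntry:
    return IndicationEntry(
        primary_id=int(row["primaryid"]),
        drug_seq=_int(row["indi_drug_seq"]) or 1,
        indication_text=row["indi_pt"].strip(),
    )

def _parse_ther(row: Dict[str, str]) -> TherapyEntry:
    return TherapyEntry(
        primary_id=int(row["primaryid"]),
        drug_seq=_int(row["dsg_drug_seq"]) or 1,
        start_date=parse_partial_date(row["start_dt"]),
        end_date=parse_partial_date(row["end_dt"]),
        duration_value=_float(row["dur"]),
        duration_unit=row["dur_cod"].strip().upper(),
    )

def _parse_outc(row: Dict[str, str]) -> OutcomeEntry:
    return OutcomeEntry(primary_id=int(row["primaryid"]), outcome_code=row["outc_cod"].strip().upper())


_ROW_PARSERS = {
    "DEMO": _parse_demo,
    "DRUG": _parse_drug,
    "REAC": _parse_reac,
    "INDI": _parse_indi,
    "THER": _parse_ther,
    "OUTC": _parse_outc,
}


def _demo_row(c: ReportCase) -> Sequence[str]:
    return (
        str(c.primary_id), str(c.case_id), str(c.case_version),
        c.receipt_date.to_faers(), c.event_date.to_faers(),
        _fmt(c.age_value), c.age_unit, "" if c.sex == "UNK" else c.sex,
        _REPORTER_TO_OCCP.get(c.reporter, ""), c.country,
    )

def _drug_row(d: DrugEntry) -> Sequence[str]:
    return (str(d.primary_id), str(d.drug_seq), d.verbatim_name, d.role_code)

def _reac_row(r: ReactionEntry) -> Sequence[str]:
    return (str(r.primary_id), r.preferred_term)

def _indi_row(i: IndicationEntry) -> Sequence[str]:
    return (str(i.primary_id), str(i.drug_seq), i.indication_text)

def _ther_row(t: TherapyEntry) -> Sequence[str]:
    return (
        str(t.primary_id), str(t.drug_seq), t.start_date.to_faers(),
        t.end_date.to_faers(), _fmt(t.duration_value), t.duration_unit,
    )

def _outc_row(o: OutcomeEntry) -> Sequence[str]:
    return (str(o.primary_id), o.outcome_code)


_ROW_WRITERS = {
    "DEMO": ("cases", _demo_row),
    "DRUG": ("drugs", _drug_row),
    "REAC": ("reactions", _reac_row),
    "INDI": ("indications", _indi_row),
    "THER": ("therapies", _ther_row),
    "OUTC": ("outcomes", _outc_row),
}


def write_tables(database: Database, directory: Union[str, os.PathLike]) -> Dict[str, str]:
    """Write all six tables of *database* under *directory*.

    Output is byte-deterministic given the same database, and round-trips
    through :func:`read_table` record-for-record.  Returns the mapping
    table kind -> file path.
    """
    os.makedirs(directory, exist_ok=True)
    paths: Dict[str, str] = {}
    for kind in TABLE_KINDS:
        attr, row_fn = _ROW_WRITERS[kind]
        path = os.path.join(directory, f"{kind}.txt")
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("$".join(_COLUMNS[kind]) + "\n")
            for rec in getattr(database, attr):
                fields = row_fn(rec)
                for f in fields:
                    if "$" in f:
                        logger.warning("field %r contains '$'; output will not round-trip", f)
                fh.write("$".join(fields) + "\n")
        paths[kind] = path
    return paths


def read_database(directory: Union[str, os.PathLike]) -> Database:
    """Read a full six-table extract written by :func:`write_tables`."""
    return Database(
        cases=read_table(os.path.join(directory, "DEMO.txt"), "DEMO"),
        drugs=read_table(os.path.join(directory, "DRUG.txt"), "DRUG"),
        reactions=read_table(os.path.join(directory, "REAC.txt"), "REAC"),
        indications=read_table(os.path.join(directory, "INDI.txt"), "INDI"),
        therapies=read_table(os.path.join(directory, "THER.txt"), "THER"),
        outcomes=read_table(os.path.join(directory, "OUTC.txt"), "OUTC"),
    )


def database_to_frames(database: Database) -> Dict[str, pd.DataFrame]:
    """The six tables as pandas DataFrames (CSV-exportable view)."""
    return {
        "DEMO": pd.DataFrame(
            [
                {
                    "primaryid": c.primary_id, "caseid": c.case_id,
                    "caseversion": c.case_version,
                    "fda_dt": c.receipt_date.to_faers(),
                    "event_dt": c.event_date.to_faers(),
                    "age": c.age_value, "age_cod": c.age_unit, "sex": c.sex,
                    "reporter": c.reporter, "country": c.country, "region": c.region,
                }
                for c in database.cases
            ]
        ),
        "DRUG": pd.DataFrame(
            [
                {
                    "primaryid": d.primary_id, "drug_seq": d.drug_seq,
                    "drugname": d.verbatim_name, "role_cod": d.role_code,
                    "canonical": d.canonical_name,
                }
                for d in database.drugs
            ]
        ),
        "REAC": pd.DataFrame(
            [
                {"primaryid": r.primary_id, "pt": r.preferred_term, "soc": r.soc}
                for r in database.reactions
            ]
        ),
        "INDI": pd.DataFrame(
            [
                {
                    "primaryid": i.primary_id, "drug_seq": i.drug_seq,
                    "indi_pt": i.indication_text, "category": i.category,
                }
                for i in database.indications
            ]
        ),
        "THER": pd.DataFrame(
            [
                {
                    "primaryid": t.primary_id, "drug_seq": t.drug_seq,
                    "start_dt": t.start_date.to_faers(), "end_dt": t.end_date.to_faers(),
                    "dur": t.duration_value, "dur_cod": t.duration_unit,
                }
                for t in database.therapies
            ]
        ),
        "OUTC": pd.DataFrame(
            [{"primaryid": o.primary_id, "outc_cod": o.outcome_code} for o in database.outcomes]
        ),
    }
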