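"""Case deduplication and vocabulary normalization.

Spontaneous-report extracts carry multiple versions of the same case and
free-text drug / indication spellings.  This module (1) keeps only the
latest version of every case, (2) maps verbatim drug names to canonical
ingredients, (3) buckets indication text into the prophylaxis categories,
and (4) maps each MedDRA preferred term to its system organ class.

The shipped vocabularies are small fixtures (see :mod:`pvsignal.vocab_data`);
each map can be overridden with a user-supplied two-column CSV, which is how
licensed RxNorm / SNOMED-CT / MedDRA content plugs in.  All lookups are
total: unknown keys fall through to ``"other"`` / ``"Unmapped"`` rather than
raising.
"""

from __future__ import annotations

import copy
import logging
import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, NamedTuple, Optional, Set

import pandas as pd

from .records import Database
from .vocab_data import (
    DRUG_SYNONYMS,
    OTHER_INDICATION,
    PROPHYLAXIS_CATEGORIES,
    PT_TO_SOC,
    UNMAPPED_SOC,
)

logger = logging.getLogger(__name__)

# dose / formulation / salt suffixes stripped from verbatim drug names
_SUFFIX_RE = re.compile(
    r"\s*(\d+(\.\d+)?\s*(MG|MCG|G|ML|IU)\b|\bTABLETS?\b|\bCAPSULES?\b|\bEC\b"
    r"|\bENTERIC[- ]COATED\b|\bHYDROCHLORIDE\b|\bSODIUM\b|\bCALCIUM\b"
    r"|\bBESYLATE\b|\bTARTRATE\b|\bSUCCINATE\b|\bORAL\b|\bDELAYED RELEASE\b)\s*$"
)


class NormalizedDrug(NamedTuple):
    name: str
    is_canonical: bool


@dataclass
class VocabularyMap:
    """The three normalization maps; lookups never fail."""

    drug_synonyms: Dict[str, str] = field(default_factory=lambda: dict(DRUG_SYNONYMS))
    indication_map: Dict[str, str] = field(default_factory=dict)
    pt_to_soc: Dict[str, str] = field(default_factory=lambda: dict(PT_TO_SOC))

    def __post_init__(self) -> None:
        self._pt_lower = {k.lower(): (k, v) for k, v in self.pt_to_soc.items()}
        self._indi_lower = {k.lower(): v for k, v in self.indication_map.items()}

    @classmethod
    def default(cls) -> "VocabularyMap":
        return cls()

    @classmethod
    def from_csv(
        cls,
        drug_csv: Optional[str] = None,
        indication_csv: Optional[str] = None,
        soc_csv: Optional[str] = None,
    ) -> "VocabularyMap":
        """Defaults with any of the three maps replaced by a two-column CSV."""
        vocab = cls()
        if drug_csv:
            vocab.drug_synonyms = _read_two_column(drug_csv, upper_keys=True)
        if indication_csv:
            vocab.indication_map = _read_two_column(indication_csv)
        if soc_csv:
            vocab.pt_to_soc = _read_two_column(soc_csv)
        vocab.__post_init__()
        return vocab


def _read_two_column(path: str, upper_keys: bool = False) -> Dict[str, str]:
    frame = pd.read_csv(path, header=0)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected a two-column CSV (key,value)")
    keys = frame.iloc[:, 0].astype(str)
    if upper_keys:
        keys = keys.str.upper()
    return dict(zip(keys, frame.iloc[:, 1].astype(str)))


def normalize_drug(verbatim_name: str, vocab: VocabularyMap) -> NormalizedDrug:
    """Canonical ingredient for a verbatim drug string.

    Upper-cases, collapses whitespace, then strips dose / formulation / salt
    suffixes until a synonym matches.  Unknown names come back lower-cased
    and flagged non-canonical.
    """
    name = " ".join(verbatim_name.split()).upper()
    while name:
        if name in vocab.drug_synonyms:
            return NormalizedDrug(vocab.drug_synonyms[name], True)
        stripped = _SUFFIX_RE.sub("", name)
        if stripped == name:
            break
        name = stripped.strip()
    return NormalizedDrug(" ".join(verbatim_name.split()).lower(), False)


def normalize_indication(indication_text: str, vocab: VocabularyMap) -> str:
    """Bucket free indication text into a prophylaxis category or "other".

    Matching is case-insensitive substring against the canonical labels
    (most specific first); any remaining text containing "prophylaxis"
    falls back to "Prophylaxis (NEC)"; everything else is "other".
    """
    text = " ".join(indication_text.split()).lower()
    if not text:
        return OTHER_INDICATION
    if text in vocab._indi_lower:
        return vocab._indi_lower[text]
    specific = [c for c in PROPHYLAXIS_CATEGORIES if c != "Prophylaxis (NEC)"]
    for category in sorted(specific, key=len, reverse=True):
        if category.lower() in text:
            return category
    if "prophylaxis" in text:
        return "Prophylaxis (NEC)"
    return OTHER_INDICATION


def map_soc(preferred_term: str, vocab: VocabularyMap) -> str:
    """System organ class for a preferred term; unmapped terms are logged."""
    hit = vocab._pt_lower.get(" ".join(preferred_term.split()).lower())
    if hit is None:
        logger.debug("preferred term %r has no SOC mapping", preferred_term)
        return UNMAPPED_SOC
    return hit[1]


def canonical_pt(preferred_term: str, vocab: VocabularyMap) -> str:
    """Case-normalize a PT against the vocabulary (unknown PTs unchanged)."""
    hit = vocab._pt_lower.get(" ".join(preferred_term.split()).lower())
    return hit[0] if hit is not None else " ".join(preferred_term.split())


@dataclass
class CleanDatabase:
    """A deduplicated, vocabulary-annotated database.

    Exactly one report per case_id; every drug carries ``canonical_name``,
    every reaction ``soc``, every indication ``category``.
    """

    db: Database
    vocab: VocabularyMap
    n_input: int
    n_dropped: int

    def __post_init__(self) -> None:
        self._event_index: Dict[str, Set[int]] = {}
        for r in self.db.reactions:
            self._event_index.setdefault(r.preferred_term.lower(), set()).add(r.primary_id)

    @property
    def n_cases(self) -> int:
        return len(self.db.cases)

    @property
    def case_ids(self) -> Set[int]:
        return {c.primary_id for c in self.db.cases}

    def cases_with_event(self, preferred_term: str) -> FrozenSet[int]:
        """Distinct primary_ids reporting the PT (case-insensitive)."""
        return frozenset(self._event_index.get(preferred_term.lower(), set()))


def deduplicate(db: Database, vocab: Optional[VocabularyMap] = None) -> CleanDatabase:
    """Keep the latest version of every case and annotate vocabularies.

    Version precedence per case_id: highest case_version, then latest
    receipt date, then largest primary_id.  Children of dropped versions
    are dropped with their parent.
    """
    vocab = vocab or VocabularyMap.default()
    best: Dict[int, tuple] = {}
    for case in db.cases:
        key = (case.case_version, case.receipt_date.sort_key(), case.primary_id)
        prev = best.get(case.case_id)
        if prev is None or key > prev[0]:
            best[case.case_id] = (key, case)
    kept_cases = [case for _, case in best.values()]
    kept_cases.sort(key=lambda c: c.primary_id)
    kept_ids = {c.primary_id for c in kept_cases}

    # child records are copied so the input database is never mutated
    clean = Database(
        cases=kept_cases,
        drugs=[copy.copy(d) for d in db.drugs if d.primary_id in kept_ids],
        reactions=[copy.copy(r) for r in db.reactions if r.primary_id in kept_ids],
        indications=[copy.copy(i) for i in db.indications if i.primary_id in kept_ids],
        therapies=[t for t in db.therapies if t.primary_id in kept_ids],
        outcomes=[o for o in db.outcomes if o.primary_id in kept_ids],
    )
    for d in clean.drugs:
        d.canonical_name = normalize_drug(d.verbatim_name, vocab).name
    for r in clean.reactions:
        r.preferred_term = canonical_pt(r.preferred_term, vocab)
        r.soc = map_soc(r.preferred_term, vocab)
    for i in clean.indications:
        i.category = normalize_indication(i.indication_text, vocab)

    n_input = len(db.cases)
    result = CleanDatabase(
        db=clean, vocab=vocab, n_input=n_input, n_dropped=n_input - len(kept_cases)
    )
    logger.info(
        "deduplicate: %d reports in, %d cases retained, %d versions dropped",
        n_input, result.n_cases, result.n_dropped,
    )
    return result
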