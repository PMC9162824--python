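"""Cohort construction and case-event pair enumeration.

The analysis cohort is every deduplicated case in which the target drug
appears with a suspect role (PS or SS) and that drug carries a prophylaxis
category indication.  A case with several prophylaxis indications belongs to
each indication stratum independently; within one stratum every statistic
counts distinct cases, so repeated mentions of a preferred term inside one
report never inflate counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Set, Tuple

from .cleaning import CleanDatabase
from .vocab_data import PROPHYLAXIS_CATEGORIES

logger = logging.getLogger(__name__)

DEFAULT_ROLES = frozenset({"PS", "SS"})
POOLED_STRATUM = "All prophylaxis"


@dataclass
class Cohort:
    """Target-drug prophylaxis cases, stratified by indication category."""

    target_drug: str
    db: CleanDatabase
    #: indication category -> distinct case primary_ids
    strata: Dict[str, Set[int]] = field(default_factory=dict)

    @property
    def case_ids(self) -> Set[int]:
        """All cohort cases regardless of stratum."""
        out: Set[int] = set()
        for cases in self.strata.values():
            out |= cases
        return out

    @property
    def size(self) -> int:
        return len(self.case_ids)

    def stratum_cases(self, indication: str) -> Set[int]:
        return self.strata.get(indication, set())

    def pooled(self) -> "Cohort":
        """The same cohort collapsed into a single stratum."""
        return Cohort(
            target_drug=self.target_drug,
            db=self.db,
            strata={POOLED_STRATUM: set(self.case_ids)},
        )

    def pair_triples(self) -> List[Tuple[int, str, str]]:
        """Distinct (case, indication, preferred term) triples."""
        triples: Set[Tuple[int, str, str]] = set()
        by_case: Dict[int, Set[str]] = {}
        for r in self.db.db.reactions:
            by_case.setdefault(r.primary_id, set()).add(r.preferred_term)
        for indication, cases in self.strata.items():
            for pid in cases:
                for pt in by_case.get(pid, ()):
                    triples.add((pid, indication, pt))
        return sorted(triples)


def select_cohort(
    db: CleanDatabase,
    target_drug: str,
    roles: Iterable[str] = DEFAULT_ROLES,
    indication_categories: Iterable[str] = PROPHYLAXIS_CATEGORIES,
) -> Cohort:
    """Build the (drug, suspect-role, prophylaxis-indication) cohort.

    Membership requires a drug entry whose canonical name equals
    *target_drug* with role in *roles*, linked (same drug_seq) to an
    indication in one of the qualifying categories.  An absent target drug
    yields an empty cohort with a logged warning, not an error.
    """
    roles = frozenset(roles)
    categories = frozenset(indication_categories)
    qualifying: Dict[int, Set[int]] = {}  # primary_id -> qualifying drug_seqs
    drug_present = False
    for d in db.db.drugs:
        if d.canonical_name == target_drug:
            drug_present = True
            if d.role_code in roles:
                qualifying.setdefault(d.primary_id, set()).add(d.drug_seq)
    if not drug_present:
        logger.warning("target drug %r not found in database; cohort is empty", target_drug)
        return Cohort(target_drug=target_drug, db=db, strata={})

    strata: Dict[str, Set[int]] = {}
    for ind in db.db.indications:
        if ind.category in categories and ind.drug_seq in qualifying.get(ind.primary_id, ()):
            strata.setdefault(ind.category, set()).add(ind.primary_id)
    cohort = Cohort(target_drug=target_drug, db=db, strata=strata)
    logger.info(
        "cohort for %r: %d cases across %d indication strata",
        target_drug, cohort.size, len(strata),
    )
    return cohort


def enumerate_pairs(cohort: Cohort) -> List[Tuple[str, str, int]]:
    """Distinct (indication, preferred term) pairs with distinct-case counts.

    ``a`` is the number of distinct cohort cases in that indication stratum
    reporting the preferred term; every emitted pair has a >= 1.
    Sorted by (indication, preferred term) for determinism.
    """
    counts: Dict[Tuple[str, str], Set[int]] = {}
    for pid, indication, pt in cohort.pair_triples():
        counts.setdefault((indication, pt), set()).add(pid)
    return [
        (indication, pt, len(cases))
        for (indication, pt), cases in sorted(counts.items())
    ]
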