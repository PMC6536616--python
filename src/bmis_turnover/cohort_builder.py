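"""Turn filtered submission records into unique-investigator histories.

An investigator is a unique (last name, first name) key; repeat submissions
under the same key form one ordered history.  Each history carries the
derived variables the downstream classification needs:

* ``newid`` — dense integer id, assigned in order of first appearance
* ``firsub`` — earliest receipt date (the date an investigator is plotted at)
* ``secdiff`` — days from first to second submission; absent for single-
  submission investigators
* ``oad`` — flag for exactly one submission ("one-and-done" candidate)

Names in registry dumps often differ only in case or stray whitespace for
the same person, so keys are normalized (trim, collapse whitespace,
casefold) by default; pass ``normalize=False`` for strict raw-string
matching.  People who genuinely share a name collapse into one history —
an accepted limitation of name-keyed deduplication that the synthetic
generator can quantify via its collision-rate knob.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from datetime import date
from enum import Enum
from typing import Sequence

from .bmis_io import SubmissionRecord

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")


class Location(str, Enum):
    US = "US"
    NON_US = "NON_US"


def normalize_name(name: str) -> str:
    """Trim, collapse internal whitespace runs, casefold."""
    return _WS.sub(" ", name.strip()).casefold()


@dataclass(frozen=True)
class InvestigatorHistory:
    """One unique investigator: ordered submissions plus derived variables."""

    newid: int
    last_name: str
    first_name: str
    submissions: tuple[date, ...]
    location: Location

    def __post_init__(self) -> None:
        if not self.submissions:
            raise ValueError("history must contain at least one submission")
        if any(
            a > b for a, b in zip(self.submissions, self.submissions[1:])
        ):
            raise ValueError("submissions must be sorted nondecreasing")

    @property
    def firsub(self) -> date:
        return self.submissions[0]

    @property
    def secdiff(self) -> int | None:
        """Days from first to second submission; None when only one."""
        if len(self.submissions) < 2:
            return None
        return (self.submissions[1] - self.submissions[0]).days

    @property
    def oad(self) -> bool:
        return len(self.submissions) == 1

    @property
    def obs(self) -> tuple[int, ...]:
        """Sequential submission indices 1..n."""
        return tuple(range(1, len(self.submissions) + 1))


def exclude_invalid_names(
    records: Sequence[SubmissionRecord],
) -> tuple[list[SubmissionRecord], int]:
    """Drop records whose last name is empty or the "??" placeholder.

    Returns the kept records (original order) and the excluded count.
    """
    kept = [
        r
        for r in records
        if normalize_name(r.last_name) not in ("", "??")
    ]
    return kept, len(records) - len(kept)


def _key(record: SubmissionRecord, normalize: bool) -> tuple[str, str]:
    if normalize:
        return (normalize_name(record.last_name), normalize_name(record.first_name))
    return (record.last_name, record.first_name)


def assign_investigator_ids(
    records: Sequence[SubmissionRecord], normalize: bool = True
) -> list[int]:
    """Assign a dense integer newid per unique name key.

    Ids start at 1 and follow order of first appearance; the returned list
    aligns with ``records``.
    """
    ids: dict[tuple[str, str], int] = {}
    out = []
    for record in records:
        key = _key(record, normalize)
        out.append(ids.setdefault(key, len(ids) + 1))
    return out


def classify_location(country_name: str | None) -> Location:
    """US iff the trimmed, case-folded country equals "usa"; else non-US.

    Missing/empty country is treated as non-US (the binary split has no
    unknown class); callers log how often this happens.
    """
    if country_name is None:
        return Location.NON_US
    return (
        Location.US
        if normalize_name(country_name) == "usa"
        else Location.NON_US
    )


def build_histories(
    records: Sequence[SubmissionRecord], ids: Sequence[int]
) -> list[InvestigatorHistory]:
    """Group records by newid into date-ordered histories.

    Same-day submissions keep original file order (stable sort), so a
    same-day second submission yields ``secdiff == 0``.  Location comes from
    the first (earliest) submission's country; disagreement among later
    submissions is logged.  Submissions beyond the second are retained in
    the sequence but never influence ``secdiff``.
    """
    if len(records) != len(ids):
        raise ValueError("records and ids must align one-to-one")
    by_id: dict[int, list[SubmissionRecord]] = {}
    for record, newid in zip(records, ids):
        by_id.setdefault(newid, []).append(record)

    histories = []
    n_missing_country = 0
    n_country_conflicts = 0
    for newid in sorted(by_id):
        group = sorted(by_id[newid], key=lambda r: r.receipt_date)  # stable
        first = group[0]
        if not first.country_name.strip():
            n_missing_country += 1
        countries = {normalize_name(r.country_name) for r in group}
        if len(countries) > 1:
            n_country_conflicts += 1
        histories.append(
            InvestigatorHistory(
                newid=newid,
                last_name=first.last_name,
                first_name=first.first_name,
                submissions=tuple(r.receipt_date for r in group),
                location=classify_location(first.country_name),
            )
        )
    if n_missing_country:
        logger.info(
            "%d histories with missing country on first submission -> NON_US",
            n_missing_country,
        )
    if n_country_conflicts:
        logger.info(
            "%d histories with conflicting countries; first submission wins",
            n_country_conflicts,
        )
    return histories


def build_cohort(
    records: Sequence[SubmissionRecord], normalize: bool = True
) -> list[InvestigatorHistory]:
    """Convenience: exclude invalid names, assign ids, build histories."""
    kept, _ = exclude_invalid_names(records)
    return build_histories(kept, assign_investigator_ids(kept, normalize=normalize))
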