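"""Reading and writing BMIS-style flat-file dumps.

The FDA's Bioresearch Monitoring Information System (BMIS) download is a
delimited text export of Form FDA 1572 submission records.  The physical
layout of the export is not standardised across vintages, so all layout
knowledge lives in a :class:`DumpDialect`: delimiter, header presence,
accepted date formats, encoding, and a mapping from source columns to the
four fields the analysis needs (last name, first name, country, receipt
date).  Every other source column is carried along verbatim in
``passthrough`` and never touches a computation.

Malformed rows are never silently dropped: :func:`read_bmis` returns a
rejection log naming the row and the reason, and refuses to proceed if more
than half the rows reject (almost always a wrong dialect, not bad data).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Mapping, Sequence, Union

logger = logging.getLogger(__name__)

SEMANTIC_FIELDS = ("last_name", "first_name", "country_name", "receipt_date")


class BmisIOError(RuntimeError):
    """Fatal condition while reading or writing a dump."""


@dataclass(frozen=True)
class SubmissionRecord:
    """One row of a BMIS dump: one Form FDA 1572 submission."""

    last_name: str
    first_name: str
    country_name: str
    receipt_date: date
    passthrough: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class DumpDialect:
    """Physical layout of a BMIS-style dump.

    ``column_map`` maps each semantic field to a source column: a header
    name when ``has_header`` is true, otherwise a zero-based column index.
    """

    delimiter: str = "|"
    date_formats: tuple[str, ...] = ("%Y-%m-%d", "%m/%d/%Y")
    column_map: Mapping[str, Union[str, int]] = field(
        default_factory=lambda: {
            "last_name": "LAST_NAME",
            "first_name": "FIRST_NAME",
            "country_name": "COUNTRY_NAME",
            "receipt_date": "RECEIPT_DATE",
        }
    )
    encoding: str = "utf-8"
    has_header: bool = True

    def __post_init__(self) -> None:
        missing = [f for f in SEMANTIC_FIELDS if f not in self.column_map]
        extra = [f for f in self.column_map if f not in SEMANTIC_FIELDS]
        if missing or extra:
            raise BmisIOError(
                f"column_map must cover exactly {SEMANTIC_FIELDS}; "
                f"missing={missing} unexpected={extra}"
            )
        sources = list(self.column_map.values())
        if len(set(sources)) != len(sources):
            raise BmisIOError("column_map sources must be distinct")


DEFAULT_DIALECT = DumpDialect()


@dataclass(frozen=True)
class Rejection:
    """A malformed dump row: 1-based data-row number plus the reason."""

    row_number: int
    reason: str


def parse_date(text: str, formats: Sequence[str]) -> date | None:
    """Try each format in order; return the first parse or None."""
    text = text.strip()
    for fmt in formats:
        try:
            return datetime.strptime(text, fmt).date()
        except ValueError:
            continue
    return None


def _read_text(path: Path, encoding: str) -> str:
    try:
        return path.read_text(encoding=encoding)
    except UnicodeDecodeError:
        logger.warning("%s: %s decode failed, falling back to latin-1", path, encoding)
        return path.read_text(encoding="latin-1")


def read_bmis(
    path: str | Path, dialect: DumpDialect = DEFAULT_DIALECT
) -> tuple[list[SubmissionRecord], list[Rejection]]:
    """Read a BMIS-style dump into submission records plus a rejection log.

    Row order is preserved.  Raises :class:`BmisIOError` for a missing
    file, for mapped header names absent from the header, and when more
    than 50% of data rows reject (dialect-mismatch heuristic).
    """
    path = Path(path)
    if not path.exists():
        raise BmisIOError(f"input file not found: {path}")
    text = _read_text(path, dialect.encoding)
    rows = list(csv.reader(text.splitlines(), delimiter=dialect.delimiter))

    if dialect.has_header:
        if not rows:
            raise BmisIOError(f"{path}: empty file, expected a header row")
        header = [h.strip() for h in rows[0]]
        missing = [
            str(src) for src in dialect.column_map.values() if src not in header
        ]
        if missing:
            raise BmisIOError(
                f"{path}: header lacks mapped column(s): {sorted(missing)}"
            )
        col_index = {f: header.index(src) for f, src in dialect.column_map.items()}
        n_cols = len(header)
        passthrough_cols = [
            (i, name) for i, name in enumerate(header) if i not in col_index.values()
        ]
        data_rows = rows[1:]
    else:
        col_index = {f: int(src) for f, src in dialect.column_map.items()}
        n_cols = (max(col_index.values()) + 1) if not rows else len(rows[0])
        passthrough_cols = [
            (i, f"COL{i}") for i in range(n_cols) if i not in col_index.values()
        ]
        data_rows = rows

    records: list[SubmissionRecord] = []
    rejections: list[Rejection] = []
    for rownum, row in enumerate(data_rows, start=1):
        if len(row) != n_cols:
            rejections.append(
                Rejection(rownum, f"expected {n_cols} fields, got {len(row)}")
            )
            continue
        raw_date = row[col_index["receipt_date"]]
        parsed = parse_date(raw_date, dialect.date_formats)
        if parsed is None:
            rejections.append(Rejection(rownum, f"unparseable date {raw_date!r}"))
            continue
        records.append(
            SubmissionRecord(
                last_name=row[col_index["last_name"]],
                first_name=row[col_index["first_name"]],
                country_name=row[col_index["country_name"]],
                receipt_date=parsed,
                passthrough={name: row[i] for i, name in passthrough_cols},
            )
        )

    n_data = len(data_rows)
    if n_data and len(rejections) > 0.5 * n_data:
        raise BmisIOError(
            f"{path}: {len(rejections)}/{n_data} rows rejected; "
            "dialect probably does not match the file"
        )
    return records, rejections


def filter_window(
    records: Sequence[SubmissionRecord], start_year: int, end_year: int
) -> list[SubmissionRecord]:
    """Keep records whose receipt year falls in [start_year, end_year]."""
    if start_year > end_year:
        raise BmisIOError(f"invalid window: {start_year} > {end_year}")
    return [r for r in records if start_year <= r.receipt_date.year <= end_year]


COHORT_COLUMNS = (
    "newid",
    "last_name",
    "first_name",
    "location",
    "firsub",
    "secdiff",
    "phenotype",
)


def write_cohort(histories, labels, path: str | Path) -> None:
    """Write a labeled cohort as comma-delimited text, one row per investigator.

    ``secdiff`` is left empty for single-submission investigators.  Rows are
    ordered by ``newid`` so the output is deterministic and re-readable by
    :func:`read_cohort`.
    """
    if len(histories) != len(labels):
        raise BmisIOError("histories and labels must align one-to-one")
    path = Path(path)
    try:
        handle = path.open("w", newline="", encoding="utf-8")
    except OSError as exc:
        raise BmisIOError(f"cannot write cohort to {path}: {exc}") from exc
    with handle:
        writer = csv.writer(handle)
        writer.writerow(COHORT_COLUMNS)
        for hist, label in sorted(zip(histories, labels), key=lambda p: p[0].newid):
            writer.writerow(
                [
                    hist.newid,
                    hist.last_name,
                    hist.first_name,
                    hist.location.value,
                    hist.firsub.isoformat(),
                    "" if hist.secdiff is None else hist.secdiff,
                    label.value,
                ]
            )


def read_cohort(path: str | Path):
    """Read a cohort file written by :func:`write_cohort`.

    Returns ``(histories, labels)``.  A two-submission investigator is
    reconstructed as dates ``[firsub, firsub + secdiff]``, which reproduces
    every derived variable exactly.
    """
    from .cohort_builder import InvestigatorHistory, Location
    from .phenotype import Phenotype

    path = Path(path)
    if not path.exists():
        raise BmisIOError(f"cohort file not found: {path}")
    histories, labels = [], []
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or tuple(reader.fieldnames) != COHORT_COLUMNS:
            raise BmisIOError(
                f"{path}: malformed cohort header {reader.fieldnames!r}"
            )
        for row in reader:
            try:
                firsub = date.fromisoformat(row["firsub"])
                subs = (
                    (firsub,)
                    if row["secdiff"] == ""
                    else (firsub, firsub + timedelta(days=int(row["secdiff"])))
                )
                histories.append(
                    InvestigatorHistory(
                        newid=int(row["newid"]),
                        last_name=row["last_name"],
                        first_name=row["first_name"],
                        submissions=subs,
                        location=Location(row["location"]),
                    )
                )
                labels.append(Phenotype(row["phenotype"]))
            except (KeyError, ValueError) as exc:
                raise BmisIOError(f"{path}: malformed cohort row {row!r}") from exc
    return histories, labels
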