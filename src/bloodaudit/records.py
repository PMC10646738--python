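"""Patient-level transfusion records: data model, validation, CSV I/O, aggregation.

One :class:`TransfusionRecord` is one patient-procedure episode of an elective
surgical admission: how many red-cell units the blood bank crossmatched
(reserved) for the patient, how many were actually transfused, and any wastage
events attached to the issued units.  Records flagged ``excluded`` (massive
transfusion, transfusion reaction) are carried through I/O but dropped from
every aggregate.

Aggregation produces one :class:`ProcedureSummary` per procedure code — the
numerators and denominators every utilization index and the MSBOS calculation
need: patient counts, unit totals, and the histogram of transfused-unit counts
per patient.
"""

from __future__ import annotations

import csv
import io
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

__all__ = [
    "WASTAGE_CATEGORIES",
    "FormatError",
    "ValidationError",
    "TransfusionRecord",
    "ProcedureSummary",
    "normalize_procedure",
    "read_records",
    "records_from_dataframe",
    "write_records",
    "summarize",
]

#: Recognised wastage-event categories: units expired after issue but before
#: transfusion, units lost to improper storage/transport, non-stored units
#: returned late (>30 min after issue), and everything else (breakage,
#: contamination, transport-system failure).
WASTAGE_CATEGORIES = frozenset(
    {"expired_after_issue", "improper_storage", "late_return", "other"}
)

#: Overall pseudo-procedure code used for whole-cohort summaries.
OVERALL_CODE = "ALL"

MANDATORY_COLUMNS = ("patient_id", "procedure", "units_crossmatched", "units_transfused")
OPTIONAL_COLUMNS = ("excluded", "wastage_events")

_TRUE_STRINGS = {"true", "1", "yes", "y", "t"}
_FALSE_STRINGS = {"false", "0", "no", "n", "f", ""}


class FormatError(ValueError):
    """The input table is structurally unusable (e.g. a mandatory column is missing)."""


class ValidationError(ValueError):
    """A field value violates the record contract (negative count, bad category, ...)."""


def normalize_procedure(code: str, aliases: Mapping[str, str] | None = None) -> str:
    """Canonicalise a procedure code: trim, upper-case, then apply the alias map."""
    norm = str(code).strip().upper()
    if aliases:
        norm = {str(k).strip().upper(): str(v).strip().upper() for k, v in aliases.items()}.get(
            norm, norm
        )
    return norm


@dataclass
class TransfusionRecord:
    """One patient-procedure episode.

    Parameters
    ----------
    patient_id : str
        Opaque identifier; repeated ids are allowed and treated as distinct
        episodes.
    procedure : str
        Procedure code (e.g. ``"VSD"``, ``"TOF"``); normalised by upper-casing
        and trimming at aggregation time.
    units_crossmatched, units_transfused : int
        Whole red-cell units reserved / actually given.  Non-negative integers.
    excluded : bool
        True for episodes that must not enter any aggregate (massive
        transfusion, transfusion reaction).
    wastage_events : list of (category, units)
        Zero or more wastage events; ``category`` must be one of
        :data:`WASTAGE_CATEGORIES` and ``units`` a positive integer.
    """

    patient_id: str
    procedure: str
    units_crossmatched: int
    units_transfused: int
    excluded: bool = False
    wastage_events: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("units_crossmatched", "units_transfused"):
            value = getattr(self, name)
            if isinstance(value, bool) or not _is_integral(value):
                raise ValidationError(f"{name} must be an integer, got {value!r}")
            value = int(value)
            if value < 0:
                raise ValidationError(f"{name} must be non-negative, got {value}")
            setattr(self, name, value)
        self.patient_id = str(self.patient_id)
        self.procedure = str(self.procedure)
        self.excluded = bool(self.excluded)
        events: list[tuple[str, int]] = []
        for category, units in self.wastage_events:
            if category not in WASTAGE_CATEGORIES:
                raise ValidationError(
                    f"unknown wastage category {category!r}; "
                    f"expected one of {sorted(WASTAGE_CATEGORIES)}"
                )
            if not _is_integral(units) or int(units) <= 0:
                raise ValidationError(f"wastage units must be a positive integer, got {units!r}")
            events.append((category, int(units)))
        self.wastage_events = events


def _is_integral(value: object) -> bool:
    if isinstance(value, bool):
        return False
    if isinstance(value, int):
        return True
    if isinstance(value, float):
        return value.is_integer()
    return False


@dataclass
class ProcedureSummary:
    """Per-procedure aggregates of included records.

    ``unit_count_histogram`` maps a transfused-unit count *k* to the number of
    patients who received exactly *k* units; it is the input to the raw MSBOS
    (weighted mean) calculation.  ``units_issued`` defaults to
    ``units_crossmatched`` when no issue data exist, so the wastage index is
    computable on minimal input.  ``units_wasted`` is broken down by category.
    """

    procedure: str
    n_patients: int
    n_transfused_patients: int
    units_crossmatched: int
    units_transfused: int
    units_issued: int
    units_wasted: dict[str, int] = field(default_factory=dict)
    unit_count_histogram: dict[int, int] = field(default_factory=dict)

    @property
    def total_units_wasted(self) -> int:
        return sum(self.units_wasted.values())

    def validate(self) -> None:
        if self.n_transfused_patients > self.n_patients:
            raise ValidationError(
                f"{self.procedure}: transfused patients ({self.n_transfused_patients}) "
                f"exceed total patients ({self.n_patients})"
            )
        if sum(self.unit_count_histogram.values()) != self.n_patients:
            raise ValidationError(f"{self.procedure}: histogram does not cover all patients")
        if sum(k * v for k, v in self.unit_count_histogram.items()) != self.units_transfused:
            raise ValidationError(f"{self.procedure}: histogram units disagree with total")


# ---------------------------------------------------------------------------
# tabular I/O


def _encode_wastage(events: Sequence[tuple[str, int]]) -> str:
    return ";".join(f"{cat}:{units}" for cat, units in events)


def _decode_wastage(text: str, row: int) -> list[tuple[str, int]]:
    text = (text or "").strip()
    if not text:
        return []
    events = []
    for chunk in text.split(";"):
        try:
            category, units_s = chunk.split(":")
            events.append((category.strip(), int(units_s)))
        except ValueError as exc:
            raise ValidationError(f"row {row}: malformed wastage event {chunk!r}") from exc
    return events


def _parse_count(value: str, column: str, row: int) -> int:
    try:
        as_float = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"row {row}: {column} is not a number: {value!r}") from None
    if not as_float.is_integer():
        raise ValidationError(f"row {row}: {column} must be an integer unit count, got {value!r}")
    n = int(as_float)
    if n < 0:
        raise ValidationError(f"row {row}: {column} must be non-negative, got {n}")
    return n


def _parse_bool(value: str, row: int) -> bool:
    text = (value or "").strip().lower()
    if text in _TRUE_STRINGS:
        return True
    if text in _FALSE_STRINGS:
        return False
    raise ValidationError(f"row {row}: cannot interpret excluded flag {value!r}")


def read_records(
    source: str | Path | IO[str],
    dialect: Mapping[str, str] | None = None,
) -> list[TransfusionRecord]:
    """Read validated records from a delimited table (CSV with header).

    ``dialect`` remaps canonical column names to the names actually present,
    e.g. ``{"units_crossmatched": "xm_units"}``.  Unknown columns are ignored;
    ``excluded`` defaults to false and wastage columns are optional.  Row
    numbers in error messages count from 1 at the first data row.
    """
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as handle:
            return read_records(handle, dialect)

    colmap = {name: name for name in MANDATORY_COLUMNS + OPTIONAL_COLUMNS}
    if dialect:
        colmap.update({k: v for k, v in dialect.items() if k in colmap})

    reader = csv.DictReader(source)
    header = reader.fieldnames or []
    for canonical in MANDATORY_COLUMNS:
        if colmap[canonical] not in header:
            raise FormatError(f"missing mandatory column {colmap[canonical]!r}")

    records: list[TransfusionRecord] = []
    for row_no, row in enumerate(reader, start=1):
        try:
            record = TransfusionRecord(
                patient_id=(row.get(colmap["patient_id"]) or "").strip(),
                procedure=(row.get(colmap["procedure"]) or "").strip(),
                units_crossmatched=_parse_count(
                    row.get(colmap["units_crossmatched"]), "units_crossmatched", row_no
                ),
                units_transfused=_parse_count(
                    row.get(colmap["units_transfused"]), "units_transfused", row_no
                ),
                excluded=_parse_bool(row.get(colmap["excluded"], ""), row_no)
                if colmap["excluded"] in header
                else False,
                wastage_events=_decode_wastage(row.get(colmap["wastage_events"], ""), row_no)
                if colmap["wastage_events"] in header
                else [],
            )
        except ValidationError as exc:
            if "row " not in str(exc):
                raise ValidationError(f"row {row_no}: {exc}") from exc
            raise
        records.append(record)
    return records


def records_from_dataframe(df, dialect: Mapping[str, str] | None = None) -> list[TransfusionRecord]:
    """Build validated records from a pandas DataFrame (same contract as CSV input)."""
    buffer = io.StringIO()
    df.to_csv(buffer, index=False)
    buffer.seek(0)
    return read_records(buffer, dialect)


def write_records(records: Iterable[TransfusionRecord], sink: str | Path | IO[str]) -> None:
    """Write records as CSV, losslessly re-readable by :func:`read_records`."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w", newline="", encoding="utf-8") as handle:
            write_records(records, handle)
            return
    writer = csv.writer(sink)
    writer.writerow(MANDATORY_COLUMNS + OPTIONAL_COLUMNS)
    for rec in records:
        writer.writerow(
            [
                rec.patient_id,
                rec.procedure,
                rec.units_crossmatched,
                rec.units_transfused,
                str(rec.excluded).lower(),
                _encode_wastage(rec.wastage_events),
            ]
        )


# ---------------------------------------------------------------------------
# aggregation


def summarize(
    records: Iterable[TransfusionRecord],
    by_procedure: bool = True,
    include_overall: bool = False,
    aliases: Mapping[str, str] | None = None,
) -> list[ProcedureSummary]:
    """Aggregate included records into per-procedure summaries.

    Excluded records contribute to nothing.  With ``by_procedure=False`` a
    single whole-cohort summary (procedure code ``"ALL"``) is returned;
    ``include_overall=True`` appends that summary after the per-procedure
    ones.  Per-procedure summaries are sorted by descending patient count,
    ties broken alphabetically.  An empty included set yields an empty list.
    """
    included = [r for r in records if not r.excluded]
    if not included:
        return []

    groups: dict[str, list[TransfusionRecord]] = defaultdict(list)
    for rec in included:
        groups[normalize_procedure(rec.procedure, aliases)].append(rec)

    def build(code: str, recs: list[TransfusionRecord]) -> ProcedureSummary:
        histogram = Counter(r.units_transfused for r in recs)
        wasted: Counter[str] = Counter()
        for r in recs:
            for category, units in r.wastage_events:
                wasted[category] += units
        crossmatched = sum(r.units_crossmatched for r in recs)
        summary = ProcedureSummary(
            procedure=code,
            n_patients=len(recs),
            n_transfused_patients=sum(1 for r in recs if r.units_transfused > 0),
            units_crossmatched=crossmatched,
            units_transfused=sum(r.units_transfused for r in recs),
            units_issued=crossmatched,
            units_wasted=dict(wasted),
            unit_count_histogram=dict(sorted(histogram.items())),
        )
        summary.validate()
        return summary

    if not by_procedure:
        return [build(OVERALL_CODE, included)]

    summaries = [build(code, recs) for code, recs in groups.items()]
    summaries.sort(key=lambda s: (-s.n_patients, s.procedure))
    if include_overall:
        summaries.append(build(OVERALL_CODE, included))
    return summaries
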