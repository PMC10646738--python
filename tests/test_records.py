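"""Record parsing, validation, CSV round trips, and per-procedure aggregation."""

import io
from collections import Counter, defaultdict

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bloodaudit.records import (
    WASTAGE_CATEGORIES,
    FormatError,
    ProcedureSummary,
    TransfusionRecord,
    ValidationError,
    read_records,
    records_from_dataframe,
    summarize,
    write_records,
)

CSV_3ROW = """\
patient_id,procedure,units_crossmatched,units_transfused
p1,VSD,2,1
p2,VSD,2,2
p3,TOF,2,0
"""


def test_read_basic_csv():
    records = read_records(io.StringIO(CSV_3ROW))
    assert len(records) == 3
    assert sum(r.units_crossmatched for r in records) == 6
    assert sum(r.units_transfused for r in records) == 3
    assert all(not r.excluded and r.wastage_events == [] for r in records)


def test_read_with_column_dialect():
    csv_text = "id,op,xm,tx\np1,VSD,2,1\n"
    dialect = {
        "patient_id": "id",
        "procedure": "op",
        "units_crossmatched": "xm",
        "units_transfused": "tx",
    }
    (rec,) = read_records(io.StringIO(csv_text), dialect)
    assert (rec.procedure, rec.units_crossmatched, rec.units_transfused) == ("VSD", 2, 1)


@pytest.mark.parametrize(
    "bad_row, match",
    [
        ("p2,VSD,2,-1", "row 2.*units_transfused"),
        ("p2,VSD,1.5,0", "row 2.*units_crossmatched"),
        ("p2,VSD,x,0", "row 2.*units_crossmatched"),
    ],
)
def test_invalid_unit_counts_report_row_number(bad_row, match):
    text = "patient_id,procedure,units_crossmatched,units_transfused\np1,VSD,2,1\n" + bad_row + "\n"
    with pytest.raises(ValidationError, match=match):
        read_records(io.StringIO(text))


def test_missing_mandatory_column_names_it():
    with pytest.raises(FormatError, match="units_transfused"):
        read_records(io.StringIO("patient_id,procedure,units_crossmatched\np1,VSD,2\n"))


def test_unknown_columns_ignored_and_excluded_parsed():
    text = (
        "patient_id,procedure,units_crossmatched,units_transfused,excluded,ward\n"
        "p1,VSD,2,1,true,ICU\np2,VSD,2,2,false,ICU\n"
    )
    records = read_records(io.StringIO(text))
    assert [r.excluded for r in records] == [True, False]


def test_record_invariants_enforced_at_construction():
    with pytest.raises(ValidationError):
        TransfusionRecord("p", "VSD", -1, 0)
    with pytest.raises(ValidationError):
        TransfusionRecord("p", "VSD", 2, 1, wastage_events=[("melted", 1)])
    with pytest.raises(ValidationError):
        TransfusionRecord("p", "VSD", 2, 1, wastage_events=[("late_return", 0)])


def test_write_empty_list_gives_header_only():
    sink = io.StringIO()
    write_records([], sink)
    lines = sink.getvalue().strip().splitlines()
    assert len(lines) == 1 and lines[0].startswith("patient_id,")


def test_wastage_events_round_trip():
    rec = TransfusionRecord(
        "p1", "VSD", 2, 1,
        wastage_events=[("expired_after_issue", 1), ("late_return", 2)],
    )
    sink = io.StringIO()
    write_records([rec], sink)
    (back,) = read_records(io.StringIO(sink.getvalue()))
    assert back == rec


_records_strategy = st.lists(
    st.builds(
        TransfusionRecord,
        patient_id=st.text(alphabet="abcdefgh0123456789", min_size=1, max_size=8),
        procedure=st.sampled_from(["VSD", "TOF", "ASD", "COA", "PS"]),
        units_crossmatched=st.integers(0, 6),
        units_transfused=st.integers(0, 4),
        excluded=st.booleans(),
        wastage_events=st.lists(
            st.tuples(st.sampled_from(sorted(WASTAGE_CATEGORIES)), st.integers(1, 3)),
            max_size=2,
        ),
    ),
    max_size=30,
)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(_records_strategy)
def test_write_read_round_trip_is_identity(records):
    sink = io.StringIO()
    write_records(records, sink)
    assert read_records(io.StringIO(sink.getvalue())) == records


def test_records_from_dataframe_matches_csv_path():
    df = pd.read_csv(io.StringIO(CSV_3ROW))
    assert records_from_dataframe(df) == read_records(io.StringIO(CSV_3ROW))


# ---------------------------------------------------------------------------
# aggregation


def test_summarize_reference_vsd_cohort(reference_cohort):
    (vsd,) = [s for s in summarize(reference_cohort) if s.procedure == "VSD"]
    assert vsd.n_patients == 64
    assert vsd.n_transfused_patients == 56
    assert vsd.units_crossmatched == 128
    assert vsd.units_transfused == 101
    assert vsd.unit_count_histogram == {0: 8, 1: 12, 2: 43, 3: 1}


def test_summarize_drops_excluded_and_empty_is_empty():
    records = [TransfusionRecord("p1", "VSD", 2, 1, excluded=True)]
    assert summarize(records) == []


def test_summarize_normalizes_and_aliases_procedures():
    records = [
        TransfusionRecord("p1", " vsd ", 2, 1),
        TransfusionRecord("p2", "VSD closure", 2, 2),
    ]
    summaries = summarize(records, aliases={"VSD CLOSURE": "VSD"})
    assert [s.procedure for s in summaries] == ["VSD"]
    assert summaries[0].n_patients == 2


def _naive_summaries(records):
    """Brute-force oracle: plain per-row accumulation."""
    groups = defaultdict(list)
    for r in records:
        if not r.excluded:
            groups[r.procedure.strip().upper()].append(r)
    out = {}
    for code, recs in groups.items():
        xm = sum(r.units_crossmatched for r in recs)
        out[code] = ProcedureSummary(
            procedure=code,
            n_patients=len(recs),
            n_transfused_patients=len([r for r in recs if r.units_transfused]),
            units_crossmatched=xm,
            units_transfused=sum(r.units_transfused for r in recs),
            units_issued=xm,
            units_wasted=dict(sum(
                (Counter(dict([(c, u)])) for r in recs for c, u in r.wastage_events),
                Counter(),
            )),
            unit_count_histogram=dict(sorted(Counter(r.units_transfused for r in recs).items())),
        )
    return out


@settings(max_examples=30, derandomize=True, deadline=None)
@given(_records_strategy)
def test_summarize_matches_naive_accumulation(records):
    summaries = {s.procedure: s for s in summarize(records)}
    assert summaries == _naive_summaries(records)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(_records_strategy)
def test_per_procedure_totals_add_up_to_overall(records):
    per_proc = summarize(records)
    overall = summarize(records, by_procedure=False)
    if not per_proc:
        assert overall == []
        return
    (all_summary,) = overall
    assert all_summary.procedure == "ALL"
    assert sum(s.n_patients for s in per_proc) == all_summary.n_patients
    assert sum(s.units_crossmatched for s in per_proc) == all_summary.units_crossmatched
    assert sum(s.units_transfused for s in per_proc) == all_summary.units_transfused
    for s in per_proc + [all_summary]:
        assert s.n_transfused_patients == sum(
            v for k, v in s.unit_count_histogram.items() if k >= 1
        )
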