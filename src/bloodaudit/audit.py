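"""Audit model and results: fit utilization indices and an MSBOS to a cohort.

:class:`BloodOrderAudit` is the entry point: construct it from records, a
DataFrame, or a CSV file, then call :meth:`~BloodOrderAudit.fit` to obtain an
:class:`AuditResults` carrying per-procedure and overall utilization indices
(with Wilson confidence intervals for the transfusion probability), threshold
flags, and the derived MSBOS table, plus a ``summary()`` text report and CSV/
JSON writers.

Two rendering styles exist.  ``full`` uses the mathematically correct
conventions (undefined CTR shown as ``undef``, T% as a percentage).  ``paper``
mirrors the conventions of classical printed audit tables: an undefined CTR
(units reserved, none transfused) is shown as 0 and T% as a fraction of 1.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .indices import Thresholds, UtilizationIndices, compute_indices
from .msbos import MSBOSEntry, build_msbos_table
from .records import (
    OVERALL_CODE,
    ProcedureSummary,
    TransfusionRecord,
    ValidationError,
    read_records,
    records_from_dataframe,
    summarize,
)

__all__ = ["BloodOrderAudit", "AuditResults", "render_table", "round_half_up"]


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up for display (1.565 → 1.57), unlike banker's rounding."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


class BloodOrderAudit:
    """Blood-ordering audit of one cohort of patient-procedure episodes.

    Parameters
    ----------
    records : sequence of TransfusionRecord
        The cohort; excluded episodes are dropped at fit time.
    aliases : mapping, optional
        Procedure-code alias map folding synonyms after normalisation.

    Examples
    --------
    >>> from bloodaudit.synthetic import reference_records
    >>> results = BloodOrderAudit(reference_records()).fit()
    >>> round(results.overall.ti, 2)
    1.31
    """

    def __init__(
        self,
        records: Sequence[TransfusionRecord],
        aliases: Mapping[str, str] | None = None,
    ) -> None:
        self.records = list(records)
        self.aliases = dict(aliases) if aliases else None
        self.n_excluded = sum(1 for r in self.records if r.excluded)

    @classmethod
    def from_csv(
        cls,
        path,
        dialect: Mapping[str, str] | None = None,
        aliases: Mapping[str, str] | None = None,
    ) -> "BloodOrderAudit":
        return cls(read_records(path, dialect), aliases)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        dialect: Mapping[str, str] | None = None,
        aliases: Mapping[str, str] | None = None,
    ) -> "BloodOrderAudit":
        return cls(records_from_dataframe(df, dialect), aliases)

    def fit(
        self,
        thresholds: Thresholds | None = None,
        multiplier: float = 1.0,
        overrides: Mapping[str, int] | None = None,
        strict_ctr: bool = False,
    ) -> "AuditResults":
        """Aggregate, compute indices and flags, and derive the MSBOS table."""
        thresholds = thresholds or Thresholds()
        summaries = summarize(self.records, by_procedure=True, aliases=self.aliases)
        if not summaries:
            raise ValidationError("no included records")
        overall = summarize(self.records, by_procedure=False, aliases=self.aliases)[0]
        return AuditResults(
            summaries=summaries,
            overall_summary=overall,
            indices=[compute_indices(s, thresholds, strict_ctr) for s in summaries],
            overall=compute_indices(overall, thresholds, strict_ctr),
            msbos=build_msbos_table(summaries, multiplier, overrides),
            thresholds=thresholds,
            multiplier=multiplier,
            strict_ctr=strict_ctr,
            n_excluded=self.n_excluded,
        )


@dataclass
class AuditResults:
    """Fitted audit: per-procedure and overall indices plus the MSBOS table."""

    summaries: list[ProcedureSummary]
    overall_summary: ProcedureSummary
    indices: list[UtilizationIndices]
    overall: UtilizationIndices
    msbos: list[MSBOSEntry]
    thresholds: Thresholds
    multiplier: float
    strict_ctr: bool = False
    n_excluded: int = 0
    provenance: dict = field(default_factory=dict)

    # -- tabular views ------------------------------------------------------

    def indices_frame(self, include_overall: bool = True) -> pd.DataFrame:
        """Indices as a DataFrame, one row per procedure (plus ``ALL``).

        ``t_pct_ci_low``/``t_pct_ci_high`` are 95% Wilson score bounds on the
        transfusion probability, from the transfused-patient proportion.
        """
        from statsmodels.stats.proportion import proportion_confint

        rows = []
        pairs = list(zip(self.summaries, self.indices))
        if include_overall:
            pairs.append((self.overall_summary, self.overall))
        for summary, idx in pairs:
            low, high = proportion_confint(
                summary.n_transfused_patients, summary.n_patients, method="wilson"
            )
            rows.append(
                {
                    "procedure": summary.procedure,
                    "n_patients": summary.n_patients,
                    "n_transfused_patients": summary.n_transfused_patients,
                    "units_crossmatched": summary.units_crossmatched,
                    "units_transfused": summary.units_transfused,
                    "ctr": idx.ctr,
                    "t_pct": idx.t_pct,
                    "t_pct_ci_low": 100 * low,
                    "t_pct_ci_high": 100 * high,
                    "ti": idx.ti,
                    "nup": idx.nup,
                    "wapi": idx.wapi,
                    "flags": ",".join(sorted(idx.flags)),
                }
            )
        return pd.DataFrame(rows)

    def msbos_frame(self) -> pd.DataFrame:
        rows = [
            {
                "procedure": e.procedure,
                "raw_msbos": e.raw_msbos,
                "rounded_msbos": e.rounded_msbos,
                "recommendation": str(e.recommendation),
                "multiplier": e.multiplier,
            }
            for e in self.msbos
        ]
        return pd.DataFrame(rows)

    @property
    def flagged(self) -> dict[str, frozenset[str]]:
        """Procedures with at least one efficiency flag raised."""
        return {idx.procedure: idx.flags for idx in self.indices if idx.flags}

    # -- rendering ----------------------------------------------------------

    def summary(self, style: str = "full") -> str:
        """Plain-text audit report (``style`` is ``"full"`` or ``"paper"``)."""
        return render_table(self, style)

    def to_files(self, output_dir, paper_style: bool = False) -> list[Path]:
        """Write indices CSV, MSBOS CSV + JSON, and the text report; return paths."""
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []

        indices_path = outdir / "indices.csv"
        self.indices_frame().to_csv(indices_path, index=False, float_format="%.6g")
        written.append(indices_path)

        msbos_csv = outdir / "msbos.csv"
        self.msbos_frame().to_csv(msbos_csv, index=False, float_format="%.6g")
        written.append(msbos_csv)

        msbos_json = outdir / "msbos.json"
        payload = [
            {
                "procedure": e.procedure,
                "raw_msbos": e.raw_msbos,
                "rounded_msbos": e.rounded_msbos,
                "recommendation": {
                    "kind": e.recommendation.kind,
                    "units": e.recommendation.units,
                },
                "multiplier": e.multiplier,
            }
            for e in self.msbos
        ]
        msbos_json.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
        written.append(msbos_json)

        report_path = outdir / "report.txt"
        report_path.write_text(
            self.summary("paper" if paper_style else "full"), encoding="utf-8"
        )
        written.append(report_path)
        return written


def _fmt_ctr(value: float | None, style: str) -> str:
    if value is None:
        return "0" if style == "paper" else "undef"
    return f"{round_half_up(value, 2):g}"


def _fmt_t(value: float, style: str) -> str:
    if style == "paper":
        return f"{round_half_up(value / 100, 2):g}"
    return f"{round_half_up(value, 1):g}%"


def _fmt_opt(value: float | None, ndigits: int = 2) -> str:
    return "undef" if value is None else f"{round_half_up(value, ndigits):g}"


def render_table(results: AuditResults, style: str = "full") -> str:
    """Render the audit as a fixed-width text report.

    ``paper`` style follows classical printed audit conventions (CTR 0 for
    zero-transfusion rows, T% as a fraction); ``full`` style prints ``undef``
    for undefined values and T% as a percentage.
    """
    if style not in {"full", "paper"}:
        raise ValueError(f"unknown style {style!r}")

    header = [
        "procedure", "patients", "transfused", "xm_units", "tx_units",
        "CTR", "T%", "TI", "NUP", "WAPI", "rawMSBOS", "MSBOS", "order", "flags",
    ]
    msbos_by_proc = {e.procedure: e for e in results.msbos}
    rows = []
    for summary, idx in zip(results.summaries, results.indices):
        entry = msbos_by_proc.get(summary.procedure)
        rows.append(
            [
                summary.procedure,
                str(summary.n_patients),
                str(summary.n_transfused_patients),
                str(summary.units_crossmatched),
                str(summary.units_transfused),
                _fmt_ctr(idx.ctr, style),
                _fmt_t(idx.t_pct, style),
                f"{round_half_up(idx.ti, 2):g}",
                _fmt_opt(idx.nup),
                _fmt_opt(idx.wapi, 1),
                f"{round_half_up(entry.raw_msbos, 2):g}" if entry else "",
                str(entry.rounded_msbos) if entry else "",
                str(entry.recommendation) if entry else "",
                ",".join(sorted(idx.flags)) or "-",
            ]
        )
    o, oi = results.overall_summary, results.overall
    rows.append(
        [
            o.procedure, str(o.n_patients), str(o.n_transfused_patients),
            str(o.units_crossmatched), str(o.units_transfused),
            _fmt_ctr(oi.ctr, style), _fmt_t(oi.t_pct, style),
            f"{round_half_up(oi.ti, 2):g}", _fmt_opt(oi.nup), _fmt_opt(oi.wapi, 1),
            "", "", "", ",".join(sorted(oi.flags)) or "-",
        ]
    )

    widths = [max(len(header[i]), *(len(r[i]) for r in rows)) for i in range(len(header))]
    fmt_row = lambda cells: "  ".join(c.rjust(w) for c, w in zip(cells, widths))
    lines = [
        f"# blood-ordering audit ({datetime.datetime.now():%Y-%m-%d %H:%M:%S})",
        f"# style={style} multiplier={results.multiplier:g} "
        f"ctr_max={results.thresholds.ctr_strict_max if results.strict_ctr else results.thresholds.ctr_max:g} "
        f"t_pct_min={results.thresholds.t_pct_min:g} ti_min={results.thresholds.ti_min:g} "
        f"excluded_records={results.n_excluded}",
        fmt_row(header),
        fmt_row(["-" * w for w in widths]),
        *[fmt_row(r) for r in rows],
    ]
    if results.flagged:
        flagged = "; ".join(f"{p}: {','.join(sorted(f))}" for p, f in sorted(results.flagged.items()))
        lines.append(f"# flagged: {flagged}")
    else:
        lines.append("# flagged: none")
    return "\n".join(lines) + "\n"
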