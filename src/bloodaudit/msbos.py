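"""Maximum Surgical Blood Order Schedule (MSBOS) construction.

The MSBOS answers, per elective procedure: how many red-cell units should the
blood bank crossmatch preoperatively — or is a type-and-screen (T&S) enough?

The schedule here is derived from observed utilization: the raw MSBOS for a
procedure is the mean number of units transfused per crossmatched patient
(identical to the transfusion index TI on the same cohort), computed as the
patient-weighted mean of the transfused-unit-count histogram.  The raw value,
optionally scaled by a site multiplier (1.0 by default; some services use
1.5×TI), is rounded *up* to a whole unit count.  A rounded value of zero means
no units are reserved and a T&S suffices; clinical judgement can raise
individual procedures above their computed value via per-procedure override
floors supplied in configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .indices import UndefinedDenominatorError
from .records import OVERALL_CODE, ProcedureSummary, ValidationError

__all__ = [
    "Recommendation",
    "MSBOSEntry",
    "raw_msbos",
    "round_msbos",
    "recommend",
    "build_msbos_table",
]

#: Order categories.  ``NO_TESTING`` is representable (some published
#: schedules include a "no testing required" tier) but never produced by the
#: derivation here, which has no rule for it.
CROSSMATCH = "crossmatch"
TYPE_AND_SCREEN = "T&S"
NO_TESTING = "none"


@dataclass(frozen=True)
class Recommendation:
    """A preoperative order: crossmatch ``units`` units, or T&S only (units = 0)."""

    kind: str  # CROSSMATCH | TYPE_AND_SCREEN | NO_TESTING
    units: int = 0

    def __str__(self) -> str:
        return str(self.units) if self.kind == CROSSMATCH else self.kind


@dataclass(frozen=True)
class MSBOSEntry:
    """Raw, rounded, and recommended order for one procedure."""

    procedure: str
    raw_msbos: float
    rounded_msbos: int
    recommendation: Recommendation
    multiplier: float = 1.0


def raw_msbos(histogram: Mapping[int, int], n_patients: int) -> float:
    """Weighted mean units per patient: Σ(k × histogram[k]) / n_patients.

    ``histogram`` maps a transfused-unit count to the number of patients who
    received exactly that many units; its values must sum to ``n_patients``.
    """
    if n_patients == 0:
        raise UndefinedDenominatorError("raw MSBOS undefined: no patients")
    if n_patients < 0:
        raise ValidationError("n_patients must be positive")
    if sum(histogram.values()) != n_patients:
        raise ValidationError(
            f"histogram covers {sum(histogram.values())} patients, expected {n_patients}"
        )
    return sum(k * count for k, count in histogram.items()) / n_patients


def round_msbos(raw: float, multiplier: float = 1.0) -> int:
    """Round the scaled raw value *up* to a whole unit count.

    Ceiling semantics: 1.03 → 2, 0.77 → 1, 0 → 0; exact integers map to
    themselves (a small tolerance absorbs float noise such as 2.0000000000004).
    """
    if multiplier <= 0:
        raise ValidationError(f"multiplier must be positive, got {multiplier}")
    if raw < 0:
        raise ValidationError(f"raw MSBOS must be non-negative, got {raw}")
    return max(0, math.ceil(raw * multiplier - 1e-9))


def recommend(rounded: int, override: int | None = None) -> Recommendation:
    """Map a rounded unit count to an order recommendation.

    Zero units → type and screen only.  One or more → crossmatch that many,
    raised to ``override`` when a per-procedure floor is configured (overrides
    never turn a T&S into a crossmatch).
    """
    if rounded < 0:
        raise ValidationError("rounded MSBOS must be non-negative")
    if rounded == 0:
        return Recommendation(TYPE_AND_SCREEN, 0)
    units = max(rounded, override) if override is not None else rounded
    return Recommendation(CROSSMATCH, units)


def build_msbos_table(
    summaries: Sequence[ProcedureSummary],
    multiplier: float = 1.0,
    overrides: Mapping[str, int] | None = None,
) -> list[MSBOSEntry]:
    """Build the schedule: one entry per procedure, sorted by descending patient count.

    Whole-cohort (``"ALL"``) summaries are skipped — a schedule is
    per-procedure by definition.  Deterministic: ties in patient count break
    alphabetically, and repeat calls on equal inputs yield equal output.
    """
    if not summaries:
        raise ValidationError("no procedure summaries to schedule")
    overrides = overrides or {}
    entries = []
    for summary in sorted(
        (s for s in summaries if s.procedure != OVERALL_CODE),
        key=lambda s: (-s.n_patients, s.procedure),
    ):
        try:
            raw = raw_msbos(summary.unit_count_histogram, summary.n_patients)
            rounded = round_msbos(raw, multiplier)
        except (ValidationError, UndefinedDenominatorError) as exc:
            raise type(exc)(f"{summary.procedure}: {exc}") from exc
        entries.append(
            MSBOSEntry(
                procedure=summary.procedure,
                raw_msbos=raw,
                rounded_msbos=rounded,
                recommendation=recommend(rounded, overrides.get(summary.procedure)),
                multiplier=multiplier,
            )
        )
    return entries
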