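"""Blood-utilization indices and efficiency thresholds.

Five standard blood-bank audit indices, computed per procedure or for a whole
cohort:

* **CTR** — crossmatch-to-transfusion ratio: units crossmatched / units
  transfused.  Ideally near 1; values above ~2–2.5 indicate over-ordering.
* **T%** — transfusion probability: percentage of crossmatched patients who
  actually received blood.  ≥30% indicates a genuine need to reserve blood.
* **TI** — transfusion index: mean units transfused per crossmatched patient.
  ≥0.5 indicates meaningful utilization.
* **NUP** — non-usage probability: fraction of requested units never
  transfused; algebraically ``1 − 1/CTR`` whenever any unit was transfused.
* **WAPI** — wastage as a percentage of issue: wasted units / issued units
  × 100, with wastage categorized.

Division-by-zero conventions: CTR is undefined (``None``) when units were
crossmatched but none transfused, and 0 when nothing was crossmatched at all;
NUP and WAPI are undefined when the denominator is zero.  Report layers decide
how undefined values are rendered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .records import ProcedureSummary, ValidationError

__all__ = [
    "UndefinedDenominatorError",
    "Thresholds",
    "UtilizationIndices",
    "compute_ctr",
    "compute_t_pct",
    "compute_ti",
    "compute_nup",
    "compute_wapi",
    "flag",
    "compute_indices",
]


class UndefinedDenominatorError(ValueError):
    """An index was requested for a denominator of zero where no convention applies."""


@dataclass(frozen=True)
class Thresholds:
    """Efficiency thresholds the indices are flagged against.

    ``ctr_max`` (default 2.5) is the commonly recommended upper bound for
    efficient ordering; ``ctr_strict_max`` (default 2.0) is the stricter bound
    above which reserved blood is considered significantly unutilized.
    ``t_pct_min`` (default 30) and ``ti_min`` (default 0.5) are the classical
    lower bounds for meaningful blood usage.
    """

    ctr_max: float = 2.5
    ctr_strict_max: float = 2.0
    t_pct_min: float = 30.0
    ti_min: float = 0.5

    def __post_init__(self) -> None:
        for name in ("ctr_max", "ctr_strict_max", "t_pct_min", "ti_min"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name} must be positive")
        if self.ctr_strict_max > self.ctr_max:
            raise ValidationError("ctr_strict_max must not exceed ctr_max")


@dataclass
class UtilizationIndices:
    """The five indices for one procedure (or the whole cohort) plus flags.

    ``ctr``, ``nup`` and ``wapi`` are ``None`` when undefined; ``flags`` is a
    frozenset drawn from ``{"ctr_inefficient", "t_low", "ti_low"}``.
    """

    procedure: str
    ctr: float | None
    t_pct: float
    ti: float
    nup: float | None
    wapi: float | None
    flags: frozenset[str] = field(default_factory=frozenset)


def _check_counts(**counts: int) -> None:
    for name, value in counts.items():
        if value < 0:
            raise ValidationError(f"{name} must be non-negative, got {value}")


def compute_ctr(units_crossmatched: int, units_transfused: int) -> float | None:
    """Crossmatch-to-transfusion ratio.

    Returns ``None`` (undefined) when units were crossmatched but none
    transfused, and 0.0 when both counts are zero.
    """
    _check_counts(units_crossmatched=units_crossmatched, units_transfused=units_transfused)
    if units_transfused == 0:
        return 0.0 if units_crossmatched == 0 else None
    return units_crossmatched / units_transfused


def compute_t_pct(n_transfused_patients: int, n_patients: int) -> float:
    """Transfusion probability: 100 × transfused patients / crossmatched patients."""
    _check_counts(n_transfused_patients=n_transfused_patients, n_patients=n_patients)
    if n_patients == 0:
        raise UndefinedDenominatorError("T% undefined: no crossmatched patients")
    if n_transfused_patients > n_patients:
        raise ValidationError("transfused patients exceed crossmatched patients")
    return 100.0 * n_transfused_patients / n_patients


def compute_ti(units_transfused: int, n_patients: int) -> float:
    """Transfusion index: mean units transfused per crossmatched patient."""
    _check_counts(units_transfused=units_transfused, n_patients=n_patients)
    if n_patients == 0:
        raise UndefinedDenominatorError("TI undefined: no crossmatched patients")
    return units_transfused / n_patients


def compute_nup(units_crossmatched: int, units_transfused: int) -> float | None:
    """Non-usage probability: (crossmatched − transfused) / crossmatched.

    Undefined (``None``) when nothing was requested.  A transfused count above
    the crossmatched count is clamped with a warning (it can only arise from
    uncrossmatched emergency units leaking into the data).
    """
    _check_counts(units_crossmatched=units_crossmatched, units_transfused=units_transfused)
    if units_crossmatched == 0:
        return None
    if units_transfused > units_crossmatched:
        warnings.warn(
            "units_transfused exceeds units_crossmatched; clamping NUP to 0",
            stacklevel=2,
        )
        units_transfused = units_crossmatched
    return (units_crossmatched - units_transfused) / units_crossmatched


def compute_wapi(units_wasted: int, units_issued: int) -> float | None:
    """Wastage as a percentage of issue: 100 × wasted / issued (``None`` if none issued)."""
    _check_counts(units_wasted=units_wasted, units_issued=units_issued)
    if units_issued == 0:
        return None
    if units_wasted > units_issued:
        raise ValidationError("wasted units exceed issued units")
    return 100.0 * units_wasted / units_issued


def flag(
    indices: UtilizationIndices,
    thresholds: Thresholds | None = None,
    strict_ctr: bool = False,
) -> frozenset[str]:
    """Flag computed indices against the thresholds.

    ``ctr_inefficient`` when CTR is defined and exceeds ``ctr_max`` (or
    ``ctr_strict_max`` in strict mode); ``t_low`` when T% is below
    ``t_pct_min``; ``ti_low`` when TI is below ``ti_min``.
    """
    thresholds = thresholds or Thresholds()
    ctr_bound = thresholds.ctr_strict_max if strict_ctr else thresholds.ctr_max
    flags = set()
    if indices.ctr is not None and indices.ctr > ctr_bound:
        flags.add("ctr_inefficient")
    if indices.t_pct < thresholds.t_pct_min:
        flags.add("t_low")
    if indices.ti < thresholds.ti_min:
        flags.add("ti_low")
    return frozenset(flags)


def compute_indices(
    summary: ProcedureSummary,
    thresholds: Thresholds | None = None,
    strict_ctr: bool = False,
) -> UtilizationIndices:
    """Compute all five indices (and flags) from a procedure summary."""
    result = UtilizationIndices(
        procedure=summary.procedure,
        ctr=compute_ctr(summary.units_crossmatched, summary.units_transfused),
        t_pct=compute_t_pct(summary.n_transfused_patients, summary.n_patients),
        ti=compute_ti(summary.units_transfused, summary.n_patients),
        nup=compute_nup(summary.units_crossmatched, summary.units_transfused),
        wapi=compute_wapi(summary.total_units_wasted, summary.units_issued),
    )
    result.flags = flag(result, thresholds, strict_ctr)
    return result
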