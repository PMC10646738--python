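"""Synthetic transfusion cohorts with the statistical structure the audit assumes.

Real transfusion-service records are rarely shareable, so every stage of the
pipeline is exercised on synthetic cohorts instead.  A cohort is specified
per procedure: a fixed number of crossmatched units per patient (2 in the
reference practice below) and a categorical distribution over transfused unit
counts {0, …, K}; patients are sampled i.i.d. from that distribution.
Optionally each issued unit carries an independent probability of a wastage
event, with a category distribution over the four standard wastage causes.

Two construction modes:

* :func:`generate_cohort` — random sampling from a :class:`CohortSpec`,
  deterministic given the seed.
* :func:`exact_cohort_from_histogram` — deterministic reconstruction of a
  cohort from its transfused-unit-count histogram, so printed audit tables can
  be replayed through the full pipeline exactly, with no sampling error.

The module also ships :data:`REFERENCE_HISTOGRAMS`: the per-procedure
histograms of a published single-center audit of 8 elective pediatric cardiac
procedure groups (ventricular/atrial septal defect repair, tetralogy of
Fallot, arterial-switch for transposition, ductus ligation, pulmonary
stenosis, coarctation repair, pacemaker insertion), in which every patient had
2 adult red-cell units crossmatched and at most 3 transfused.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np
import yaml

from .records import WASTAGE_CATEGORIES, TransfusionRecord, ValidationError

__all__ = [
    "CohortBlock",
    "CohortSpec",
    "generate_cohort",
    "exact_cohort_from_histogram",
    "REFERENCE_HISTOGRAMS",
    "REFERENCE_CROSSMATCH_PER_PATIENT",
    "REFERENCE_RECOMMENDATION_FLOORS",
    "REFERENCE_OVERALL",
    "reference_records",
]

_PMF_TOL = 1e-9


@dataclass
class CohortBlock:
    """Generative parameters for one procedure's patients.

    ``transfusion_pmf`` maps a transfused-unit count to its probability; it
    must sum to 1.  ``wastage_rate`` is the per-issued-unit probability of a
    wastage event; categories are drawn from ``wastage_category_pmf``
    (uniform over the four standard categories by default).
    """

    procedure: str
    n_patients: int
    transfusion_pmf: dict[int, float]
    crossmatch_per_patient: int = 2
    wastage_rate: float = 0.0
    wastage_category_pmf: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError(f"{self.procedure}: n_patients must be >= 1")
        if self.crossmatch_per_patient < 0:
            raise ValidationError(f"{self.procedure}: crossmatch_per_patient must be >= 0")
        if not 0.0 <= self.wastage_rate <= 1.0:
            raise ValidationError(f"{self.procedure}: wastage_rate must be in [0, 1]")
        self.transfusion_pmf = {int(k): float(v) for k, v in self.transfusion_pmf.items()}
        _validate_pmf(self.transfusion_pmf, f"{self.procedure}: transfusion_pmf")
        if any(k < 0 for k in self.transfusion_pmf):
            raise ValidationError(f"{self.procedure}: unit counts must be non-negative")
        if not self.wastage_category_pmf:
            self.wastage_category_pmf = {c: 1 / len(WASTAGE_CATEGORIES) for c in sorted(WASTAGE_CATEGORIES)}
        _validate_pmf(self.wastage_category_pmf, f"{self.procedure}: wastage_category_pmf")
        if set(self.wastage_category_pmf) - WASTAGE_CATEGORIES:
            raise ValidationError(f"{self.procedure}: unknown wastage categories")

    @property
    def expected_units_per_patient(self) -> float:
        return sum(k * p for k, p in self.transfusion_pmf.items())


def _validate_pmf(pmf: Mapping, label: str) -> None:
    if not pmf:
        raise ValidationError(f"{label} is empty")
    if any(not 0.0 <= p <= 1.0 for p in pmf.values()):
        raise ValidationError(f"{label} has probabilities outside [0, 1]")
    total = sum(pmf.values())
    if abs(total - 1.0) > _PMF_TOL:
        raise ValidationError(f"{label} sums to {total}, not 1")


@dataclass
class CohortSpec:
    """A multi-procedure synthetic cohort: one block per procedure plus a seed."""

    blocks: list[CohortBlock]
    seed: int | None = None

    @classmethod
    def from_dict(cls, data: Mapping) -> "CohortSpec":
        blocks = [CohortBlock(**block) for block in data["blocks"]]
        return cls(blocks=blocks, seed=data.get("seed"))

    @classmethod
    def from_yaml(cls, source: str | Path | IO[str]) -> "CohortSpec":
        if isinstance(source, (str, Path)):
            with open(source, encoding="utf-8") as handle:
                return cls.from_yaml(handle)
        return cls.from_dict(yaml.safe_load(source))


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> list[TransfusionRecord]:
    """Sample a cohort: exactly ``n_patients`` records per block, i.i.d. transfused counts.

    One seeded generator drives the whole cohort (``seed`` argument overrides
    the spec's); record order is generation order, so identical spec + seed
    gives identical cohorts.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    records: list[TransfusionRecord] = []
    for block in spec.blocks:
        counts = sorted(block.transfusion_pmf)
        probs = np.array([block.transfusion_pmf[k] for k in counts], dtype=float)
        probs /= probs.sum()  # renormalise away the <=1e-9 tolerance
        drawn = rng.choice(counts, size=block.n_patients, p=probs)
        categories = sorted(block.wastage_category_pmf)
        cat_probs = np.array([block.wastage_category_pmf[c] for c in categories], dtype=float)
        cat_probs /= cat_probs.sum()
        for i, units in enumerate(drawn):
            events: list[tuple[str, int]] = []
            if block.wastage_rate > 0 and block.crossmatch_per_patient > 0:
                n_wasted = rng.binomial(block.crossmatch_per_patient, block.wastage_rate)
                for _ in range(int(n_wasted)):
                    events.append((str(rng.choice(categories, p=cat_probs)), 1))
            records.append(
                TransfusionRecord(
                    patient_id=f"{block.procedure}-{i + 1:05d}",
                    procedure=block.procedure,
                    units_crossmatched=block.crossmatch_per_patient,
                    units_transfused=int(units),
                    wastage_events=events,
                )
            )
    return records


def exact_cohort_from_histogram(
    histogram: Mapping[int, int],
    crossmatch_per_patient: int = 2,
    procedure: str = "PROC",
) -> list[TransfusionRecord]:
    """Deterministically reconstruct a cohort realizing a unit-count histogram.

    Produces ``histogram[k]`` patients with exactly ``k`` transfused units
    each, so summarizing the result recovers the histogram identically and the
    full pipeline reproduces any audit table computed from it.
    """
    if not histogram:
        raise ValidationError("histogram is empty")
    records = []
    i = 0
    for units in sorted(histogram, reverse=True):
        for _ in range(histogram[units]):
            i += 1
            records.append(
                TransfusionRecord(
                    patient_id=f"{procedure}-{i:05d}",
                    procedure=procedure,
                    units_crossmatched=crossmatch_per_patient,
                    units_transfused=int(units),
                )
            )
    return records


# ---------------------------------------------------------------------------
# reference audit (single-center elective pediatric cardiac surgery)

#: Transfused-unit-count histograms per procedure group, as printed in the
#: reference audit's schedule calculation (patients over 0/1/2/3 units).
REFERENCE_HISTOGRAMS: dict[str, dict[int, int]] = {
    "VSD": {3: 1, 2: 43, 1: 12, 0: 8},
    "TOF": {2: 11, 1: 8, 0: 10},
    "DTGA": {2: 9, 1: 2, 0: 2},
    "ASD": {2: 10, 1: 5},
    "PDA": {0: 3},
    "PS": {2: 1, 1: 3},
    "COA": {2: 1, 1: 8, 0: 4},
    "PACING": {0: 5},
}

#: The reference service crossmatched 2 adult units for every patient.
REFERENCE_CROSSMATCH_PER_PATIENT = 2

#: Clinical-judgement floors applied on top of the computed schedule
#: (coarctation repair is kept at 2 units despite a computed 1).
REFERENCE_RECOMMENDATION_FLOORS: dict[str, int] = {"COA": 2}

#: Whole-audit totals as published (the printed per-procedure rows cover only
#: part of the cohort, so these totals are inputs in their own right).
REFERENCE_OVERALL = {
    "n_patients": 205,
    "n_transfused_patients": 157,
    "units_crossmatched": 410,
    "units_transfused": 262,
}


def reference_records() -> list[TransfusionRecord]:
    """All reference-audit procedure cohorts as one exact (non-random) record list."""
    records = []
    for procedure, histogram in REFERENCE_HISTOGRAMS.items():
        records.extend(
            exact_cohort_from_histogram(
                histogram, REFERENCE_CROSSMATCH_PER_PATIENT, procedure
            )
        )
    return records
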