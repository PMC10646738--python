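# Methods

## Model of the data

The unit of analysis is one patient-procedure episode of elective surgery:
the blood bank crossmatches `c` red-cell units for the patient before the
operation and `k` units are eventually transfused (`k` may exceed `c` for an
individual patient when extra units are obtained intraoperatively). Units
are whole adult red-cell bags; no volume arithmetic is performed. Episodes
flagged as excluded (massive transfusion, transfusion reaction) are carried
through I/O but enter no aggregate, mirroring standard audit exclusion
practice. Procedure codes are free strings normalised by trimming and
upper-casing, with an optional alias map folding synonyms; repeated patient
identifiers are treated as distinct episodes.

Aggregation per procedure produces the counts every downstream quantity is a
ratio of: patients crossmatched `N`, patients transfused `N_t`, units
crossmatched `X`, units transfused `T`, the histogram `h(k)` of patients by
transfused-unit count, issued units (defaulting to `X` when no separate
issue figure exists — audits typically record reserved units only) and
wasted units by category.

## Indices and conventions

CTR `= X/T`, T% `= 100·N_t/N`, TI `= T/N`, NUP `= (X−T)/X`, WAPI
`= 100·wasted/issued`. Useful identities, enforced as invariants in the test
suite whenever `0 < T ≤ X`:

- `NUP = 1 − 1/CTR` (to 1e-12),
- `CTR · TI = X/N`,
- `TI = (T%/100) ·` (mean units among transfused patients),
- the whole-cohort TI is the patient-weighted mean of per-procedure TIs.

Degenerate denominators are handled by convention rather than exception
where a convention exists in practice: CTR is `None` (undefined) when units
were reserved but none transfused and 0 when nothing was reserved at all;
NUP and WAPI are `None` when nothing was requested/issued. T% and TI with
zero patients raise `UndefinedDenominatorError` — there is no cohort to
speak of. A transfused total exceeding the crossmatched total clamps NUP to
0 with a warning (it arises when uncrossmatched emergency units enter the
records). Undefined values serialize as empty CSV cells, JSON `null`, and
`undef` in text reports; the `paper` rendering style instead prints 0 for an
undefined CTR and T% as a fraction of 1, because classical printed audit
tables use those conventions and bit-level reproduction of such tables is a
supported use.

Display rounding is two decimal places, half-up (`1.565 → 1.57`), applied
only at the rendering layer; all internal values keep full precision.

## Thresholds

Flags compare each procedure's indices to configurable bounds: CTR above
2.5 (`ctr_inefficient`; the widely recommended upper bound for efficient
ordering), with a strict mode at 2.0 (the bound above which reserved blood
counts as significantly unutilized); T% below 30 (`t_low`); TI below 0.5
(`ti_low`). Both CTR bounds appear in the transfusion-audit literature, so
both are kept and the default flags against 2.5.

## MSBOS derivation

Raw MSBOS for a procedure is `Σ k·h(k) / N` — exactly TI, computed from the
histogram so printed schedule calculations can be replayed cell by cell.
The rounded schedule is `ceil(raw × multiplier)`; "rounded up" is ceiling,
not half-up, which is the only rule consistent with observed published
schedules (1.03 → 2, 0.77 → 1, 0 → 0), with a 1e-9 tolerance so exact
integers map to themselves. The multiplier defaults to 1.0 (appropriate
when adult bags are used for pediatric patients, as in the reference
service); 1.5 is available for sites following the 1.5×TI convention. A
rounded value of 0 yields "type and screen only"; positive values yield an
`n`-unit crossmatch, raised to a configured per-procedure floor where
clinical judgement demands more than the data (floors never convert a T&S
into a crossmatch). A "no testing required" tier is representable but never
emitted — no derivation rule produces it. The table is sorted by descending
patient count (ties alphabetically) and is a pure function of its input.

## Synthetic cohorts

The generator emulates the structure the analysis assumes: per procedure, a
fixed crossmatch count per patient (2 in the reference practice) and i.i.d.
transfused-unit counts from a categorical distribution over {0,…,K}, K = 3
by default (the largest per-patient count observed in the reference audit).
Optional wastage events occur per issued unit with a Bernoulli rate and a
categorical cause distribution (uniform over the four standard causes by
default, rate 0 unless asked for — the reference audit recorded no
wastage). One `numpy` generator seeded per cohort drives everything; record
order is generation order, so identical spec + seed gives identical
cohorts. `exact_cohort_from_histogram` is the deterministic counterpart:
it realizes a histogram exactly, with no sampling, which is how the shipped
reference cohorts are built and how printed tables are reproduced without
tolerance.

What the generator does *not* emulate: patient covariates (weight,
hemoglobin, comorbidity), within-procedure heterogeneity over time,
correlation between crossmatch and transfusion counts, or surgeon effects.
Passing tests therefore demonstrate correctness of the accounting and the
schedule derivation on data with the assumed structure, not that a derived
schedule is clinically adequate for any particular service.

## Reference cohorts and known discrepancies

The shipped reference histograms come from a published single-center audit
of eight elective pediatric cardiac procedure groups (205 patients overall,
410 units crossmatched, 262 transfused). The printed per-procedure rows
cover 146 patients (292/191 units) — the remainder of the cohort is not
itemized — so the overall indices are computed from the published totals,
which are inputs in their own right, while per-procedure quantities are
recomputed from the histograms. Two printed figures are internally
inconsistent with their own numerators: the ASD raw value appears truncated
(25/15 = 1.667 printed as 1.66) and the overall T% likewise (157/205 =
76.6% printed as 76%); this package reports the correctly rounded values.
The coarctation row's recommended order (2) exceeds its computed rounded
value (1); that is clinical judgement, reproduced via the shipped override
floor rather than derived. One source table lists 23 transposition patients
while its schedule calculation divides by 13; the pipeline always divides
by the cohort it is actually given.

## Problem sizes and verification

Exact-reproduction tests run on the 146-record reference cohort and are
instantaneous. Property-based tests (hypothesis, derandomised) use cohorts
of up to ~60 records against brute-force per-row accumulation oracles.
Parameter-recovery tests and the acceptance script use a 10,000-patient
synthetic cohort and assert recovery of TI, T% and CTR within 3 standard
errors of the generative moments (delta-method SE for CTR). The whole suite
and the acceptance script each complete in a few seconds on one CPU.

## Limitations

Plasma and platelet products are out of scope, as are HL7/FHIR/LIS
integration, hemoglobin-trigger or risk-factor modelling, and longitudinal
comparison across audit periods. WAPI is computable only to the extent that
issue and wastage data exist; with reserved-unit data alone it reports
wastage against crossmatched units. The MSBOS here is purely utilization-
derived; services should overlay clinical judgement via the override
mechanism rather than editing computed values.
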