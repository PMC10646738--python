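# bloodaudit

Blood-ordering audits for elective surgery: compute the standard blood-bank
utilization indices from patient-level transfusion records, flag inefficient
ordering, and derive a **Maximum Surgical Blood Order Schedule (MSBOS)** —
the per-procedure table telling the blood bank how many red-cell units to
crossmatch preoperatively, or whether a type-and-screen (T&S) suffices.

It is written for transfusion-medicine and hospital blood-bank teams running
utilization reviews, with a library API (`BloodOrderAudit` → `AuditResults`)
and a small CLI (`bloodaudit audit | simulate | msbos`).

## The indices

For a cohort of crossmatched surgical patients, with `X` units crossmatched,
`T` units transfused, `N` patients crossmatched and `N_t` patients actually
transfused:

- **CTR** (crossmatch-to-transfusion ratio) = `X / T`. Ideally near 1;
  values above 2–2.5 indicate significant over-ordering. Undefined when
  units were reserved but none transfused (classical printed tables show 0).
- **T%** (transfusion probability) = `100 · N_t / N`. Values of 30% and
  above indicate blood was genuinely needed.
- **TI** (transfusion index) = `T / N`, the mean units transfused per
  crossmatched patient. 0.5 or more indicates meaningful utilization.
- **NUP** (non-usage probability) = `(X − T) / X`, equal to `1 − 1/CTR`.
- **WAPI** (wastage as % of issue) = `100 · wasted / issued`, with wastage
  categorized (expired after issue, improper storage, late return, other).

The MSBOS for a procedure is the patient-weighted mean of transfused unit
counts — identical to TI — optionally scaled by a site multiplier (1.0 by
default, 1.5 at sites following the 1.5×TI convention), then rounded **up**
to a whole unit count. A rounded value of 0 maps to "T&S only"; clinical
judgement can raise individual procedures via per-procedure override floors.

## Worked example

The package ships the per-procedure transfused-unit histograms of a
single-center audit of 205 elective pediatric cardiac surgeries (2 adult
units crossmatched per patient), replayable as exact record-level cohorts:

```python
from bloodaudit import BloodOrderAudit, reference_records
from bloodaudit.synthetic import REFERENCE_RECOMMENDATION_FLOORS

results = BloodOrderAudit(reference_records()).fit(
    overrides=REFERENCE_RECOMMENDATION_FLOORS
)
print(results.summary("paper"))
```

```
procedure  patients  transfused  xm_units  tx_units   CTR    T%    TI   NUP  WAPI  rawMSBOS  MSBOS  order            flags
---------  --------  ----------  --------  --------  ----  ----  ----  ----  ----  --------  -----  -----  ---------------
      VSD        64          56       128       101  1.27  0.88  1.58  0.21     0      1.58      2      2                -
      TOF        29          19        58        30  1.93  0.66  1.03  0.48     0      1.03      2      2                -
      ASD        15          15        30        25   1.2     1  1.67  0.17     0      1.67      2      2                -
      COA        13           9        26        10   2.6  0.69  0.77  0.62     0      0.77      1      2  ctr_inefficient
     DTGA        13          11        26        20   1.3  0.85  1.54  0.23     0      1.54      2      2                -
   PACING         5           0        10         0     0     0     0     1     0         0      0    T&S     t_low,ti_low
       PS         4           4         8         5   1.6     1  1.25  0.38     0      1.25      2      2                -
      PDA         3           0         6         0     0     0     0     1     0         0      0    T&S     t_low,ti_low
      ALL       146         114       292       191  1.53  0.78  1.31  0.35     0                                        -
# flagged: COA: ctr_inefficient; PACING: t_low,ti_low; PDA: t_low,ti_low
```

Reading it: ventricular septal defect repair (VSD) transfused 101 units to
64 patients, so its raw MSBOS is 101/64 = 1.58, rounded up to a 2-unit
preoperative crossmatch. Coarctation repair (COA) is the only procedure
whose CTR (2.6) exceeds the 2.5 efficiency bound; its computed 1-unit order
is raised to 2 by a configured clinical floor. Ductus ligation (PDA) and
pacemaker insertion never transfused, so a type-and-screen suffices —
internally their CTR is undefined; the `paper` style prints 0 and T% as a
fraction, matching classical audit tables, while `full` prints `undef` and
percentages.

Synthetic cohorts with the same statistical structure (fixed crossmatch per
patient, categorical transfused-unit counts, optional per-unit wastage
events) come from `bloodaudit.synthetic`, or from the shell:

```sh
bloodaudit simulate --spec cohort.yaml --seed 7 --out cohort.csv
bloodaudit audit --records cohort.csv --out audit_out/
```

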