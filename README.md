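# hegrid

Error-grid analysis and accuracy assessment for continuous glucose
monitoring (CGM) in hypoglycaemia disorders.

Patients with congenital hyperinsulinism (CHI) and related conditions use
CGM purely to detect hypoglycaemia — not to dose insulin — so the classic
diabetes error grids (Clarke, Parkes) grade their measurement errors
against the wrong risks: they call a missed hypoglycaemia "no risk" and a
missed hyperglycaemia "dangerous". `hegrid` implements the alternative: a
**hypoglycaemia error grid (HEG)** built from clinician consensus, together
with the full accuracy-statistics pipeline needed to evaluate a CGM device
against fingerprick (SMBG) reference measurements.

The package is aimed at clinical researchers assessing sensor accuracy in
hypoglycaemia-first populations, and at anyone who needs a scriptable,
file-based error-grid workflow.

## What it does

* **Risk grids** (`hegrid.grid`) — polygon-based risk surfaces over
  (SMBG, CGM) space with zones A (none) < B (slight) < C (moderate) <
  D (severe) < E. Classification is deterministic; points on a zone
  boundary go to the more severe zone (a patient-safety tie-break). Ships
  with a reconstructed HEG (mmol/L, domain [0, 12]²) plus the published
  Clarke and Parkes (type 1) grids in the same JSON schema; mg/dL files are
  converted on load (1 mmol/L = 18.016 mg/dL).
* **Consensus grid construction** (`hegrid.construction`) — from rater
  questionnaires (4 glucose cutpoints defining 5 ranges + a 5×5 risk
  matrix): rasterisation over the 100×100 grid covering [0, 10) mmol/L in
  0.1 steps, per-cell mean risk (A=1 … D=4, half rounds up), slim-region
  merging, least-squares straightening of staggered (staircase) boundaries,
  and domain extension with the edge zones prolonged unchanged.
* **Pairing** (`hegrid.pairing`) — each SMBG is matched to the same
  patient's closest CGM value within ±5 minutes (ties go to the earlier
  reading); plus a windowed hypoglycaemia detection rate (any
  below-threshold CGM within ±15 minutes of an SMBG-confirmed event).
* **Metrics** (`hegrid.metrics`) — bias (mean CGM−SMBG), MAD, MARD
  (denominator = SMBG), ARD-by-glucose with linear/quadratic trends,
  sensitivity/specificity at arbitrary hypoglycaemia thresholds (strict
  `<`), hypoglycaemia incidence/odds within CGM strata, per-zone
  percentages, and the *practical subset* (pairs with at least one value
  below the 4.0 mmol/L action threshold).
* **Synthetic cohorts** (`hegrid.simulate`) — a seeded AR(1)+excursion
  generator emulating weeks of free-living CGM/SMBG data, so the whole
  pipeline is testable without patient data.

## Worked example

Simulate a 10-patient, 12-week cohort, then run the full report:

```sh
hegrid simulate --preset paper-like --seed 1 --out-dir data/
hegrid report --cgm data/cgm.csv --smbg data/smbg.csv --text
```

```text
2086 paired readings from 2086 SMBG and 241920 CGM readings (0 SMBG unpaired)
mean difference (CGM-SMBG) +0.47 mmol/L, MAD 0.89 mmol/L, MARD 18.0%, mean |dt| 1.2 min
threshold 3 mmol/L: sensitivity 59.5%, specificity 96.4%
threshold 3.5 mmol/L: sensitivity 57.5%, specificity 95.3%
threshold 3.9 mmol/L: sensitivity 59.1%, specificity 94.7%
detection (<3 mmol/L, 30-min window): 109/111 = 98%
detection (<3.5 mmol/L, 30-min window): 248/252 = 98%
detection (<3.9 mmol/L, 30-min window): 377/381 = 99%
zone percentages (full dataset):
  HEG: A 92.9, B 2.7, C 4.4; A-false-negative 0.0; C+ 4.4
  Clarke: A 68.6, B 25.6, C 0.0, D 5.8, E 0.0; A-false-negative 1.4; C+ 5.8
  Parkes: A 77.8, B 20.6, C 1.6, D 0.0, E 0.0; A-false-negative 2.5; C+ 1.6
practical subset (<4 mmol/L, n=506): mean diff +0.15, MAD 0.91, MARD 26.5%
```

Reading this: the simulated sensor over-reads by ~0.5 mmol/L on average
with a typical absolute error near 1 mmol/L (MARD 18%). Point sensitivity
for hypoglycaemia (<3.5 mmol/L) is 57.5%, while the diffuse 30-minute
window detects nearly every event. The legacy Clarke/Parkes grids park
1.4–2.5% of pairs — all missed hypoglycaemias — in their "no risk" zone A;
the HEG classifies every false negative as at least slight risk
(A-false-negative 0.0) and grades 4.4% of pairs as moderate (C+).
Restricting to the practically relevant pairs (either value below
4 mmol/L) drops MARD to 26.5%: accuracy is worst exactly where it matters.

Other subcommands: `build-grid` (questionnaire JSON/CSV → grid JSON),
`pair`, `classify`, `plot` (zones coloured by severity, false negatives
drawn as crosses). The same functionality is available as a library; see
the module docstrings.

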