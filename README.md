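# msrelapse

Claims-based analysis of high relapse activity (HRA) in multiple sclerosis:
relapse detection from administrative claims, treatment-pattern detection, and
adjusted utilization/cost modelling — with a synthetic claims generator so the
whole pipeline is testable without proprietary data.

## The problem

MS relapses are not recorded as such in insurance claims, yet relapse
frequency drives downstream utilization and cost. For researchers working with
administrative claims databases (enrollment spans, medical claims with ICD-9-CM
diagnosis codes, pharmacy fills), this package implements the standard
claims-based phenotyping chain:

1. **Relapse detection.** A relapse event is either (a) an inpatient stay with
   an MS diagnosis (340.xx) in the primary position, dated at admission, or
   (b) an outpatient/ER visit with an MS code in the primary or secondary
   position plus a qualifying corticosteroid claim on the day of the visit or
   within 7 days after it. Events without a 30-day event-free *clean period*
   between them merge into a single relapse episode.
2. **Exposure.** Patients with ≥2 episodes starting in the baseline year form
   the HRA cohort; 0–1 episodes, the non-HRA cohort.
3. **Cohort selection.** MS diagnosis in both the baseline and prior year,
   continuous enrollment over the baseline and follow-up years, age ≥18 —
   with a per-filter attrition report.
4. **Treatment experience.** Proportion of days covered,
   PDC = |covered days ∩ year| / |year|, per disease-modifying therapy (DMT);
   treatment-naïve = no baseline DMT claims, treatment-experienced = any
   single-DMT PDC ≥ 80% (ABCR therapies billed only through J-codes are
   excluded, since switches cannot be followed there).
5. **Treatment patterns.** Index DMT = last baseline DMT claim;
   discontinuation = a ≥60-day supply gap after a run-out (dated at the
   run-out); switch = first claim for a different DMT; initiation = first DMT
   claim in follow-up for naïve patients. Follow-up is flexible, censored
   2010-12-31.
6. **Estimation.** Bivariate t/chi-square summaries; logistic models for
   binary utilization and treatment-pattern outcomes with Wald odds ratios
   exp(β̂ ± 1.96·SE); a gamma GLM with log link for follow-up non-DMT costs,
   turned into covariate-adjusted group means by *recycled predictions*
   (predict every patient's cost with exposure forced to 1, then to 0, and
   average), with standard errors and 95% intervals from a paired
   *bias-corrected bootstrap*: resample patients, z₀ = Φ⁻¹(fraction of
   replicates below the point estimate), interval = replicate percentiles at
   Φ(2z₀ ± 1.96).

Every threshold (windows, clean period, PDC cut-off, gap length, code lists)
lives in a single `StudyConfig`, so the sensitivity analysis (all DMT-exposed
patients regardless of PDC) is a configuration switch.

## Worked example

```python
from pathlib import Path
import pandas as pd
from msrelapse import (SimConfig, StudyConfig, generate, inject_violators,
                       run_pipeline, write_table)

med, ph, enr, gt = generate(SimConfig(n_patients=2000, seed=7))
med, ph, enr, gt = inject_violators(
    med, ph, enr, gt,
    {"drop_prior_dx": 0.05, "enrollment_gap": 0.03, "underage": 0.02}, seed=8)
Path("claims").mkdir(exist_ok=True)
write_table(med, "claims/medical_claims.csv")
write_table(ph, "claims/pharmacy_claims.csv")
write_table(enr, "claims/enrollment.csv")

run_pipeline(StudyConfig(bootstrap_reps=200), "claims", "reports", seed=1)

print(pd.read_csv("reports/attrition.csv").to_string(index=False))
t2 = pd.read_csv("reports/table2.csv").set_index(["outcome", "term"])
print("HRA odds ratio, all-cause hospitalization:",
      t2.loc[("fu_allcause_hosp", "hra")].round(2).to_dict())
print(pd.read_csv("reports/table3.csv").to_string(index=False))
print(pd.read_csv("reports/figure2.csv").round(2).to_string(index=False))
```

prints

```
                       filter  n_remaining
                 all_patients         2000
ms_dx_baseline_and_prior_year         1923
        continuous_enrollment         1872
                  age_18_plus         1839
HRA odds ratio, all-cause hospitalization: {'odds_ratio': 2.54, 'ci_lower': 1.62, 'ci_upper': 3.99}
          group     mean      se  ci_lower  ci_upper
      hra_group 32193.64 2863.01  25294.95  37364.21
  non_hra_group 19610.21  393.02  18766.40  20322.90
cost_difference 12583.43 2924.04   5408.37  17750.92
                      model  odds_ratio  ci_lower  ci_upper
            start_dmt_naive        4.08      1.90      8.76
     switch_dmt_experienced        1.17      0.59      2.34
discontinue_dmt_experienced        0.98      0.52      1.84
```

The attrition table counts patients surviving each selection filter (the
generator planted violators at known rates). The odds ratio is the adjusted
HRA effect on follow-up all-cause hospitalization — the generator planted an
odds ratio of 2.0, and the estimate's interval covers it. The cost table gives
recycled-prediction adjusted mean follow-up non-DMT costs for the HRA and
non-HRA groups and their difference, with paired bias-corrected bootstrap
intervals; the generator planted a cost ratio of 1.8, and at this cohort size
(99 HRA patients) the difference is recovered with the wide interval the
bootstrap reports. The last table holds the treatment-pattern models: the
generator plants an exposure effect on DMT initiation among naïve patients
(odds ratio 2, estimated noisily here), while adherence archetypes are drawn
independently of exposure, so the switch and discontinuation models estimate a
true null.

A `msrelapse` CLI wraps the same stages
(`simulate | cohort | relapses | patterns | model | run-all | report`):

```bash
msrelapse simulate --n 2000 --seed 7 --out claims/
msrelapse run-all --in claims/ --out reports/ --seed 1
```

## Layout

- `src/msrelapse/config.py` — `StudyConfig`: every window, threshold and code list
- `src/msrelapse/io.py` — typed CSV readers/writers (exact-cents currency)
- `src/msrelapse/relapse.py` — relapse events, episode merging, HRA
- `src/msrelapse/cohort.py` — selection filters, attrition, subgroups
- `src/msrelapse/patterns.py` — PDC, index DMT, switch/discontinue/start
- `src/msrelapse/covariates.py` — Charlson index, symptom/utilization flags, costs
- `src/msrelapse/models.py` — Model/Results estimation layer and bootstrap
- `src/msrelapse/simulate.py` — synthetic claims generator with ground truth
- `src/msrelapse/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
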