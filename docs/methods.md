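# Methods

This note records the modelling assumptions, parameter defaults, numerical
choices and known limitations behind `msrelapse`. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Relapse detection

A candidate relapse event is either an inpatient claim with an MS diagnosis
(prefix `340`) in the primary position — dated at admission, with "at any time
during the hospitalization" read as: any claim line of the stay with MS
primary — or an outpatient/ER visit with an MS code in position 1 or 2
together with a qualifying corticosteroid claim dated in
`[visit, visit + steroid_window_days]` (default 7, inclusive on both ends;
fills *before* the visit never qualify). Corticosteroid identification is by
configurable code lists (generic pharmacy names plus IV J-codes) because no
authoritative list exists for the phenotype; the default covers
methylprednisolone, prednisone, prednisolone, dexamethasone and corticotropin.

Two disambiguation rules prevent double counting:

- one steroid claim qualifies at most one visit — the earliest visit whose
  window contains the fill — so a single fill is not spent on several
  clustered visits;
- multiple qualifying claims on one date collapse to one event per
  (patient, date, type), since encounters are commonly split across claim
  lines.

**Clean-period semantics.** "30 event-free days between the start of separate
relapses" admits two readings. The default `chain` rule starts a new episode
only when an event falls ≥ `clean_period_days` after the *previous event*, so
events at days 0, 25, 50 form one episode even though day 50 is more than 30
days from the episode start; this matches the requirement that the gap contain
*no* qualifying events. The alternative `start_to_start` rule (new episode
when ≥30 days from the episode start) is a config switch for sensitivity
work. Episodes are attributed to the year of their start date, because "two
or more relapses during 2009" references onset.

## Cohort selection

Filters run in a fixed order with attrition logged per step: (a) an MS code
in any diagnosis position in both the baseline (2009) and prior (2008) years;
(b) enrollment spans covering every day of 2009–2010, with an optional
`enrollment_gap_allowance` (default 0 days) for administrative seams;
(c) age ≥18, computed as `baseline_year − birth_year` since claims carry only
birth year. Final membership is an intersection, so filter order changes
attrition counts but never the final cohort. Rule-out diagnoses cannot be
distinguished in this schema; all MS codes are treated as non-rule-out, a
documented divergence from selection flowcharts that exclude them.

Age bins are 18–35, 36–45, 46–55, 56–65, 65+ with "56–65" inclusive of 65 and
"65+" meaning older than 65, resolving the overlap such tables conventionally
print at age 65.

## PDC and treatment patterns

PDC over a period is |union of covered days ∩ period| / |period|, with fills
covering `[fill, fill + days_supply)` and the denominator computed from the
period (365 for 2009), never hard-coded. Overlapping same-drug fills
contribute their union by default; a `stockpiling` switch shifts an
overlapping refill forward to the current run-out, since refill handling is
not standardized. J-code administrations carry no days supply and receive an
imputed `jcode_days_supply` (default 30 — the common dispensing quantum and a
neutral choice for monthly in-office natalizumab).

Treatment-experienced means the *maximum single-drug* PDC reaches the
threshold (default 0.80, inclusive), reading "PDC for any DMT ≥80%" as any one
therapy; a `union_all_dmt` switch offers the union-of-days alternative.
Patients with ABCR therapies (interferon β-1a/β-1b, glatiramer acetate)
evidenced by baseline J-codes are excluded from the experienced subgroup —
J-codes are linked only to generic names and standard dosages, so switches
cannot be followed. The stricter reading (any baseline ABCR J-code excludes)
is used rather than "J-code-only" evidence, since mixed billing leaves the
same ambiguity about the billed therapy.

The index DMT is the drug of the latest baseline claim, with same-date ties
broken by longest days supply, then lexicographically — an arbitrary but
deterministic rule. Discontinuation is the first gap ≥ `gap_days` (default
60) between a supply run-out and the next index-drug claim or the censor date,
dated at the run-out (exposure ends at run-out, not at the gap's end); a final
gap truncated below 60 days by the censor date is censored, not an event.
Switch is the first claim for a different DMT after the index date. Switch and
discontinuation are detected independently — a patient can contribute to both
outcome models — over the flexible follow-up window ending at the censor date
(2010-12-31); for PDC ≥ 80% patients the events necessarily land in the
follow-up year, which is the stated rationale for the 80% bar.

## Covariates and outcomes

The Charlson comorbidity index uses the Deyo ICD-9-CM prefix mapping with the
original category weights; each category counts once per patient regardless of
claim multiplicity, making the score invariant to claim duplication and order.
The full map is configuration so an alternative adaptation drops in. The
MS-symptom flag is an any-match over configurable prefix groups (fatigue,
spasticity, sensory disturbance, pain, ataxia, tremor, bladder/bowel,
cognitive, weakness, depression, optic neuritis); the packaged default is an
approximation, as the exact code set used in the claims literature is not
public.

MS-specific utilization defaults to MS in the primary position for
hospitalizations (consistent with the inpatient relapse rule) and primary or
secondary for ER visits; both rules are configurable because "MS-specific" has
no canonical claims definition. Baseline utilization covariates are measured
in the baseline year, follow-up outcomes in the follow-up year. Costs combine
plan-paid and patient-paid into one amount at ingestion, are stored as exact
integer cents (order-independent sums), and follow-up cost totals exclude DMT
pharmacy fills and medical claims carrying DMT J-codes.

## Estimation

Binary outcomes are fitted by one-record-per-patient logistic regression with
prior-period covariates — the natural reading of a longitudinal design with
exactly one follow-up observation per patient; no random effects. Fits are
IRLS (statsmodels GLM) with deviance tolerance 1e-8 and a 100-iteration cap.
Categorical covariates expand against fixed reference levels (age 18–35, male,
Northeast, employee, FFS). Complete separation raises an explicit error;
quasi-separation on a sparse indicator (huge coefficient, huge SE) is kept and
surfaces as a very wide interval, the conventional presentation. Rank
deficiency raises an error naming the aliased terms; inside subgroup fits the
pipeline drops structurally constant indicator columns instead, since a level
can be legitimately empty there. Odds ratios are exp(β̂) with Wald 95%
intervals exp(β̂ ± 1.96·SE).

Costs use a gamma GLM with log link and Pearson dispersion. The gamma support
excludes zero, so zero follow-up costs are replaced by half the smallest
positive observed cost before fitting (config-switchable to exclusion); the
choice matters little when zeros are rare and is reported as configuration.
Adjusted group means come from recycled predictions (marginal
standardization): predict every patient with exposure forced to 1, then 0,
average each arm over the whole sample, difference the arms. An intercept-only
gamma log-link fit reproduces the sample mean exactly — a canonical-property
check used in the tests.

Uncertainty for the adjusted means and their difference comes from a paired
nonparametric bootstrap with bias-corrected (BC, not accelerated) percentile
intervals: B patient resamples (default 1000), each driving the entire
estimator so the two arms and the difference stay paired;
z₀ = Φ⁻¹(fraction of replicates below the point estimate), interval =
replicate quantiles at Φ(2z₀ ± 1.96). The fraction is clipped to
[1/(B+1), B/(B+1)] to keep z₀ finite; a degenerate replicate distribution
yields a zero-width interval with a warning; estimator failure on more than 1%
of resamples aborts. With a symmetric replicate distribution z₀ ≈ 0 and the BC
interval collapses to the plain percentile interval. Results are
bit-reproducible from the seed.

## Synthetic data

The generator emulates the structure of a commercial claims extract: 2008–2010
enrollment, MS maintenance visits in both qualifying years, ICD-9-CM coded
medical claims across inpatient/outpatient/ER settings, pharmacy fills with
days supply, J-code administrations, and gamma-distributed costs. Defaults are
the study conditions: 77% female; age ~ N(51.5, 11²) truncated to [18, 85];
region/employment/plan mixes matching the target population margins; 68% with
any DMT use; relapse counts from a zero-inflated Poisson (inflation 0.6, rate
0.632) solved so P(count ≥ 2) = 0.053, since only the ≥2 mass drives exposure
classification; planted exposure effects of odds ratio 2.0 on follow-up
hospitalization and ratio 1.8 on follow-up cost, gamma shape 1.5 (dispersion
is otherwise unconstrained, and all calibration tests compare against planted
values, never external estimates).

Planted episodes are spaced ≥45 days apart (more than clean period + steroid
window + 1 = 38), maintenance visits keep a 30-day buffer around relapse
dates, follow-up hospitalizations start after day 35 of the follow-up year so
an MS-primary stay cannot extend a year-end baseline episode, and steroid
fills exist only at planted outpatient relapses when decoy noise is off — together a detectability guarantee: the detector must recover
every planted episode exactly, and does, which is an acceptance check. Decoy
processes (non-MS claims; unlinked steroid fills, default 0.1/patient-year)
reintroduce false-positive pressure so detector specificity is measurable
rather than silently assumed. Adherence archetypes drive DMT fills:
persistent (contiguous supply through the censor date), discontinuer (planted
run-out in follow-up, then silence), switcher (index drug continued plus a new
DMT at a planted follow-up date), sporadic (three scattered fills, PDC < 0.8).
Treatment-naive patients initiate a DMT in follow-up with probability
logit⁻¹(−1.4 + log(2)·HRA) at a planted date, so the naive-start model has a
planted exposure effect too; the adherence archetypes themselves are assigned
independently of exposure, so the switch and discontinuation models estimate a
true null under the default generator.
Follow-up claims are engineered so the pipeline's derived outcome flags and
exact cost sums equal the ledger (outcome claims receive fixed shares of the
planted cost; DMT claims are excluded by code).

What the generator does *not* emulate: realistic ICD-9 code frequencies beyond
the codes the pipeline inspects, claim adjudication and reversals, dose
titration, seasonal patterns, or correlation between demographics and
outcomes beyond the planted coefficient vectors. Passing tests therefore
demonstrate algorithmic correctness and statistical calibration under the
stated generating process, not performance on real claims.

Cohort-filter violators are injected separately with labels (prior-year MS
codes removed; a 15-day enrollment hole; birth year rewritten to age 15), so
attrition counts can be cross-checked against ground truth exactly.

## Problem sizes in the checks

The packaged checks use: 1000 random event sets for the episode-merge oracle;
a noise-free cohort of 2000 for exact detector recovery; 500 random fill sets
for the PDC oracle; 1500 patients (all DMT users) for pattern recovery; 200
record-level cohorts of n = 5000 for Wald coverage and type-I calibration;
B = 500 bootstrap replicates on n = 2000 for the cost-difference recovery;
and a 10-patient hand-built fixture for the end-to-end attrition and record
assembly check. The calibration bands (coverage 93–97%, type-I 3.5–6.5% at
200 replicates) are roughly one binomial standard error wide, so they verify
calibration rather than certify it to high precision.

## Known limitations

- The detector is treatment-based: untreated relapses are invisible, so true
  relapse counts are underestimated by construction; the same holds for the
  phenotype on real data.
- "Qualifying corticosteroid" routes (oral vs IV) are not restricted; the
  code lists are configuration.
- A switch occurring inside a sub-60-day gap counts as both a switch and (if
  the gap later qualifies) a discontinuation; the two outcomes are modelled
  separately and no exclusivity is imposed.
- Costs are totals; no decomposition, inflation adjustment, indirect costs or
  quality-of-life measures.
- No GEE/mixed models, propensity scores, two-part cost models or
  multiple-testing adjustment — out of scope by design.
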