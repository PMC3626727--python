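"""Synthetic commercial-claims data with planted ground truth.

The generator emits the three claims tables the pipeline consumes, together
with a queryable ground-truth ledger: every patient's planted relapse episode
dates and types, HRA status, DMT adherence archetype, planted switch and
run-out dates, planted outcome probabilities and realized outcomes. Defaults
are calibrated to the study population the pipeline targets: 77% female, mean
age 51.5 (SD 11, truncated to 18-85), about 5.3% of patients with two or more
relapses in the baseline year, 68% with any DMT use.

Planted relapses are spaced at least ``min_episode_spacing`` days apart (more
than the clean period plus the steroid window), so with decoy noise switched
off every planted episode is detectable exactly; decoy steroid fills, when
enabled, create the false-positive pressure the detector faces on real data.

Follow-up ER visits and hospitalizations are Bernoulli draws from a logistic
model in the planted covariates (including true HRA); follow-up non-DMT costs
are gamma draws around a log-linear mean. The realized 2010 claims are
engineered so the pipeline's derived outcome flags and exact cost sums match
the ledger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .config import StudyConfig
from .io import DX_COLS, ENROLLMENT_COLUMNS

DMT_DRUGS = ["interferon_beta_1a", "interferon_beta_1b", "glatiramer_acetate", "natalizumab"]
NATALIZUMAB_JCODE = "J2323"
ABCR_JCODES = {"interferon_beta_1a": "J1826", "interferon_beta_1b": "J1830",
               "glatiramer_acetate": "J1595"}
STEROID_PHARM = ["methylprednisolone", "prednisone", "prednisolone", "dexamethasone"]

# comorbidity prefixes planted for the Charlson score (code -> Charlson weight)
COMORBIDITY_POOL = [("428.0", 1), ("250.00", 1), ("491.20", 1),
                    ("410.71", 1), ("714.0", 1), ("585.9", 2)]
SYMPTOM_POOL = ["780.79", "729.1", "311", "782.0", "596.54", "780.71"]
DECOY_DX_POOL = ["786.50", "723.1", "401.9", "V70.0"]


class GenerationError(RuntimeError):
    """Raised when planted events cannot fit the requested constraints."""


@dataclass
class SimConfig:
    """Parameters of the synthetic population; defaults are the study conditions."""

    n_patients: int = 1000
    seed: int = 0
    female_frac: float = 0.77
    age_mean: float = 51.5
    age_sd: float = 11.0
    age_min: int = 18
    age_max: int = 85
    region_probs: dict = field(default_factory=lambda: {
        "northeast": 0.127, "north_central": 0.323, "south": 0.339,
        "west": 0.209, "unknown": 0.002})
    employee_frac: float = 0.565
    plan_probs: dict = field(default_factory=lambda: {
        "ffs": 0.813, "non_ffs": 0.164, "missing": 0.023})
    # zero-inflated Poisson relapse counts; these defaults give P(count>=2)=0.053
    zero_inflation: float = 0.6
    relapse_rate: float = 0.632
    max_relapses: int = 6
    min_episode_spacing: int = 45
    inpatient_relapse_prob: float = 0.2
    er_relapse_visit_prob: float = 0.3   # outpatient relapse visit billed as ER
    ms_secondary_dx_prob: float = 0.3    # MS in dx2 rather than dx1 on relapse visits
    dmt_use_frac: float = 0.68
    archetype_probs: dict = field(default_factory=lambda: {
        "persistent": 0.50, "discontinuer": 0.20, "switcher": 0.15, "sporadic": 0.15})
    abcr_jcode_frac: float = 0.02        # DMT users billed via ABCR J-codes only
    symptom_prob: float = 0.70
    comorbidity_rate: float = 0.55       # Poisson mean of planted Charlson categories
    baseline_er_prob: float = 0.23
    baseline_hosp_prob: float = 0.12
    er_coeffs: dict = field(default_factory=lambda: {
        "const": -1.45, "hra": math.log(1.4), "any_ms_symptom": 0.40,
        "baseline_er": 0.90, "baseline_hosp": 0.30, "cci": 0.12})
    hosp_coeffs: dict = field(default_factory=lambda: {
        "const": -2.30, "hra": math.log(2.0), "any_ms_symptom": 0.35,
        "baseline_er": 0.55, "baseline_hosp": 0.90, "cci": 0.19})
    cost_coeffs: dict = field(default_factory=lambda: {
        "const": math.log(13500.0), "hra": math.log(1.8), "any_ms_symptom": 0.25,
        "baseline_er": 0.15, "baseline_hosp": 0.50, "cci": 0.10})
    # follow-up DMT initiation among treatment-naive patients
    start_coeffs: dict = field(default_factory=lambda: {
        "const": -1.4, "hra": math.log(2.0)})
    gamma_shape: float = 1.5
    ms_dx_er_prob: float = 0.6           # follow-up ER claim carries an MS code
    ms_dx_hosp_prob: float = 0.5
    decoy_nonms_rate: float = 1.0        # baseline-year non-MS claims per patient
    decoy_steroid_rate: float = 0.10     # baseline-year unlinked steroid fills

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be at least 1")
        for name, probs in (("region_probs", self.region_probs),
                            ("plan_probs", self.plan_probs),
                            ("archetype_probs", self.archetype_probs)):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
            if any(not 0 <= p <= 1 for p in probs.values()):
                raise ValueError(f"{name} entries must lie in [0, 1]")

    def prob_hra(self) -> float:
        """P(planted relapse count >= 2) under the zero-inflated Poisson law."""
        lam = self.relapse_rate
        return (1 - self.zero_inflation) * (1 - math.exp(-lam) * (1 + lam))


@dataclass
class GroundTruth:
    """Planted per-patient latent state plus the global coefficient vectors."""

    patients: pd.DataFrame
    coefficients: dict

    def to_csv(self, path) -> None:
        self.patients.to_csv(path, index=False, lineterminator="\n")


def _spaced_days(rng, n: int, n_days: int, spacing: int, pid: str) -> list[int]:
    """n sorted day offsets in [0, n_days) with pairwise gaps >= spacing,
    uniform over all feasible placements (gap-deflation construction)."""
    m = n_days - (n - 1) * spacing
    if n > 0 and m < n:
        raise GenerationError(f"patient {pid}: cannot place {n} episodes "
                              f"{spacing} days apart inside {n_days} days")
    if n == 0:
        return []
    u = np.sort(rng.choice(m, size=n, replace=False))
    return [int(u[i] + i * spacing) for i in range(n)]


def _cents(x: float) -> int:
    return max(int(round(x * 100)), 0)


def generate(sim: SimConfig, config: StudyConfig | None = None
             ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (medical, pharmacy, enrollment, ground_truth).

    Identical ``sim.seed`` yields identical output. Every patient is enrolled
    continuously 2008-2010 with MS diagnoses in both the prior and baseline
    years; cohort-filter violators are added separately via
    :func:`inject_violators`.
    """
    config = config or StudyConfig()
    rng = np.random.default_rng(sim.seed)
    y0 = date(config.baseline_year, 1, 1)
    prior0 = date(config.prior_year, 1, 1)
    fu0 = date(config.followup_year, 1, 1)
    censor = config.censor_date

    med, pharm, enrol, truth = [], [], [], []

    def add_med(pid, start, end, setting, dx, procs, cents):
        dx = (list(dx) + [""] * 4)[:4]
        med.append((pid, start, end, setting, *dx, procs, cents))

    regions = list(sim.region_probs)
    region_p = [sim.region_probs[r] for r in regions]
    plans = list(sim.plan_probs)
    plan_p = [sim.plan_probs[p] for p in plans]
    archetypes = list(sim.archetype_probs)
    arch_p = [sim.archetype_probs[a] for a in archetypes]

    for i in range(sim.n_patients):
        pid = f"P{i:06d}"
        sex = "female" if rng.random() < sim.female_frac else "male"
        while True:
            age = int(round(rng.normal(sim.age_mean, sim.age_sd)))
            if sim.age_min <= age <= sim.age_max:
                break
        region = regions[rng.choice(len(regions), p=region_p)]
        employment = "employee" if rng.random() < sim.employee_frac else "other"
        plan = plans[rng.choice(len(plans), p=plan_p)]
        birth_year = config.baseline_year - age
        enrol.append((pid, date(config.prior_year, 1, 1), date(config.followup_year, 12, 31),
                      birth_year, sex, region, employment, plan))

        # ---- planted relapses in the baseline year --------------------------
        n_rel = 0 if rng.random() < sim.zero_inflation else int(rng.poisson(sim.relapse_rate))
        n_rel = min(n_rel, sim.max_relapses)
        rel_days = _spaced_days(rng, n_rel, 365, sim.min_episode_spacing, pid)
        rel_dates, rel_types = [], []
        er_relapse_visit = False
        for d in rel_days:
            rd = y0 + timedelta(days=d)
            rel_dates.append(rd)
            if rng.random() < sim.inpatient_relapse_prob:
                rel_types.append("inpatient_ms_primary")
                add_med(pid, rd, rd + timedelta(days=3), "inpatient", ["340"],
                        "", _cents(rng.gamma(2.0, 4000.0)))
            else:
                rel_types.append("outpatient_ms_plus_steroid")
                setting = "er" if rng.random() < sim.er_relapse_visit_prob else "outpatient"
                er_relapse_visit = er_relapse_visit or setting == "er"
                if rng.random() < sim.ms_secondary_dx_prob:
                    dx = ["367.4", "340"]
                else:
                    dx = ["340"]
                add_med(pid, rd, rd, setting, dx, "", _cents(rng.gamma(2.0, 150.0)))
                lag = int(rng.integers(0, config.steroid_window_days + 1))
                drug = STEROID_PHARM[rng.choice(len(STEROID_PHARM))]
                pharm.append((pid, rd + timedelta(days=lag), drug, 7,
                              _cents(rng.gamma(2.0, 12.0))))
        true_hra = int(n_rel >= config.hra_threshold)

        def clear_of_relapses(day: int) -> bool:
            return all(abs(day - r) > config.clean_period_days for r in rel_days)

        # ---- maintenance MS visits (cohort-qualifying diagnoses) ------------
        for base, need_clear in ((prior0, False), (y0, True)):
            placed = 0
            while placed < 2:
                day = int(rng.integers(0, 365))
                if need_clear and not clear_of_relapses(day):
                    continue
                add_med(pid, base + timedelta(days=day), base + timedelta(days=day),
                        "outpatient", ["340"], "", _cents(rng.gamma(2.0, 100.0)))
                placed += 1

        # ---- planted comorbidities and symptoms ------------------------------
        k = min(int(rng.poisson(sim.comorbidity_rate)), len(COMORBIDITY_POOL))
        cci_true = 0
        for j in rng.choice(len(COMORBIDITY_POOL), size=k, replace=False):
            code, w = COMORBIDITY_POOL[j]
            cci_true += w
            add_med(pid, y0 + timedelta(days=int(rng.integers(0, 365))), None,
                    "outpatient", [code], "", _cents(rng.gamma(2.0, 75.0)))
        symptom = int(rng.random() < sim.symptom_prob)
        if symptom:
            code = SYMPTOM_POOL[rng.choice(len(SYMPTOM_POOL))]
            add_med(pid, y0 + timedelta(days=int(rng.integers(0, 365))), None,
                    "outpatient", [code], "", _cents(rng.gamma(2.0, 90.0)))

        # ---- planted baseline utilization ------------------------------------
        base_er = int(rng.random() < sim.baseline_er_prob)
        if base_er:
            add_med(pid, y0 + timedelta(days=int(rng.integers(0, 365))), None,
                    "er", ["786.50"], "", _cents(rng.gamma(2.0, 400.0)))
        base_hosp = int(rng.random() < sim.baseline_hosp_prob)
        if base_hosp:
            d = y0 + timedelta(days=int(rng.integers(0, 362)))
            add_med(pid, d, d + timedelta(days=3), "inpatient", ["486"], "",
                    _cents(rng.gamma(2.0, 4500.0)))
        # what the pipeline will derive (planted flag OR a relapse claim of
        # that setting) — outcomes are drawn from these derived values
        base_er_true = int(base_er or er_relapse_visit)
        base_hosp_true = int(base_hosp or ("inpatient_ms_primary" in rel_types))

        # ---- DMT exposure -----------------------------------------------------
        dmt_user = int(rng.random() < sim.dmt_use_frac)
        archetype, index_dmt, switch_date, disc_runout = "", "", None, None
        if dmt_user:
            if rng.random() < sim.abcr_jcode_frac:
                archetype = "abcr_jcode"
                drug = DMT_DRUGS[rng.choice(3)]  # an ABCR therapy
                index_dmt = drug
                d = y0 + timedelta(days=int(rng.integers(0, 40)))
                while d <= date(config.baseline_year, 12, 31):
                    add_med(pid, d, d, "outpatient", [], ABCR_JCODES[drug],
                            _cents(rng.gamma(2.0, 1200.0)))
                    d += timedelta(days=28)
            else:
                archetype = archetypes[rng.choice(len(archetypes), p=arch_p)]
                drug = DMT_DRUGS[rng.choice(len(DMT_DRUGS))]
                index_dmt = drug
                start = y0 + timedelta(days=int(rng.integers(0, 10)))

                def emit_dmt(drug_, day, supply=30):
                    if drug_ == "natalizumab":
                        add_med(pid, day, day, "outpatient", [], NATALIZUMAB_JCODE,
                                _cents(rng.gamma(2.0, 1500.0)))
                    else:
                        pharm.append((pid, day, drug_, supply,
                                      _cents(rng.gamma(2.0, 1250.0))))

                step = 28 if drug == "natalizumab" else 30
                if archetype == "persistent":
                    d = start
                    while d <= censor:
                        emit_dmt(drug, d)
                        d += timedelta(days=step)
                elif archetype == "discontinuer":
                    n_fills = int(rng.integers(13, 21))
                    d = start
                    for _ in range(n_fills):
                        emit_dmt(drug, d)
                        d += timedelta(days=step)
                    # last fill plus its 30-day (imputed or dispensed) supply
                    disc_runout = d - timedelta(days=step) + timedelta(days=30)
                elif archetype == "switcher":
                    d = start
                    while d <= censor:
                        emit_dmt(drug, d)
                        d += timedelta(days=step)
                    new = DMT_DRUGS[rng.choice(len(DMT_DRUGS))]
                    while new == drug:
                        new = DMT_DRUGS[rng.choice(len(DMT_DRUGS))]
                    switch_date = fu0 + timedelta(days=int(rng.integers(30, 270)))
                    d = switch_date
                    nstep = 28 if new == "natalizumab" else 30
                    while d <= censor:
                        emit_dmt(new, d)
                        d += timedelta(days=nstep)
                else:  # sporadic
                    for _ in range(3):
                        emit_dmt(drug, y0 + timedelta(days=int(rng.integers(0, 335))))

        # ---- planted follow-up initiation for treatment-naive patients --------
        init_date = None
        if not dmt_user:
            eta_start = sim.start_coeffs["const"] + sim.start_coeffs["hra"] * true_hra
            if rng.random() < 1.0 / (1.0 + math.exp(-eta_start)):
                init_date = fu0 + timedelta(days=int(rng.integers(0, 330)))
                new_drug = DMT_DRUGS[rng.choice(len(DMT_DRUGS))]
                d = init_date
                for _ in range(3):
                    if d > censor:
                        break
                    if new_drug == "natalizumab":
                        add_med(pid, d, d, "outpatient", [], NATALIZUMAB_JCODE,
                                _cents(rng.gamma(2.0, 1500.0)))
                        d += timedelta(days=28)
                    else:
                        pharm.append((pid, d, new_drug, 30,
                                      _cents(rng.gamma(2.0, 1250.0))))
                        d += timedelta(days=30)

        # ---- decoy noise ------------------------------------------------------
        for _ in range(rng.poisson(sim.decoy_nonms_rate)):
            code = DECOY_DX_POOL[rng.choice(len(DECOY_DX_POOL))]
            add_med(pid, y0 + timedelta(days=int(rng.integers(0, 365))), None,
                    "outpatient", [code], "", _cents(rng.gamma(2.0, 60.0)))
        for _ in range(rng.poisson(sim.decoy_steroid_rate)):
            drugname = STEROID_PHARM[rng.choice(len(STEROID_PHARM))]
            pharm.append((pid, y0 + timedelta(days=int(rng.integers(0, 365))),
                          drugname, 10, _cents(rng.gamma(2.0, 10.0))))

        # ---- follow-up outcomes -----------------------------------------------
        x = {"hra": true_hra, "any_ms_symptom": symptom, "baseline_er": base_er_true,
             "baseline_hosp": base_hosp_true, "cci": cci_true}

        def eta(coeffs):
            return coeffs["const"] + sum(coeffs[k] * v for k, v in x.items())

        p_er = 1.0 / (1.0 + math.exp(-eta(sim.er_coeffs)))
        p_hosp = 1.0 / (1.0 + math.exp(-eta(sim.hosp_coeffs)))
        fu_er = int(rng.random() < p_er)
        fu_hosp = int(rng.random() < p_hosp)
        expected_cost = math.exp(eta(sim.cost_coeffs))
        cost_cents = max(_cents(rng.gamma(sim.gamma_shape, expected_cost / sim.gamma_shape)), 100)

        remaining = cost_cents
        if fu_er:
            c = int(0.15 * cost_cents)
            dx1 = "340" if rng.random() < sim.ms_dx_er_prob else "786.50"
            add_med(pid, fu0 + timedelta(days=int(rng.integers(0, 365))), None,
                    "er", [dx1], "", c)
            remaining -= c
        if fu_hosp:
            c = int(0.40 * cost_cents)
            dx1 = "340" if rng.random() < sim.ms_dx_hosp_prob else "486"
            # start after the clean period of any year-end baseline episode so
            # an MS-primary stay cannot extend a planted 2009 episode
            d = fu0 + timedelta(days=int(rng.integers(35, 362)))
            add_med(pid, d, d + timedelta(days=3), "inpatient", [dx1], "", c)
            remaining -= c
        add_med(pid, fu0 + timedelta(days=int(rng.integers(0, 365))), None,
                "outpatient", ["340"], "", remaining)

        truth.append((pid, sex, age, region, employment, plan, n_rel,
                      ";".join(d.isoformat() for d in rel_dates),
                      ";".join(rel_types), true_hra, cci_true, symptom,
                      base_er_true, base_hosp_true, dmt_user, archetype, index_dmt,
                      switch_date.isoformat() if switch_date else "",
                      disc_runout.isoformat() if disc_runout else "",
                      init_date.isoformat() if init_date else "",
                      p_er, p_hosp, expected_cost, fu_er, fu_hosp, cost_cents, ""))

    medical = pd.DataFrame(med, columns=["patient_id", "service_start", "service_end",
                                         "setting", *DX_COLS, "proc_codes", "paid_cents"])
    medical["service_end"] = [e if e is not None else s
                              for s, e in zip(medical["service_start"], medical["service_end"])]
    medical["service_start"] = pd.to_datetime(medical["service_start"])
    medical["service_end"] = pd.to_datetime(medical["service_end"])
    pharmacy = pd.DataFrame(pharm, columns=["patient_id", "fill_date", "drug_code",
                                            "days_supply", "paid_cents"])
    pharmacy["fill_date"] = pd.to_datetime(pharmacy["fill_date"])
    if pharmacy.empty:
        pharmacy = pharmacy.astype({"fill_date": "datetime64[ns]", "days_supply": "int64",
                                    "paid_cents": "int64"})
    enrollment = pd.DataFrame(enrol, columns=ENROLLMENT_COLUMNS)
    enrollment["span_start"] = pd.to_datetime(enrollment["span_start"])
    enrollment["span_end"] = pd.to_datetime(enrollment["span_end"])

    gt = GroundTruth(
        patients=pd.DataFrame(truth, columns=[
            "patient_id", "sex", "age", "region", "employment", "plan_type",
            "n_relapses", "relapse_dates", "relapse_types", "true_hra", "cci_true",
            "any_ms_symptom_true", "baseline_er_true", "baseline_hosp_true",
            "dmt_user", "archetype", "index_dmt", "switch_date", "disc_runout",
            "init_date", "p_fu_er", "p_fu_hosp", "expected_cost", "fu_er", "fu_hosp",
            "cost_cents", "violation"]),
        coefficients={"er": dict(sim.er_coeffs), "hosp": dict(sim.hosp_coeffs),
                      "cost": dict(sim.cost_coeffs), "gamma_shape": sim.gamma_shape})
    return medical, pharmacy, enrollment, gt


def noise_free(sim: SimConfig) -> SimConfig:
    """Copy of ``sim`` with every decoy-noise process switched off."""
    import dataclasses
    return dataclasses.replace(sim, decoy_nonms_rate=0.0, decoy_steroid_rate=0.0)


# ---------------------------------------------------------------------------
# cohort-filter violators

VIOLATION_KINDS = ("drop_prior_dx", "enrollment_gap", "underage")


def inject_violators(medical: pd.DataFrame, pharmacy: pd.DataFrame,
                     enrollment: pd.DataFrame, ground_truth: GroundTruth,
                     rates: dict, seed: int = 0, config: StudyConfig | None = None):
    """Degrade a labelled fraction of patients so each cohort filter fires.

    ``rates`` maps violation kind to a fraction in [0, 1]: ``drop_prior_dx``
    removes all prior-year MS-coded claims, ``enrollment_gap`` opens a 15-day
    hole in follow-up-year enrollment, ``underage`` rewrites birth year to age
    15. Ground-truth rows record each patient's violations.
    """
    config = config or StudyConfig()
    unknown = set(rates) - set(VIOLATION_KINDS)
    if unknown:
        raise ValueError(f"unknown violation kinds: {sorted(unknown)}")
    if any(not 0.0 <= r <= 1.0 for r in rates.values()):
        raise ValueError("violation rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    medical = medical.copy()
    enrollment = enrollment.copy()
    gt = ground_truth.patients.copy()
    pids = gt["patient_id"].to_numpy()
    chosen = {kind: set(pids[rng.random(len(pids)) < rates.get(kind, 0.0)])
              for kind in VIOLATION_KINDS}

    if chosen["drop_prior_dx"]:
        lo = pd.Timestamp(date(config.prior_year, 1, 1))
        hi = pd.Timestamp(date(config.prior_year, 12, 31))
        is_ms = pd.Series(False, index=medical.index)
        for c in DX_COLS:
            is_ms |= medical[c].str.startswith(config.ms_dx_prefix)
        drop = (medical["patient_id"].isin(chosen["drop_prior_dx"]) & is_ms
                & (medical["service_start"] >= lo) & (medical["service_start"] <= hi))
        medical = medical[~drop].reset_index(drop=True)

    if chosen["enrollment_gap"]:
        gap_start = pd.Timestamp(date(config.followup_year, 6, 1))
        gap_end = pd.Timestamp(date(config.followup_year, 6, 15))
        keep = enrollment[~enrollment["patient_id"].isin(chosen["enrollment_gap"])]
        split = []
        for _, row in enrollment[enrollment["patient_id"].isin(chosen["enrollment_gap"])].iterrows():
            a = row.copy()
            a["span_end"] = gap_start - pd.Timedelta(days=1)
            b = row.copy()
            b["span_start"] = gap_end + pd.Timedelta(days=1)
            split.extend([a, b])
        enrollment = pd.concat([keep, pd.DataFrame(split)], ignore_index=True)
        enrollment = enrollment.sort_values(["patient_id", "span_start"]).reset_index(drop=True)

    if chosen["underage"]:
        mask = enrollment["patient_id"].isin(chosen["underage"])
        enrollment.loc[mask, "birth_year"] = config.baseline_year - 15

    labels = []
    for pid in gt["patient_id"]:
        kinds = [k for k in VIOLATION_KINDS if pid in chosen[k]]
        labels.append(";".join(kinds))
    gt["violation"] = labels
    return medical, pharmacy, enrollment, GroundTruth(patients=gt,
                                                      coefficients=ground_truth.coefficients)


# ---------------------------------------------------------------------------
# record-level generator for estimation calibration

def simulate_analysis_records(n: int, seed: int, or_hra: float = 2.0,
                              cost_ratio: float = 1.8, gamma_shape: float = 1.5,
                              hra_prev: float = 0.053
                              ) -> tuple[pd.DataFrame, dict]:
    """Patient-record table drawn directly from the outcome models.

    Skips the claims layer: covariates come from the study-population margins,
    ``fu_allcause_hosp`` from a logistic model with exposure log-odds
    ``log(or_hra)``, and ``fu_cost_nondmt`` from a gamma around a log-linear
    mean with exposure effect ``log(cost_ratio)``. Returns the records plus a
    truth dict with the planted coefficients and the planted marginal
    (recycled-prediction) cost difference on this sample.
    """
    rng = np.random.default_rng(seed)
    hra = (rng.random(n) < hra_prev).astype(int)
    age = np.clip(np.round(rng.normal(51.5, 11.0, n)), 18, 85).astype(int)
    from .covariates import age_group
    records = pd.DataFrame({
        "hra": hra,
        "age": age,
        "age_group": [age_group(a) for a in age],
        "sex": np.where(rng.random(n) < 0.77, "female", "male"),
        "region": np.array(["northeast", "north_central", "south", "west"])[
            rng.choice(4, size=n, p=[0.128, 0.323, 0.339, 0.210])],
        "employment": np.where(rng.random(n) < 0.565, "employee", "other"),
        "plan_type": np.array(["ffs", "non_ffs", "missing"])[
            rng.choice(3, size=n, p=[0.813, 0.164, 0.023])],
        "cci": rng.poisson(0.6, n).astype(float),
        "any_ms_symptom": (rng.random(n) < 0.69).astype(int),
        "any_dmt_use": (rng.random(n) < 0.68).astype(int),
        "baseline_er": (rng.random(n) < 0.23).astype(int),
        "baseline_hosp": (rng.random(n) < 0.12).astype(int),
    })
    b_hosp = {"const": -2.30, "hra": math.log(or_hra), "any_ms_symptom": 0.35,
              "baseline_er": 0.55, "baseline_hosp": 0.90, "cci": 0.19}
    b_cost = {"const": math.log(13500.0), "hra": math.log(cost_ratio),
              "any_ms_symptom": 0.25, "baseline_er": 0.15, "baseline_hosp": 0.50,
              "cci": 0.10}

    def lin(b):
        eta = np.full(n, b["const"])
        for k, v in b.items():
            if k != "const":
                eta += v * records[k].to_numpy(float)
        return eta

    eta_h = lin(b_hosp)
    records["fu_allcause_hosp"] = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta_h))).astype(int)
    eta_c = lin(b_cost)
    mu = np.exp(eta_c)
    records["fu_cost_nondmt"] = rng.gamma(gamma_shape, mu / gamma_shape)

    # planted marginal difference: force exposure both ways for everyone
    base = eta_c - b_cost["hra"] * records["hra"].to_numpy(float)
    diff = float(np.mean(np.exp(base + b_cost["hra"])) - np.mean(np.exp(base)))
    truth = {"or_hra": or_hra, "hosp_coeffs": b_hosp, "cost_coeffs": b_cost,
             "marginal_cost_difference": diff, "gamma_shape": gamma_shape}
    return records, truth
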