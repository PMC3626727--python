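"""Study configuration.

Every numeric threshold, window, and code list used by the pipeline lives in a
single :class:`StudyConfig` object so that variants of the analysis (e.g. the
sensitivity cohort, alternative episode-merge semantics, alternative MS-specific
diagnosis-position rules) are configuration changes rather than code changes.
Configs round-trip through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates its contract."""


# Disease-modifying therapies of the 2009-2010 era. Pharmacy claims identify
# drugs by normalized generic-name codes; in-office administrations appear as
# HCPCS J-codes on medical claims.
DEFAULT_DMT_CODES: dict[str, dict[str, list[str]]] = {
    "interferon_beta_1a": {"pharmacy": ["interferon_beta_1a"], "jcode": ["J1826", "Q3025", "Q3026"]},
    "interferon_beta_1b": {"pharmacy": ["interferon_beta_1b"], "jcode": ["J1830"]},
    "glatiramer_acetate": {"pharmacy": ["glatiramer_acetate"], "jcode": ["J1595"]},
    "natalizumab": {"pharmacy": ["natalizumab"], "jcode": ["J2323"]},
}

# ABCR = the self-injectable platform therapies (Avonex/Rebif = interferon
# beta-1a, Betaseron = interferon beta-1b, Copaxone = glatiramer acetate).
# Patients whose ABCR use is billed through J-codes cannot be followed for
# switches and are excluded from the treatment-experienced cohort.
ABCR_DRUGS: tuple[str, ...] = (
    "interferon_beta_1a",
    "interferon_beta_1b",
    "glatiramer_acetate",
)

# Qualifying corticosteroids for the outpatient relapse rule: pharmacy codes
# (normalized generic names) plus IV-administration J-codes.
DEFAULT_STEROID_CODES: dict[str, list[str]] = {
    "pharmacy": [
        "methylprednisolone",
        "prednisone",
        "prednisolone",
        "dexamethasone",
        "corticotropin",
    ],
    "jcode": ["J2920", "J2930", "J1100", "J0800", "J7509", "J7510"],
}

# Deyo ICD-9-CM adaptation of the Charlson comorbidity categories, keyed by
# code prefix (match = str.startswith). Trimmed to the leading prefixes per
# category; the full map is configuration, so an alternative mapping (e.g.
# Quan) drops in via YAML.
DEFAULT_CCI_MAP: dict[str, str] = {
    "410": "myocardial_infarction", "412": "myocardial_infarction",
    "428": "congestive_heart_failure",
    "443.9": "peripheral_vascular", "441": "peripheral_vascular", "785.4": "peripheral_vascular",
    "430": "cerebrovascular", "431": "cerebrovascular", "432": "cerebrovascular",
    "433": "cerebrovascular", "434": "cerebrovascular", "435": "cerebrovascular",
    "436": "cerebrovascular", "437": "cerebrovascular", "438": "cerebrovascular",
    "290": "dementia",
    "490": "chronic_pulmonary", "491": "chronic_pulmonary", "492": "chronic_pulmonary",
    "493": "chronic_pulmonary", "494": "chronic_pulmonary", "495": "chronic_pulmonary",
    "496": "chronic_pulmonary",
    "710.0": "rheumatologic", "710.1": "rheumatologic", "710.4": "rheumatologic",
    "714.0": "rheumatologic", "714.1": "rheumatologic", "714.2": "rheumatologic", "725": "rheumatologic",
    "531": "peptic_ulcer", "532": "peptic_ulcer", "533": "peptic_ulcer", "534": "peptic_ulcer",
    "571.2": "mild_liver", "571.4": "mild_liver", "571.5": "mild_liver", "571.6": "mild_liver",
    "250.0": "diabetes", "250.1": "diabetes", "250.2": "diabetes", "250.3": "diabetes",
    "250.7": "diabetes",
    "250.4": "diabetes_complications", "250.5": "diabetes_complications", "250.6": "diabetes_complications",
    "344.1": "hemiplegia", "342": "hemiplegia",
    "582": "renal", "583": "renal", "585": "renal", "586": "renal", "588": "renal",
    "140": "malignancy", "150": "malignancy", "151": "malignancy", "162": "malignancy",
    "170": "malignancy", "174": "malignancy", "185": "malignancy", "200": "malignancy",
    "203": "malignancy", "204": "malignancy", "205": "malignancy", "208": "malignancy",
    "572.2": "severe_liver", "572.3": "severe_liver", "572.4": "severe_liver", "572.8": "severe_liver",
    "196": "metastatic_tumor", "197": "metastatic_tumor", "198": "metastatic_tumor",
    "199.0": "metastatic_tumor", "199.1": "metastatic_tumor",
    "042": "aids", "043": "aids", "044": "aids",
}

# Original Charlson weights per category.
DEFAULT_CCI_WEIGHTS: dict[str, int] = {
    "myocardial_infarction": 1, "congestive_heart_failure": 1, "peripheral_vascular": 1,
    "cerebrovascular": 1, "dementia": 1, "chronic_pulmonary": 1, "rheumatologic": 1,
    "peptic_ulcer": 1, "mild_liver": 1, "diabetes": 1,
    "diabetes_complications": 2, "hemiplegia": 2, "renal": 2, "malignancy": 2,
    "severe_liver": 3, "metastatic_tumor": 6, "aids": 6,
}

# Approximate ICD-9-CM prefixes for the classical MS symptom clusters
# (fatigue, spasticity, sensory disturbance, pain, ataxia, tremor, bladder and
# bowel dysfunction, cognitive effects, weakness, depression, optic neuritis).
# The exact symptom code set used in the source literature is not public; this
# map is a documented approximation and is fully overridable.
DEFAULT_SYMPTOM_CODES: dict[str, list[str]] = {
    "fatigue": ["780.7"],
    "spasticity": ["728.85", "781.0"],
    "sensory": ["782.0"],
    "pain": ["338", "729.1", "724"],
    "ataxia": ["781.3"],
    "tremor": ["333.1"],
    "bladder": ["596.5", "788.3"],
    "bowel": ["564.0", "787.6"],
    "cognitive": ["294.9", "310"],
    "weakness": ["728.87", "780.79"],
    "depression": ["296", "311"],
    "optic_neuritis": ["377.3"],
}

SETTINGS = ("inpatient", "outpatient", "er")
SEXES = ("male", "female")
REGIONS = ("northeast", "north_central", "south", "west", "unknown")
EMPLOYMENTS = ("employee", "other")
PLAN_TYPES = ("ffs", "non_ffs", "missing")


def _parse_date(value) -> date:
    if isinstance(value, date):
        return value
    return date.fromisoformat(str(value))


@dataclass
class StudyConfig:
    """All tunable parameters of the analysis.

    Windows follow the conventions stated on each operation; dates are
    ISO-8601 in files. ``episode_rule`` selects the clean-period semantics:
    ``"chain"`` (default) starts a new episode only when an event falls at
    least ``clean_period_days`` after the *previous event*; ``"start_to_start"``
    measures from the episode start instead.
    """

    baseline_year: int = 2009
    prior_year: int = 2008
    followup_year: int = 2010
    censor_date: date = date(2010, 12, 31)
    ms_dx_prefix: str = "340"
    clean_period_days: int = 30
    steroid_window_days: int = 7
    hra_threshold: int = 2
    pdc_threshold: float = 0.80
    gap_days: int = 60
    min_age: int = 18
    dmt_codes: dict = field(default_factory=lambda: {k: {s: list(v) for s, v in d.items()} for k, d in DEFAULT_DMT_CODES.items()})
    steroid_codes: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_STEROID_CODES.items()})
    cci_map: dict = field(default_factory=lambda: dict(DEFAULT_CCI_MAP))
    cci_weights: dict = field(default_factory=lambda: dict(DEFAULT_CCI_WEIGHTS))
    symptom_codes: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_SYMPTOM_CODES.items()})
    ms_er_dx_positions: str = "primary_or_secondary"   # MS-specific ER rule
    ms_hosp_dx_positions: str = "primary_only"          # MS-specific hospitalization rule
    episode_rule: str = "chain"
    pdc_rule: str = "max_single_drug"   # or "union_all_dmt"
    stockpiling: bool = False           # shift-forward refill handling for PDC
    jcode_days_supply: int = 30         # imputed supply for J-code administrations
    enrollment_gap_allowance: int = 0   # administrative seam tolerance, days
    sensitivity_mode: bool = False      # all DMT-exposed regardless of PDC
    zero_cost_policy: str = "half_min_positive"  # or "exclude"
    bootstrap_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        self.censor_date = _parse_date(self.censor_date)
        for name in ("clean_period_days", "steroid_window_days", "hra_threshold",
                     "gap_days", "min_age", "jcode_days_supply"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if not (0.0 < self.pdc_threshold <= 1.0):
            raise ConfigError("pdc_threshold must lie in (0, 1]")
        if self.censor_date.year != self.followup_year:
            raise ConfigError("censor_date must fall inside followup_year")
        if self.episode_rule not in ("chain", "start_to_start"):
            raise ConfigError(f"unknown episode_rule {self.episode_rule!r}")
        if self.pdc_rule not in ("max_single_drug", "union_all_dmt"):
            raise ConfigError(f"unknown pdc_rule {self.pdc_rule!r}")
        for attr in ("ms_er_dx_positions", "ms_hosp_dx_positions"):
            if getattr(self, attr) not in ("primary_only", "primary_or_secondary"):
                raise ConfigError(f"{attr} must be primary_only or primary_or_secondary")

    # -- derived code sets ---------------------------------------------------

    def dmt_pharmacy_codes(self, drug: str | None = None) -> set[str]:
        drugs = [drug] if drug else list(self.dmt_codes)
        return {c for d in drugs for c in self.dmt_codes[d].get("pharmacy", [])}

    def dmt_jcodes(self, drug: str | None = None) -> set[str]:
        drugs = [drug] if drug else list(self.dmt_codes)
        return {c for d in drugs for c in self.dmt_codes[d].get("jcode", [])}

    def abcr_jcodes(self) -> set[str]:
        return {c for d in ABCR_DRUGS if d in self.dmt_codes
                for c in self.dmt_codes[d].get("jcode", [])}

    def baseline_window(self) -> tuple[date, date]:
        return date(self.baseline_year, 1, 1), date(self.baseline_year, 12, 31)

    def prior_window(self) -> tuple[date, date]:
        return date(self.prior_year, 1, 1), date(self.prior_year, 12, 31)

    def followup_window(self) -> tuple[date, date]:
        return date(self.followup_year, 1, 1), min(date(self.followup_year, 12, 31), self.censor_date)

    # -- YAML round-trip -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["censor_date"] = self.censor_date.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
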