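"""Config-driven end-to-end orchestration.

``run_pipeline`` sequences the full analysis over a claims directory: cohort
selection → relapse detection and HRA classification → PDC and subgroups →
treatment-pattern detection → patient records → bivariate table, adjusted
odds-ratio models, gamma cost model with recycled predictions and a paired
bias-corrected bootstrap, and the treatment-pattern odds ratios. Every report
row is computed by the upstream modules; this layer only wires them together,
logs attrition, and writes CSVs plus a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import covariates as cov_mod
from . import io as io_mod
from . import models as models_mod
from . import patterns as patterns_mod
from . import relapse as relapse_mod
from .config import StudyConfig

logger = logging.getLogger(__name__)

MODEL_COVARIATES = models_mod.DEFAULT_COVARIATES  # Table-2 covariate set
SUBGROUP_COVARIATES = [c for c in MODEL_COVARIATES if c != "any_dmt_use"]


@dataclass
class RunManifest:
    """Everything needed to reproduce a run byte-for-byte."""

    config: dict
    input_digests: dict
    stage_seconds: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    seed: int = 0

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs remain on disk."""


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _or_rows(fit: models_mod.GlmResults, outcome: str) -> pd.DataFrame:
    tab = fit.odds_ratios()
    tab.insert(0, "outcome", outcome)
    return tab


def run_pipeline(config: StudyConfig | str, input_dir, output_dir,
                 seed: int | None = None) -> RunManifest:
    """Execute the whole analysis; returns the run manifest.

    ``config`` may be a :class:`StudyConfig` or a path to a YAML file. With
    ``config.sensitivity_mode`` the treatment-experienced cohort is replaced by
    all DMT-exposed patients regardless of PDC.
    """
    if not isinstance(config, StudyConfig):
        config = StudyConfig.from_yaml(config)
    seed = config.seed if seed is None else int(seed)
    in_dir, out_dir = Path(input_dir), Path(output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(),
        input_digests={f.name: _digest(f) for f in sorted(in_dir.glob("*.csv"))},
        seed=seed)

    def stage(name):
        class _Timer:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_

            def __exit__(self_, exc_type, exc, tb):
                manifest.stage_seconds[name] = round(time.perf_counter() - self_.t0, 3)
                if exc is not None:
                    raise StageError(f"stage {name!r} failed: {exc}") from exc
                logger.info("stage %s: done in %.2fs", name, manifest.stage_seconds[name])
        return _Timer()

    def emit(df, name):
        io_mod.write_table(df, out_dir / name)
        manifest.outputs.append(name)

    with stage("load"):
        bundle = io_mod.read_claims(in_dir, config)

    with stage("cohort"):
        ids, attrition = cohort_mod.select_main_cohort(
            bundle.medical, bundle.enrollment, config, pharmacy=bundle.pharmacy)
        emit(attrition.to_frame(), "attrition.csv")
        logger.info("main cohort: %d patients", len(ids))

    with stage("relapses"):
        events = relapse_mod.find_candidate_events(bundle.medical, bundle.pharmacy, config)
        episodes = relapse_mod.merge_into_episodes(events, config)
        emit(episodes.drop(columns=["event_dates"]), "relapse_episodes.csv")
        counts = relapse_mod.count_relapses(episodes, config.baseline_window())

    with stage("patterns"):
        claims = patterns_mod.dmt_claims(bundle.pharmacy, bundle.medical, config)
        pdc = patterns_mod.compute_pdc_table(
            claims[claims["patient_id"].isin(ids)], config.baseline_window(), config)
        emit(pdc, "pdc.csv")
        subgroups = cohort_mod.assign_subgroups(ids, claims, bundle.medical, pdc, config)
        naive = subgroups.loc[subgroups["subgroup"] == "naive", "patient_id"]
        if config.sensitivity_mode:
            exposed = cohort_mod.select_sensitivity_cohort(subgroups)
        else:
            exposed = pd.Index(
                subgroups.loc[subgroups["subgroup"] == "experienced", "patient_id"],
                name="patient_id")
        pat = patterns_mod.detect_patterns(claims, naive, exposed, config)
        emit(pat.events, "pattern_events.csv")

    with stage("records"):
        records = cov_mod.build_patient_records(
            ids, bundle.medical, bundle.pharmacy, bundle.enrollment,
            counts, config, subgroups=subgroups, patterns=pat)
        records["fu_cost_nondmt"] = records["fu_cost_nondmt_cents"] / 100.0
        emit(records.drop(columns=["fu_cost_nondmt"]), "patient_records.csv")

    with stage("models"):
        emit(models_mod.bivariate_table(records), "table1.csv")

        or_tabs = []
        for outcome in ("fu_allcause_er", "fu_allcause_hosp", "fu_ms_er", "fu_ms_hosp"):
            fit = models_mod.UtilizationModel(
                records, outcome, covariates=MODEL_COVARIATES, drop_constant=True).fit()
            or_tabs.append(_or_rows(fit, outcome))
        emit(pd.concat(or_tabs, ignore_index=True), "table2.csv")

        boot = models_mod.bootstrap_adjusted_costs(
            records, outcome="fu_cost_nondmt", covariates=MODEL_COVARIATES,
            B=config.bootstrap_reps, seed=seed, zero_policy=config.zero_cost_policy,
            drop_constant=True)
        table3 = pd.DataFrame(
            [(label, r.point, r.se, r.ci_lower, r.ci_upper)
             for label, r in (("hra_group", boot["exposed"]),
                              ("non_hra_group", boot["unexposed"]),
                              ("cost_difference", boot["difference"]))],
            columns=["group", "mean", "se", "ci_lower", "ci_upper"]).round(2)
        emit(table3, "table3.csv")

        fig2 = []
        for label, outcome, sub_ids in (("start_dmt_naive", "started", naive),
                                        ("switch_dmt_experienced", "switched", exposed),
                                        ("discontinue_dmt_experienced", "discontinued", exposed)):
            sub = records[records["patient_id"].isin(sub_ids)]
            if sub["hra"].nunique() < 2 or sub[outcome].nunique() < 2:
                logger.warning("figure2 %s: degenerate subgroup, skipped", label)
                continue
            fit = models_mod.UtilizationModel(
                sub, outcome, covariates=SUBGROUP_COVARIATES, drop_constant=True).fit()
            row = fit.odds_ratios().set_index("term").loc["hra"]
            fig2.append((label, row["odds_ratio"], row["ci_lower"], row["ci_upper"]))
        emit(pd.DataFrame(fig2, columns=["model", "odds_ratio", "ci_lower", "ci_upper"]),
             "figure2.csv")

    manifest.write(out_dir / "manifest.json")
    manifest.outputs.append("manifest.json")
    return manifest
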