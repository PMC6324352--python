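"""End-to-end analysis pipeline: simulate/load -> score -> group -> fit ->
calibrate -> report, with a machine-readable manifest.

Every stage failure aborts with the stage name and cause; filter counts
(cohort exclusions, unmapped codes) are logged and recorded in the manifest
so the cohort accounting is auditable. Given a fixed configuration the
produced table files and manifest are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from ._util import sha256_file
from .calibration import SubgroupDef, calibration_table, improvement_series
from .claims_data import (
    ClaimsTables,
    Cohort,
    CohortConfig,
    assemble_cohort,
    read_claims,
    summarize_cohort,
    write_summary,
)
from .cost_models import FittedModel, ModelDesign, ModelFamily, compare_fit, fit, predict
from .hcc_engine import RiskModelSpec, has_mh_hcc, load_model_spec, score_cohort
from .psycms_grouper import (
    PsyCMSCodeList,
    classify_cohort,
    flag_frame,
    load_codelist,
    missed_mh_analysis,
)
from .synthetic_data import (
    DIABETES_CCS,
    GeneratorConfig,
    MispricingMode,
    generate,
    inject_mispricing,
    write_files,
)

logger = logging.getLogger("riskcalib")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    outdir: str
    simulate: bool = True
    n: int = 5000
    seed: int = 7
    mispricing: str = MispricingMode.MH_UNPRICED.value
    cost_year: int = 2012
    claims_paths: Mapping[str, str] | None = None  # diagnoses/costs/demographics files
    model_spec_dir: str | None = None
    codelist_dir: str | None = None
    sensitivity: bool = False  # also fit sqrt-OLS and gamma-GLM families
    log_level: str = "INFO"

    @property
    def diagnosis_year(self) -> int:
        return self.cost_year - 1

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        if doc["claims_paths"] is not None:
            doc["claims_paths"] = dict(doc["claims_paths"])
        return doc


def built_in_subgroups(codelist: PsyCMSCodeList) -> tuple[SubgroupDef, ...]:
    """The three comparison subgroups: diabetes is risk-model-measured (raw
    diabetes categories), mental health and dementia are grouper-measured."""
    return (
        SubgroupDef("diabetes", lambda h, p: bool(h.raw_ccs & DIABETES_CCS)),
        SubgroupDef("mental_health", lambda h, p: bool(p.flags.get("any_mh_sa", False))),
        SubgroupDef("dementia", lambda h, p: bool(p.flags.get("dementia", False))),
    )


@dataclass
class PipelineResult:
    manifest: dict
    outdir: Path
    cohort: Cohort
    models: dict[str, FittedModel]

    @property
    def manifest_path(self) -> Path:
        return self.outdir / "manifest.json"


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                logger.info("stage %s", name)
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return wrapper

    return deco


@_stage("simulate")
def _stage_simulate(config: RunConfig, outdir: Path):
    gen_config = inject_mispricing(
        GeneratorConfig(n=config.n, seed=config.seed, cost_year=config.cost_year),
        config.mispricing,
    )
    synth = generate(gen_config)
    write_files(synth, outdir / "inputs")
    n_total = len(synth.tables.demographics)
    logger.info(
        "simulated %d patients, %d excluded by cohort rules", n_total, n_total - len(synth.cohort)
    )
    return synth.cohort, synth.model_spec, synth.codelist, n_total


@_stage("load")
def _stage_load(config: RunConfig):
    if config.claims_paths is None:
        raise FileNotFoundError("claims_paths must be set when simulate is false")
    tables = read_claims(config.claims_paths)
    cohort = assemble_cohort(
        tables, CohortConfig(cost_year=config.cost_year, diagnosis_year=config.diagnosis_year)
    )
    return tables, cohort, len(tables.demographics)


@_stage("score")
def _stage_score(cohort: Cohort, spec: RiskModelSpec):
    profiles, unmapped = score_cohort(cohort, spec)
    logger.info("scored %d patients; %d unmapped diagnosis codes", len(profiles), sum(unmapped.values()))
    return profiles, unmapped


@_stage("group")
def _stage_group(cohort: Cohort, codelist: PsyCMSCodeList):
    return classify_cohort(cohort, codelist)


@_stage("fit")
def _stage_fit(cohort, scores, psycms_profiles, codelist, sensitivity: bool):
    models: dict[str, FittedModel] = {}
    models["ols_base"] = fit(cohort, scores, None, ModelDesign(family=ModelFamily.OLS_LINEAR))
    models["ols_psycms"] = fit(
        cohort, scores, psycms_profiles, ModelDesign.augmented(codelist, ModelFamily.OLS_LINEAR)
    )
    if sensitivity:
        models["sqrt_base"] = fit(cohort, scores, None, ModelDesign(family=ModelFamily.OLS_SQRT))
        models["gamma_base"] = fit(
            cohort, scores, None, ModelDesign(family=ModelFamily.GLM_GAMMA_LOG)
        )
    for name, model in models.items():
        logger.info("fit %s: R2=%.4f (n=%d)", name, model.r_squared, model.n)
    return models


@_stage("calibrate")
def _stage_calibrate(cohort, models, scores, hcc_profiles, psycms_profiles, codelist, outdir: Path):
    y = cohort.total_costs()
    ids = cohort.patient_ids
    yhat_base = predict(models["ols_base"], scores)
    yhat_aug = predict(models["ols_psycms"], scores, psycms_profiles)

    tables = {}
    skipped = []
    tables["all"] = calibration_table(y, yhat_base, ids, label="all")
    for subgroup in built_in_subgroups(codelist):
        mask = subgroup.mask(hcc_profiles, psycms_profiles)
        try:
            tables[subgroup.name] = calibration_table(
                y, yhat_base, ids, label=subgroup.name, subgroup_mask=mask
            )
        except ValueError as exc:
            logger.warning("skipping calibration for %s: %s", subgroup.name, exc)
            skipped.append(subgroup.name)

    mh_mask = built_in_subgroups(codelist)[1].mask(hcc_profiles, psycms_profiles)
    improvement = improvement_series(y, yhat_base, yhat_aug, ids, subgroup_mask=mh_mask)
    return tables, improvement, skipped


@_stage("report")
def _stage_report(cohort, spec, codelist, hcc_profiles, psycms_profiles, outdir: Path):
    flags = flag_frame(psycms_profiles, codelist)
    flags = flags.rename(columns={c: f"psycms_{c}" for c in flags.columns})
    flags.insert(
        0, "v21_any_diabetes", [bool(h.raw_ccs & DIABETES_CCS) for h in hcc_profiles]
    )
    flags.insert(1, "v21_any_mh_sa", [has_mh_hcc(h, spec) for h in hcc_profiles])
    summary = summarize_cohort(cohort, flags)
    write_summary(summary, outdir / "table1_summary.csv")
    missed = missed_mh_analysis(cohort, hcc_profiles, psycms_profiles, spec, codelist, top_n=10)
    missed.write_csv(outdir / "table2_missed.csv")
    return summary, missed


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis and write all artifacts plus a manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "models").mkdir(exist_ok=True)

    if config.simulate:
        cohort, spec, codelist, n_total = _stage_simulate(config, outdir)
    else:
        tables, cohort, n_total = _stage_load(config)
        try:
            if config.model_spec_dir is None:
                raise FileNotFoundError("model_spec_dir is not set")
            if config.codelist_dir is None:
                raise FileNotFoundError("codelist_dir is not set")
            spec = load_model_spec(config.model_spec_dir)
            codelist = load_codelist(config.codelist_dir)
        except Exception as exc:
            raise PipelineError("score", exc) from exc

    hcc_profiles, unmapped = _stage_score(cohort, spec)
    psycms_profiles = _stage_group(cohort, codelist)
    scores = np.array([h.score for h in hcc_profiles])
    models = _stage_fit(cohort, scores, psycms_profiles, codelist, config.sensitivity)
    tables, improvement, skipped = _stage_calibrate(
        cohort, models, scores, hcc_profiles, psycms_profiles, codelist, outdir
    )
    _stage_report(cohort, spec, codelist, hcc_profiles, psycms_profiles, outdir)

    for name, table in tables.items():
        table.write_csv(outdir / f"calibration_{name}.csv")
    improvement.write_csv(outdir / "improvement_mental_health.csv")
    for name, model in models.items():
        model.to_json(outdir / "models" / f"{name}.json")

    comparison = compare_fit(models["ols_base"], models["ols_psycms"])
    artifact_names = (
        ["table1_summary.csv", "table2_missed.csv", "improvement_mental_health.csv"]
        + [f"calibration_{name}.csv" for name in tables]
        + [f"models/{name}.json" for name in models]
    )
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "counts": {
            "n_generated": n_total,
            "n_cohort": len(cohort),
            "n_excluded": n_total - len(cohort),
            "n_unmapped_codes": int(sum(unmapped.values())),
        },
        "fit": {
            "r_squared_base": comparison.r_squared_base,
            "r_squared_augmented": comparison.r_squared_augmented,
            "r_squared_difference": comparison.difference,
            "mh_gap_reduction": improvement.reduction,
        },
        "artifacts": {
            name: sha256_file(outdir / name) for name in sorted(artifact_names)
        },
        "partial": sorted(skipped),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(manifest=manifest, outdir=outdir, cohort=cohort, models=models)
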