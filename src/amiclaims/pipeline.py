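"""End-to-end pipeline: generate/load a bundle, extract cohorts, and emit
the full set of characterization reports as CSV + JSON.

Reports are machine-readable replicas of the study's descriptive outputs:
annual series (counts, per-1,000 proportions, version attribution),
demographics by ICD version stratum, gender-by-age rate curves (single
years and bins), windowed concurrent-condition tables, the drug-class
table under the top-100-products rule, procedure tables with the
EKG any-code query, and the inpatient length-of-stay summary.

A run manifest (seed, config hash, package version) makes a run exactly
reproducible; outputs are staged in a temporary directory and moved into
place only on success, so a failed run never leaves partial reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .characterize import (
    CONDITION_WINDOW,
    TREATMENT_WINDOW,
    annual_series,
    demographics_table,
    drug_class_table,
    gender_age_curve,
    los_summary,
    multi_code_any,
    pct,
    windowed_items,
)
from .codes import CodeList, load_ami_codelist
from .cohort import (
    QueryPeriod,
    StudyConfig,
    build_cohort,
    eligible_persons,
    version_attribution,
)
from .model import ClaimsBundle, Version, read_bundle, validate_bundle, write_bundle
from .resources import (
    EKG_CODE_SET,
    load_condition_categories,
    load_drug_classes,
    load_procedure_categories,
)
from .simulate import GeneratorConfig, generate, load_profile

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``bundle_dir`` (pre-existing six-file bundle) or
    ``profile`` (generator profile name/path, with ``seed``) must be set.
    """

    out_dir: str | Path = "pipeline_out"
    bundle_dir: str | Path | None = None
    profile: str | None = None
    seed: int = 0
    codelist_path: str | Path | None = None
    study: StudyConfig = field(default_factory=StudyConfig)
    top_n_conditions: int = 10
    top_n_items: int = 100
    ekg_codes: frozenset[str] = EKG_CODE_SET
    write_bundle_copy: bool = False
    log_level: str = "INFO"

    def codelist(self) -> CodeList:
        if self.codelist_path is not None:
            return CodeList.from_yaml(self.codelist_path)
        return load_ami_codelist()


def _config_hash(run: RunConfig) -> str:
    payload = {
        "profile": run.profile, "seed": run.seed,
        "bundle_dir": str(run.bundle_dir) if run.bundle_dir else None,
        "study": {"study_start": str(run.study.study_start),
                  "study_end": str(run.study.study_end),
                  "era_boundary": str(run.study.era_boundary),
                  "min_age_years": run.study.min_age_years,
                  "enrollment_gap_days": run.study.enrollment_gap_days},
        "top_n_conditions": run.top_n_conditions,
        "top_n_items": run.top_n_items,
        "ekg_codes": sorted(run.ekg_codes),
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage naming is the contract
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


@_stage("load")
def _load_bundle(run: RunConfig) -> ClaimsBundle:
    if (run.bundle_dir is None) == (run.profile is None):
        raise ValueError("set exactly one of bundle_dir or profile")
    if run.bundle_dir is not None:
        bundle = read_bundle(run.bundle_dir)
    else:
        config = load_profile(run.profile)
        bundle = generate(config, run.seed)
    violations = validate_bundle(bundle, last_study_year=run.study.study_end.year)
    if violations:
        raise ValueError(f"bundle failed validation: {violations[:5]} ...")
    logger.info("bundle: %d persons, %d diagnosis claims", bundle.n_persons, len(bundle.diagnoses))
    return bundle


def run_pipeline(run: RunConfig) -> dict:
    """Execute the full pipeline and return the JSON-able summary.

    Writes per-report CSVs plus ``summary.json`` and ``manifest.json`` to
    ``run.out_dir``.  Any stage failure raises :class:`PipelineError`
    naming the stage, and leaves no partial output directory behind.
    """
    logging.basicConfig(level=run.log_level)
    out_dir = Path(run.out_dir)
    bundle = _load_bundle(run)
    codelist = run.codelist()
    study = run.study
    years = list(range(study.study_start.year, study.study_end.year + 1))
    period = QueryPeriod.years(years[0], years[-1])

    tmp = Path(tempfile.mkdtemp(prefix=".amiclaims-", dir=out_dir.parent if out_dir.parent.exists() else "."))
    try:
        summary: dict = {}

        # --- cohorts (attrition is logged at each filter) ---------------
        any_cohort = build_cohort(bundle, codelist, period, "any_healthcare", study)
        inpat_cohort = build_cohort(bundle, codelist, period, "inpatient", study)
        logger.info("cohorts: any=%d inpatient=%d denominator=%d",
                    any_cohort.size, inpat_cohort.size, any_cohort.denominator)
        summary["cohorts"] = {
            "period": period.label,
            "any_healthcare": any_cohort.size,
            "inpatient": inpat_cohort.size,
            "denominator": any_cohort.denominator,
            "inpatient_share_pct": pct(inpat_cohort.size, any_cohort.size)
            if any_cohort.size else None,
        }
        any_cohort.events.to_csv(tmp / "cohort_any_healthcare.csv", index=False)
        inpat_cohort.events.to_csv(tmp / "cohort_inpatient.csv", index=False)

        # --- annual series + version attribution ------------------------
        try:
            annual = annual_series(bundle, codelist, years, study)
            annual.to_csv(tmp / "annual_series.csv", index=False)
            summary["annual_series"] = annual.to_dict(orient="records")
            summary["version_attribution"] = version_attribution(
                bundle, codelist, period, "any_healthcare", study)
        except Exception as exc:
            raise PipelineError(f"stage 'annual_series' failed: {exc}") from exc

        # --- demographics ------------------------------------------------
        try:
            strata = {
                "icd9": build_cohort(bundle, codelist, period, "any_healthcare", study,
                                     version=Version.ICD9CM),
                "icd10": build_cohort(bundle, codelist, period, "any_healthcare", study,
                                      version=Version.ICD10CM),
                "combined": any_cohort,
            }
            demo = demographics_table(strata)
            demo.to_csv(tmp / "demographics.csv", index=False)
            summary["demographics"] = demo.to_dict(orient="records")
        except Exception as exc:
            raise PipelineError(f"stage 'demographics' failed: {exc}") from exc

        # --- gender-age curve --------------------------------------------
        try:
            pop = eligible_persons(bundle, period, study)
            for by_bin, name in ((False, "gender_age_curve.csv"),
                                 (True, "gender_agebin_curve.csv")):
                gender_age_curve(any_cohort, pop, by_bin=by_bin).to_csv(tmp / name, index=False)
        except Exception as exc:
            raise PipelineError(f"stage 'gender_age_curve' failed: {exc}") from exc

        # --- windowed characterization ----------------------------------
        try:
            cond_map = load_condition_categories()
            conditions = windowed_items(any_cohort, bundle.diagnoses, CONDITION_WINDOW,
                                        item="code", top_n=run.top_n_items)
            tbl = conditions.table.copy()
            tbl["category"] = tbl["item"].map(cond_map.category)
            tbl.to_csv(tmp / "concurrent_conditions.csv", index=False)
            cardiac = tbl[tbl["category"] == "cardiac"].head(run.top_n_conditions)
            cardiac.to_csv(tmp / "concurrent_conditions_cardiac.csv", index=False)

            drug_map = load_drug_classes()
            classes = drug_class_table(any_cohort, bundle.drugs, TREATMENT_WINDOW, drug_map,
                                       top_n_products=run.top_n_items)
            classes.to_csv(tmp / "drug_classes.csv", index=False)
            summary["drug_classes"] = classes.to_dict(orient="records")

            proc_map = load_procedure_categories()
            procs = windowed_items(any_cohort, bundle.procedures, TREATMENT_WINDOW,
                                   item="procedure_code", top_n=run.top_n_items)
            ptbl = procs.table.copy()
            ptbl["category"] = ptbl["item"].map(proc_map.category)
            ptbl.to_csv(tmp / "procedures.csv", index=False)
            ptbl[ptbl["category"] == "evaluation_management"].to_csv(
                tmp / "procedures_em.csv", index=False)
            n_ekg, pct_ekg = multi_code_any(any_cohort, bundle.procedures, TREATMENT_WINDOW,
                                            set(run.ekg_codes))
            summary["ekg_any"] = {"person_count": n_ekg, "pct": pct_ekg}
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage 'characterize' failed: {exc}") from exc

        # --- length of stay ----------------------------------------------
        try:
            los = los_summary(inpat_cohort, bundle.admissions)
            summary["los"] = {
                "n": los.n, "mean": los.mean, "sd": los.sd, "median": los.median,
                "iqr": list(los.iqr), "range": list(los.range),
                "band_props": los.band_props, "n_unlinked": los.n_unlinked,
            }
            pd.DataFrame([summary["los"]]).to_json(tmp / "los_summary.json",
                                                   orient="records", indent=2)
        except Exception as exc:
            raise PipelineError(f"stage 'los_summary' failed: {exc}") from exc

        if run.write_bundle_copy:
            write_bundle(bundle, tmp / "bundle")

        manifest = {
            "package_version": __version__,
            "seed": run.seed,
            "profile": run.profile,
            "bundle_dir": str(run.bundle_dir) if run.bundle_dir else None,
            "config_hash": _config_hash(run),
            "n_persons": bundle.n_persons,
        }
        (tmp / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        (tmp / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))

        if out_dir.exists():
            shutil.rmtree(out_dir)
        tmp.rename(out_dir)
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    return summary
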