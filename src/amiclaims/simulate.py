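"""Synthetic administrative-claims generator.

Emulates a person-linked commercial / Medicare-supplemental claims
database at desk scale so the full phenotyping pipeline can run and be
verified without access to proprietary source data.  The generator is
calibrated, by default, to published marginal frequencies for the AMI
population: annual diagnosis rate ~3/1,000 enrollees, inpatient share of
cases 63.4%, case age-bin mixture (44.9% aged 65+), male share 61.4%,
per-code concurrent-diagnosis frequencies, cardiac drug-class ordering,
EKG any-code rate 79.0%, and the inpatient length-of-stay band
distribution (69.9 / 17.8 / 5.4 / 6.9% for 1–5 / 6–10 / 11–14 / >14 days).

Marginals are treated as independent given case status — the generator
reproduces each configured frequency in expectation but carries no joint
structure (e.g. age × drug class) beyond what case status induces.

Reproducibility: one RNG stream per output table, split from the master
seed, so the same seed gives a byte-identical bundle and adding a table
never perturbs earlier ones.
"""

from __future__ import annotations

from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .model import ClaimsBundle, Setting

__all__ = [
    "GeneratorConfig",
    "CatalogueItem",
    "generate",
    "ground_truth",
    "load_profile",
    "AGE_BIN_KEYS",
]

AGE_BIN_KEYS = ["0-17", "18-34", "35-44", "45-54", "55-64", "65+"]
_BIN_BOUNDS = {"0-17": (0, 17), "18-34": (18, 34), "35-44": (35, 44),
               "45-54": (45, 54), "55-64": (55, 64), "65+": (65, 95)}

ERA_BOUNDARY = np.datetime64("2015-10-01")


class CatalogueItem(BaseModel):
    """A code or product with its in-window occurrence probability."""

    code: str
    name: str = ""
    category: str = ""
    drug_class: str = ""
    version: str = ""
    prob: float = 0.0

    @field_validator("prob")
    @classmethod
    def _prob_range(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("probability must be in [0, 1]")
        return v


def _default_concurrent() -> list[CatalogueItem]:
    nine = [("78650", 0.513), ("4019", 0.470), ("41401", 0.468), ("2724", 0.326),
            ("41400", 0.247), ("79431", 0.192), ("4280", 0.178)]
    ten = [("I10", 0.516), ("R079", 0.435), ("I2510", 0.435), ("E785", 0.299),
           ("R9431", 0.199), ("R0789", 0.193), ("I509", 0.137), ("I517", 0.114)]
    return (
        [CatalogueItem(code=c, version="icd9cm", prob=p) for c, p in nine]
        + [CatalogueItem(code=c, version="icd10cm", prob=p) for c, p in ten]
    )


def _default_drugs() -> list[CatalogueItem]:
    rows = [
        ("D0001", "metoprolol tartrate", "beta_blocker", 0.20),
        ("D0002", "carvedilol", "beta_blocker", 0.12),
        ("D0003", "atenolol", "beta_blocker", 0.08),
        ("D0004", "metoprolol succinate", "beta_blocker", 0.06),
        ("D0005", "atorvastatin calcium", "anti_lipid", 0.283),
        ("D0006", "simvastatin", "anti_lipid", 0.08),
        ("D0007", "rosuvastatin calcium", "anti_lipid", 0.05),
        ("D0008", "clopidogrel bisulfate", "anti_platelet", 0.22),
        ("D0009", "ticagrelor", "anti_platelet", 0.07),
        ("D0010", "prasugrel", "anti_platelet", 0.03),
        ("D0011", "lisinopril", "ace_arb", 0.18),
        ("D0012", "losartan potassium", "ace_arb", 0.07),
        ("D0013", "hydrochlorothiazide/lisinopril", "ace_arb", 0.01),
        ("D0014", "nitroglycerin", "anti_anginal", 0.15),
        ("D0015", "isosorbide mononitrate", "anti_anginal", 0.04),
        ("D0016", "furosemide", "diuretic", 0.10),
        ("D0017", "hydrochlorothiazide", "diuretic", 0.03),
        ("D0018", "amlodipine besylate", "calcium_channel_blocker", 0.06),
        ("D0019", "diltiazem", "calcium_channel_blocker", 0.015),
        ("D0020", "digoxin", "other", 0.025),
        ("D0021", "warfarin sodium", "other", 0.02),
    ]
    return [CatalogueItem(code=c, name=n, category="cardiac", drug_class=k, prob=p)
            for c, n, k, p in rows]


def _default_procedures() -> list[CatalogueItem]:
    em = [("99232", 0.534), ("99223", 0.520), ("99285", 0.462), ("99233", 0.423),
          ("99291", 0.341), ("99214", 0.338), ("99239", 0.290), ("99222", 0.277),
          ("99238", 0.246), ("99213", 0.188), ("99231", 0.175)]
    other = [("71045", "imaging", 0.30), ("80053", "laboratory", 0.40),
             ("85025", "laboratory", 0.35), ("A0427", "emergency_medical_services", 0.15),
             ("88305", "pathology", 0.05), ("93306", "ultrasound_doppler", 0.30),
             ("96372", "medication_management", 0.10)]
    return (
        [CatalogueItem(code=c, category="evaluation_management", prob=p) for c, p in em]
        + [CatalogueItem(code=c, category=k, prob=p) for c, k, p in other]
    )


def _default_ekg() -> list[CatalogueItem]:
    return [CatalogueItem(code="93010", category="procedure", prob=0.711),
            CatalogueItem(code="93005", category="procedure", prob=0.200),
            CatalogueItem(code="93000", category="procedure", prob=0.164)]


class GeneratorConfig(BaseModel):
    """Full specification of the simulated study conditions.

    Defaults encode the calibrated profile; probability vectors are
    validated and mixes normalized at construction.
    """

    n_persons: int = 200_000
    years: tuple[int, int] = (2014, 2017)

    male_prob_case: float = 0.614
    male_prob_background: float = 0.481
    case_age_mix: dict[str, float] = Field(default_factory=lambda: {
        "0-17": 0.002, "18-34": 0.017, "35-44": 0.051,
        "45-54": 0.162, "55-64": 0.319, "65+": 0.449})
    background_age_mix: dict[str, float] = Field(default_factory=lambda: {
        "0-17": 0.220, "18-34": 0.244, "35-44": 0.148,
        "45-54": 0.164, "55-64": 0.158, "65+": 0.067})

    annual_ami_rate_per_1000: float = 3.0
    both_version_prob: float = 0.093
    enrollment_gap_prob: float = 0.02

    setting_mix: dict[str, float] = Field(default_factory=lambda: {
        "inpatient": 0.634, "emergency_department": 0.150, "other_outpatient": 0.080,
        "primary_care_office_visit": 0.050, "specialty_office_visit": 0.040,
        "other_outpatient_office_visit": 0.020, "non_doctor_office_visit": 0.012,
        "lab_test": 0.008, "pharmacy": 0.006})
    position_mix: dict[str, float] = Field(default_factory=lambda: {
        "principal": 0.6, "secondary": 0.3, "unspecified": 0.1})
    icd9_code_mix: dict[str, float] = Field(default_factory=lambda: {
        "41071": 0.45, "41090": 0.25, "41070": 0.15, "41001": 0.05,
        "41011": 0.04, "41041": 0.03, "41091": 0.03})
    icd10_code_mix: dict[str, float] = Field(default_factory=lambda: {
        "I214": 0.55, "I213": 0.20, "I219": 0.08, "I2109": 0.05, "I2101": 0.04,
        "I2111": 0.03, "I2102": 0.02, "I220": 0.02, "I221": 0.01})

    concurrent_marginals: list[CatalogueItem] = Field(default_factory=_default_concurrent)
    drug_catalogue: list[CatalogueItem] = Field(default_factory=_default_drugs)
    procedure_catalogue: list[CatalogueItem] = Field(default_factory=_default_procedures)
    ekg_any_prob: float = 0.79
    ekg_codes: list[CatalogueItem] = Field(default_factory=_default_ekg)

    background_dx_rate: float = 2.0
    background_drug_rate: float = 0.5
    background_proc_rate: float = 0.5
    decoy_dx_icd9: list[str] = Field(default_factory=lambda: [
        "4139", "412", "25000", "496", "5859", "2859", "30000",
        "71590", "0389", "V4581", "486", "4439", "2768"])
    decoy_dx_icd10: list[str] = Field(default_factory=lambda: [
        "I209", "I252", "E119", "J449", "N179", "D649", "F419",
        "M545", "A419", "Z951", "J189", "I739", "E875"])
    decoy_products: list[CatalogueItem] = Field(default_factory=lambda: [
        CatalogueItem(code="D9001", name="levothyroxine", category="endocrine"),
        CatalogueItem(code="D9002", name="omeprazole", category="gastrointestinal"),
        CatalogueItem(code="D9003", name="metformin", category="endocrine"),
        CatalogueItem(code="D9004", name="amoxicillin", category="infectious_disease")])
    decoy_procedures: list[str] = Field(default_factory=lambda: ["36415", "71046", "80061"])

    los_band_probs: tuple[float, float, float, float] = (0.699, 0.178, 0.054, 0.069)
    los_tail_geom_p: float = 0.1
    los_max_days: int = 384

    @field_validator("male_prob_case", "male_prob_background", "both_version_prob",
                     "enrollment_gap_prob", "ekg_any_prob", "los_tail_geom_p")
    @classmethod
    def _probs(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("probability must be in [0, 1]")
        return v

    @field_validator("case_age_mix", "background_age_mix", "setting_mix",
                     "position_mix", "icd9_code_mix", "icd10_code_mix")
    @classmethod
    def _simplex(cls, v: dict[str, float]) -> dict[str, float]:
        vals = list(v.values())
        if any(p < 0 for p in vals):
            raise ValueError("mixture probabilities must be non-negative")
        total = sum(vals)
        if not 0.98 <= total <= 1.02:
            raise ValueError(f"mixture must sum to ~1 (got {total:.4f})")
        return {k: p / total for k, p in v.items()}

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        if self.n_persons < 0:
            raise ValueError("n_persons must be non-negative")
        if abs(sum(self.los_band_probs) - 1.0) > 0.02:
            raise ValueError("los_band_probs must sum to ~1")
        if not 0 < self.annual_ami_rate_per_1000 <= 1000 and self.annual_ami_rate_per_1000 != 0:
            raise ValueError("annual_ami_rate_per_1000 out of range")
        bad = set(self.setting_mix) - {s.value for s in Setting}
        if bad:
            raise ValueError(f"unknown settings in setting_mix: {sorted(bad)}")
        return self


def load_profile(name_or_path: str) -> GeneratorConfig:
    """Load a generator profile: a packaged name ("paper_calibrated",
    "tiny_fixture") or a YAML file path.  Profile files override the
    calibrated defaults field by field."""
    import yaml
    from importlib.resources import files
    from pathlib import Path

    p = Path(name_or_path)
    if p.suffix in {".yaml", ".yml"} and p.exists():
        data = yaml.safe_load(p.read_text()) or {}
    else:
        res = files("amiclaims").joinpath(f"data/profiles/{name_or_path}.yaml")
        data = yaml.safe_load(res.read_text()) or {}
    return GeneratorConfig(**data)


def _sample_mix(rng: np.random.Generator, mix: dict[str, float], n: int) -> np.ndarray:
    keys = np.array(list(mix.keys()))
    probs = np.array(list(mix.values()), dtype=float)
    probs = probs / probs.sum()
    return keys[rng.choice(len(keys), size=n, p=probs)]


def _age_from_bins(rng: np.random.Generator, bins: np.ndarray, min_first_bin: int) -> np.ndarray:
    out = np.zeros(len(bins), dtype=int)
    for key, (lo, hi) in _BIN_BOUNDS.items():
        mask = bins == key
        if mask.any():
            low = max(lo, min_first_bin) if key == "0-17" else lo
            out[mask] = rng.integers(low, hi + 1, size=int(mask.sum()))
    return out


def _year_starts(years: Sequence[int]) -> np.ndarray:
    return np.array([np.datetime64(f"{y}-01-01") for y in years])


def _simulate(config: GeneratorConfig, seed: int) -> tuple[ClaimsBundle, pd.DataFrame]:
    ss = np.random.SeedSequence(seed)
    rng_person, rng_event, rng_dx, rng_drug, rng_proc, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    years = list(range(config.years[0], config.years[1] + 1))
    n_years = len(years)
    n = config.n_persons
    study_start = np.datetime64(f"{years[0]}-01-01")
    study_end = np.datetime64(f"{years[-1]}-12-31")
    year_starts = _year_starts(years)
    year_lengths = np.array(
        [(np.datetime64(f"{y + 1}-01-01") - np.datetime64(f"{y}-01-01")).astype(int) for y in years]
    )

    # ---- persons stream: enrollment gaps, case years, demographics -------
    person_id = np.array([f"P{i:07d}" for i in range(n)])
    has_gap = rng_person.random(n) < config.enrollment_gap_prob
    gap_year_idx = rng_person.integers(0, n_years, n)
    gap_day = rng_person.integers(30, 300, n)  # 30-day interior gap start (day of year)

    rate = config.annual_ami_rate_per_1000 / 1000.0
    case_mat = rng_person.random((n, n_years)) < rate
    case_mat[has_gap, gap_year_idx[has_gap]] = False  # gap year cannot index
    is_case = case_mat.any(axis=1)
    first_case_idx = np.where(is_case, case_mat.argmax(axis=1), 0)

    case_bins = _sample_mix(rng_person, config.case_age_mix, n)
    bg_bins = _sample_mix(rng_person, config.background_age_mix, n)
    case_age = _age_from_bins(rng_person, case_bins, min_first_bin=1)
    bg_age = _age_from_bins(rng_person, bg_bins, min_first_bin=0)
    # cases: age drawn at first case year; background: age at study start
    birth_year = np.where(
        is_case,
        np.array(years)[first_case_idx] - case_age,
        years[0] - bg_age,
    )
    male_draw = rng_person.random(n)
    gender = np.where(
        male_draw < np.where(is_case, config.male_prob_case, config.male_prob_background),
        "male", "female",
    )

    persons = pd.DataFrame({"person_id": person_id, "birth_year": birth_year, "gender": gender})
    plan = np.where(years[0] - birth_year >= 65, "medicare_supplemental", "commercial")

    # ---- enrollment spans ------------------------------------------------
    enr_rows = []
    no_gap = ~has_gap
    enr_rows.append(pd.DataFrame({
        "person_id": person_id[no_gap],
        "start_date": study_start, "end_date": study_end, "plan": plan[no_gap]}))
    if has_gap.any():
        g_pid = person_id[has_gap]
        g_year = np.array(years)[gap_year_idx[has_gap]]
        g_start = np.array([np.datetime64(f"{y}-01-01") for y in g_year]) + gap_day[has_gap]
        enr_rows.append(pd.DataFrame({
            "person_id": g_pid, "start_date": study_start,
            "end_date": g_start - np.timedelta64(1, "D"), "plan": plan[has_gap]}))
        enr_rows.append(pd.DataFrame({
            "person_id": g_pid, "start_date": g_start + np.timedelta64(30, "D"),
            "end_date": study_end, "plan": plan[has_gap]}))
    enrollment = pd.concat(enr_rows, ignore_index=True)
    enrollment["start_date"] = pd.to_datetime(enrollment["start_date"])
    enrollment["end_date"] = pd.to_datetime(enrollment["end_date"])

    # ---- index events (events stream) ------------------------------------
    ev_person_idx, ev_year_idx = np.nonzero(case_mat)
    n_ev = len(ev_person_idx)
    ev_year = np.array(years)[ev_year_idx]
    ev_year_start = year_starts[ev_year_idx]
    ev_year_len = year_lengths[ev_year_idx]

    is_2015 = ev_year == 2015
    both_flag = np.zeros(n_ev, dtype=bool)
    both_flag[is_2015] = rng_event.random(int(is_2015.sum())) < config.both_version_prob
    day = np.floor(rng_event.random(n_ev) * ev_year_len).astype(int)
    # "both"-version 2015 events index in the ICD-9 era (Jan-Sep, 273 days)
    day[both_flag] = np.floor(rng_event.random(int(both_flag.sum())) * 273).astype(int)
    ev_date = ev_year_start + day.astype("timedelta64[D]")
    ev_is9 = ev_date < ERA_BOUNDARY

    ev_code = np.empty(n_ev, dtype=object)
    if ev_is9.any():
        ev_code[ev_is9] = _sample_mix(rng_event, config.icd9_code_mix, int(ev_is9.sum()))
    if (~ev_is9).any():
        ev_code[~ev_is9] = _sample_mix(rng_event, config.icd10_code_mix, int((~ev_is9).sum()))
    ev_setting = _sample_mix(rng_event, config.setting_mix, n_ev)
    ev_position = _sample_mix(rng_event, config.position_mix, n_ev)

    dx_frames = [pd.DataFrame({
        "person_id": person_id[ev_person_idx],
        "service_date": ev_date,
        "code": ev_code,
        "version": np.where(ev_is9, "icd9cm", "icd10cm"),
        "position": ev_position,
        "setting": ev_setting,
    })]

    # extra cross-era claim for "both"-version 2015 cases (Oct-Dec, 92 days)
    nb = int(both_flag.sum())
    if nb:
        extra_day = 273 + np.floor(rng_event.random(nb) * 92).astype(int)
        extra_date = ev_year_start[both_flag] + extra_day.astype("timedelta64[D]")
        extra_code = _sample_mix(rng_event, config.icd10_code_mix, nb)
        extra_setting = _sample_mix(rng_event, config.setting_mix, nb)
        extra_position = _sample_mix(rng_event, config.position_mix, nb)
        dx_frames.append(pd.DataFrame({
            "person_id": person_id[ev_person_idx[both_flag]],
            "service_date": extra_date,
            "code": extra_code,
            "version": "icd10cm",
            "position": extra_position,
            "setting": extra_setting,
        }))

    # ---- concurrent in-window diagnoses (dx stream) ----------------------
    concurrent_rows = {i: [] for i in range(n_ev)}
    for entry in config.concurrent_marginals:
        offs = rng_dx.integers(-1, 2, n_ev)
        hit = rng_dx.random(n_ev) < entry.prob
        d = ev_date + offs.astype("timedelta64[D]")
        era_ok = (d < ERA_BOUNDARY) if entry.version == "icd9cm" else (d >= ERA_BOUNDARY)
        sel = hit & era_ok
        if sel.any():
            dx_frames.append(pd.DataFrame({
                "person_id": person_id[ev_person_idx[sel]],
                "service_date": d[sel],
                "code": entry.code,
                "version": entry.version,
                "position": "secondary",
                "setting": ev_setting[sel],
            }))
            for i in np.nonzero(sel)[0]:
                concurrent_rows[int(i)].append(entry.code)

    # ---- drug orders (drug stream) ---------------------------------------
    drug_frames = []
    drug_truth = {i: [] for i in range(n_ev)}
    for item in config.drug_catalogue:
        hit = rng_drug.random(n_ev) < item.prob
        if hit.any():
            offs = rng_drug.integers(-1, 15, int(hit.sum()))
            drug_frames.append(pd.DataFrame({
                "person_id": person_id[ev_person_idx[hit]],
                "order_date": ev_date[hit] + offs.astype("timedelta64[D]"),
                "product_code": item.code,
                "product_name": item.name,
            }))
            for i in np.nonzero(hit)[0]:
                drug_truth[int(i)].append(item.code)

    # ---- procedures (proc stream) ----------------------------------------
    proc_frames = []
    proc_truth = {i: [] for i in range(n_ev)}
    for item in config.procedure_catalogue:
        hit = rng_proc.random(n_ev) < item.prob
        if hit.any():
            offs = rng_proc.integers(-1, 15, int(hit.sum()))
            proc_frames.append(pd.DataFrame({
                "person_id": person_id[ev_person_idx[hit]],
                "service_date": ev_date[hit] + offs.astype("timedelta64[D]"),
                "procedure_code": item.code,
                "setting": ev_setting[hit],
            }))
            for i in np.nonzero(hit)[0]:
                proc_truth[int(i)].append(item.code)
    # EKG: calibrate the any-code rate exactly, code marginals conditionally
    has_ekg = rng_proc.random(n_ev) < config.ekg_any_prob
    ekg_any = max(config.ekg_any_prob, 1e-9)
    got_any = np.zeros(n_ev, dtype=bool)
    for item in config.ekg_codes:
        q = min(1.0, item.prob / ekg_any)
        hit = has_ekg & (rng_proc.random(n_ev) < q)
        got_any |= hit
        if hit.any():
            offs = rng_proc.integers(-1, 15, int(hit.sum()))
            proc_frames.append(pd.DataFrame({
                "person_id": person_id[ev_person_idx[hit]],
                "service_date": ev_date[hit] + offs.astype("timedelta64[D]"),
                "procedure_code": item.code,
                "setting": ev_setting[hit],
            }))
            for i in np.nonzero(hit)[0]:
                proc_truth[int(i)].append(item.code)
    # force the most common code for has_ekg persons whose conditional draws
    # all came up empty, so the any-EKG marginal is exact
    force = has_ekg & ~got_any
    if force.any() and config.ekg_codes:
        lead = max(config.ekg_codes, key=lambda e: e.prob)
        offs = rng_proc.integers(-1, 15, int(force.sum()))
        proc_frames.append(pd.DataFrame({
            "person_id": person_id[ev_person_idx[force]],
            "service_date": ev_date[force] + offs.astype("timedelta64[D]"),
            "procedure_code": lead.code,
            "setting": ev_setting[force],
        }))
        for i in np.nonzero(force)[0]:
            proc_truth[int(i)].append(lead.code)

    # ---- admissions (event stream continues) -----------------------------
    inpat = ev_setting == "inpatient"
    if nb:
        extra_inpat = extra_setting == "inpatient"
    adm_frames = []
    los_all = np.full(n_ev, -1, dtype=int)

    def _draw_los(rng: np.random.Generator, m: int) -> np.ndarray:
        band = rng.choice(4, size=m, p=np.array(config.los_band_probs) / sum(config.los_band_probs))
        los = np.empty(m, dtype=int)
        for b, (lo, hi) in enumerate([(1, 5), (6, 10), (11, 14), (None, None)]):
            mask = band == b
            cnt = int(mask.sum())
            if not cnt:
                continue
            if b < 3:
                los[mask] = rng.integers(lo, hi + 1, cnt)
            else:
                tail = 15 + rng.geometric(config.los_tail_geom_p, cnt) - 1
                los[mask] = np.minimum(tail, config.los_max_days)
        return los

    if inpat.any():
        m = int(inpat.sum())
        los = _draw_los(rng_event, m)
        los_all[inpat] = los
        adm_frames.append(pd.DataFrame({
            "person_id": person_id[ev_person_idx[inpat]],
            "admit_date": ev_date[inpat],
            "discharge_date": ev_date[inpat] + los.astype("timedelta64[D]"),
        }))
    if nb and extra_inpat.any():
        m = int(extra_inpat.sum())
        los = _draw_los(rng_event, m)
        adm_frames.append(pd.DataFrame({
            "person_id": person_id[ev_person_idx[both_flag][extra_inpat]],
            "admit_date": extra_date[extra_inpat],
            "discharge_date": extra_date[extra_inpat] + los.astype("timedelta64[D]"),
        }))

    # ---- background noise (noise stream) ---------------------------------
    def _noise_dates(rng: np.random.Generator, m: int) -> np.ndarray:
        total_days = int((study_end - study_start).astype(int)) + 1
        return study_start + rng.integers(0, total_days, m).astype("timedelta64[D]")

    counts = rng_noise.poisson(config.background_dx_rate, n)
    m = int(counts.sum())
    if m:
        pid_rep = np.repeat(person_id, counts)
        d = _noise_dates(rng_noise, m)
        is9 = d < ERA_BOUNDARY
        code = np.empty(m, dtype=object)
        if is9.any():
            code[is9] = np.array(config.decoy_dx_icd9)[
                rng_noise.integers(0, len(config.decoy_dx_icd9), int(is9.sum()))]
        if (~is9).any():
            code[~is9] = np.array(config.decoy_dx_icd10)[
                rng_noise.integers(0, len(config.decoy_dx_icd10), int((~is9).sum()))]
        dx_frames.append(pd.DataFrame({
            "person_id": pid_rep, "service_date": d, "code": code,
            "version": np.where(is9, "icd9cm", "icd10cm"),
            "position": _sample_mix(rng_noise, config.position_mix, m),
            "setting": _sample_mix(rng_noise, config.setting_mix, m),
        }))
    counts = rng_noise.poisson(config.background_drug_rate, n)
    m = int(counts.sum())
    if m and config.decoy_products:
        idx = rng_noise.integers(0, len(config.decoy_products), m)
        drug_frames.append(pd.DataFrame({
            "person_id": np.repeat(person_id, counts),
            "order_date": _noise_dates(rng_noise, m),
            "product_code": np.array([p.code for p in config.decoy_products])[idx],
            "product_name": np.array([p.name for p in config.decoy_products])[idx],
        }))
    counts = rng_noise.poisson(config.background_proc_rate, n)
    m = int(counts.sum())
    if m and config.decoy_procedures:
        proc_frames.append(pd.DataFrame({
            "person_id": np.repeat(person_id, counts),
            "service_date": _noise_dates(rng_noise, m),
            "procedure_code": np.array(config.decoy_procedures)[
                rng_noise.integers(0, len(config.decoy_procedures), m)],
            "setting": _sample_mix(rng_noise, config.setting_mix, m),
        }))

    # ---- assemble --------------------------------------------------------
    def _cat(frames, cols, date_cols):
        if not frames:
            df = pd.DataFrame(columns=cols)
        else:
            df = pd.concat(frames, ignore_index=True)[cols]
        for c in date_cols:
            df[c] = pd.to_datetime(df[c])
        return df

    bundle = ClaimsBundle(
        persons=persons,
        enrollment=enrollment[["person_id", "start_date", "end_date", "plan"]],
        diagnoses=_cat(dx_frames,
                       ["person_id", "service_date", "code", "version", "position", "setting"],
                       ["service_date"]),
        drugs=_cat(drug_frames, ["person_id", "order_date", "product_code", "product_name"],
                   ["order_date"]),
        procedures=_cat(proc_frames, ["person_id", "service_date", "procedure_code", "setting"],
                        ["service_date"]),
        admissions=_cat(adm_frames, ["person_id", "admit_date", "discharge_date"],
                        ["admit_date", "discharge_date"]),
    )

    # ---- ground truth ----------------------------------------------------
    ev_order = np.lexsort((ev_date.astype("datetime64[D]").astype(int), ev_person_idx))
    first_ev: dict[int, int] = {}
    n_case_years = np.zeros(n, dtype=int)
    for j in ev_order[::-1]:
        first_ev[int(ev_person_idx[j])] = int(j)
    for j in range(n_ev):
        n_case_years[ev_person_idx[j]] += 1
    truth_rows = []
    for i in range(n):
        if not is_case[i]:
            truth_rows.append({
                "person_id": person_id[i], "is_case": False, "index_date": pd.NaT,
                "index_code": "", "index_version": "", "index_setting": "",
                "age_at_index": -1, "both_2015": False, "n_case_years": 0,
                "los_days": -1, "concurrent_codes": "", "drug_products": "",
                "procedure_codes": ""})
            continue
        j = first_ev[i]
        idx_year = int(ev_year[j])
        truth_rows.append({
            "person_id": person_id[i],
            "is_case": True,
            "index_date": pd.Timestamp(ev_date[j]),
            "index_code": ev_code[j],
            "index_version": "icd9cm" if ev_is9[j] else "icd10cm",
            "index_setting": ev_setting[j],
            "age_at_index": idx_year - int(birth_year[i]),
            "both_2015": bool(both_flag[j]),
            "n_case_years": int(n_case_years[i]),
            "los_days": int(los_all[j]),
            "concurrent_codes": "|".join(concurrent_rows[j]),
            "drug_products": "|".join(drug_truth[j]),
            "procedure_codes": "|".join(proc_truth[j]),
        })
    truth = pd.DataFrame(truth_rows)
    return bundle, truth


def generate(config: GeneratorConfig, seed: int) -> ClaimsBundle:
    """Generate a reproducible synthetic claims bundle (same config and
    seed give a record-identical bundle)."""
    bundle, _ = _simulate(config, seed)
    return bundle


def ground_truth(config: GeneratorConfig, seed: int) -> pd.DataFrame:
    """Per-person truth table for the same config/seed: case status, index
    event, length of stay, and the in-window items attached to the first
    event.  Consistent with :func:`generate` by construction."""
    _, truth = _simulate(config, seed)
    return truth
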