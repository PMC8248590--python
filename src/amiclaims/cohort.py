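"""Cohort extraction under the claims-phenotyping inclusion rules.

The engine applies a wildcard code list to a :class:`~amiclaims.model.ClaimsBundle`
with the following rules:

* **Continuous enrollment** — a person enters a query period only if their
  (merged) enrollment spans cover at least one whole calendar year inside
  the period; only claims dated inside such fully-enrolled years can index.
* **Era gating** — ICD-9-CM codes are queried only before the U.S.
  transition date (2015-10-01), ICD-10-CM codes only on/after it, to
  exclude overt coding errors.
* **Any position, scoped setting** — a single matching diagnosis code in
  any coding position qualifies; the setting scope is either all nine
  settings ("any healthcare setting") or inpatient only.
* **First event per period** — each person is counted once per query
  period at their chronologically first qualifying claim; readmissions and
  subsequent events inside the period are ignored.
* **Infant exclusion** — persons younger than ``min_age_years`` (default 1)
  at a calendar year's start are excluded from that year's numerator and
  denominator.

Same-day ties are broken deterministically: inpatient setting first, then
principal coding position, then lexicographic code order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .codes import CodeList
from .model import ClaimsBundle, Setting, Version

__all__ = [
    "StudyConfig",
    "QueryPeriod",
    "Cohort",
    "ANY_HEALTHCARE",
    "INPATIENT_ONLY",
    "merge_spans",
    "continuously_enrolled",
    "era_valid",
    "eligible_person_years",
    "eligible_persons",
    "build_cohort",
    "version_attribution",
]

ANY_HEALTHCARE: frozenset[str] = frozenset(s.value for s in Setting)
INPATIENT_ONLY: frozenset[str] = frozenset({Setting.INPATIENT.value})

_SCOPES = {"any_healthcare": ANY_HEALTHCARE, "inpatient": INPATIENT_ONLY}


@dataclass(frozen=True)
class StudyConfig:
    """Global study parameters: period bounds, ICD era boundary, minimum
    age, and the enrollment-gap allowance (0 = strictly continuous)."""

    study_start: date = date(2014, 1, 1)
    study_end: date = date(2017, 12, 31)
    era_boundary: date = date(2015, 10, 1)
    min_age_years: int = 1
    enrollment_gap_days: int = 0

    def __post_init__(self) -> None:
        if not (self.study_start < self.era_boundary < self.study_end):
            raise ValueError("require study_start < era_boundary < study_end")


@dataclass(frozen=True)
class QueryPeriod:
    start: date
    end: date
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("period start after end")
        if not self.label:
            object.__setattr__(self, "label", f"{self.start.year}-{self.end.year}"
                               if self.start.year != self.end.year else str(self.start.year))

    @classmethod
    def year(cls, y: int) -> "QueryPeriod":
        return cls(date(y, 1, 1), date(y, 12, 31), str(y))

    @classmethod
    def years(cls, first: int, last: int) -> "QueryPeriod":
        return cls(date(first, 1, 1), date(last, 12, 31), f"{first}-{last}")

    def calendar_years(self) -> list[int]:
        """Whole calendar years contained in the period."""
        return [y for y in range(self.start.year, self.end.year + 1)
                if date(y, 1, 1) >= self.start and date(y, 12, 31) <= self.end]


@dataclass
class Cohort:
    """One query period's index events plus denominator bookkeeping.

    ``events`` has one row per person: person_id, index_date, code,
    version, setting, age_at_index, gender.  ``denominator`` counts the
    continuously enrolled, age-eligible population for the period.
    """

    period: QueryPeriod
    setting_scope: str
    events: pd.DataFrame
    denominator: int
    config: StudyConfig = field(default_factory=StudyConfig)

    @property
    def size(self) -> int:
        return len(self.events)


def merge_spans(spans: list[tuple[date, date]]) -> list[tuple[date, date]]:
    """Merge overlapping or adjacent (end + 1 day = next start) spans into
    disjoint, sorted spans covering the same set of days."""
    if not spans:
        return []
    ordered = sorted(spans)
    out = [ordered[0]]
    for start, end in ordered[1:]:
        last_start, last_end = out[-1]
        if start <= last_end + timedelta(days=1):
            out[-1] = (last_start, max(last_end, end))
        else:
            out.append((start, end))
    return out


def continuously_enrolled(
    spans: list[tuple[date, date]], year: int, gap_days: int = 0
) -> bool:
    """True iff merged spans cover the whole calendar year, allowing
    *interior* gaps of at most ``gap_days``; the year's first and last day
    must themselves be covered."""
    merged = merge_spans(spans)
    y0, y1 = date(year, 1, 1), date(year, 12, 31)
    clipped = [(max(s, y0), min(e, y1)) for s, e in merged if e >= y0 and s <= y1]
    if not clipped:
        return False
    if clipped[0][0] != y0 or clipped[-1][1] != y1:
        return False
    for (s0, e0), (s1, e1) in zip(clipped, clipped[1:]):
        if (s1 - e0).days - 1 > gap_days:
            return False
    return True


def era_valid(version: Version | str, service_date: date, config: StudyConfig) -> bool:
    """Era gate: ICD-9-CM before the boundary, ICD-10-CM on/after it."""
    version = Version(version)
    if version == Version.ICD9CM:
        return service_date < config.era_boundary
    return service_date >= config.era_boundary


def _merged_spans_frame(enrollment: pd.DataFrame) -> pd.DataFrame:
    """Vectorized per-person span merge: returns person_id, start, end."""
    if not len(enrollment):
        return pd.DataFrame(columns=["person_id", "start", "end"])
    df = enrollment[["person_id", "start_date", "end_date"]].copy()
    df["start_date"] = pd.to_datetime(df["start_date"])
    df["end_date"] = pd.to_datetime(df["end_date"])
    df = df.sort_values(["person_id", "start_date", "end_date"], kind="mergesort")
    running_max = df.groupby("person_id")["end_date"].cummax()
    prev_end = running_max.groupby(df["person_id"]).shift()
    new_group = prev_end.isna() | (df["start_date"] > prev_end + pd.Timedelta(days=1))
    gid = new_group.cumsum()
    merged = df.groupby([df["person_id"], gid]).agg(
        start=("start_date", "min"), end=("end_date", "max")
    ).reset_index(level=0).reset_index(drop=True)
    return merged


def eligible_person_years(
    bundle: ClaimsBundle, period: QueryPeriod, config: StudyConfig | None = None
) -> pd.DataFrame:
    """Person-years passing the enrollment and age rules within the period.

    Returns columns person_id, year, age (age = year - birth_year).
    """
    config = config or StudyConfig()
    years = period.calendar_years()
    if not years:
        return pd.DataFrame(columns=["person_id", "year", "age"])
    merged = _merged_spans_frame(bundle.enrollment)
    rows = []
    if config.enrollment_gap_days == 0:
        # fast path: a single merged span must contain the whole year
        for y in years:
            y0, y1 = pd.Timestamp(y, 1, 1), pd.Timestamp(y, 12, 31)
            ok = merged[(merged["start"] <= y0) & (merged["end"] >= y1)]
            if len(ok):
                rows.append(pd.DataFrame({"person_id": ok["person_id"].unique(), "year": y}))
    else:
        for pid, grp in merged.groupby("person_id"):
            spans = [(s.date(), e.date()) for s, e in zip(grp["start"], grp["end"])]
            for y in years:
                if continuously_enrolled(spans, y, config.enrollment_gap_days):
                    rows.append(pd.DataFrame({"person_id": [pid], "year": [y]}))
    if not rows:
        return pd.DataFrame(columns=["person_id", "year", "age"])
    py = pd.concat(rows, ignore_index=True)
    py = py.merge(bundle.persons[["person_id", "birth_year"]], on="person_id", how="left")
    py["age"] = py["year"] - py["birth_year"]
    py = py[py["age"] >= config.min_age_years]
    return py[["person_id", "year", "age"]].reset_index(drop=True)


def eligible_persons(
    bundle: ClaimsBundle, period: QueryPeriod, config: StudyConfig | None = None
) -> pd.DataFrame:
    """Denominator population: one row per eligible person with gender and
    age at the first eligible year."""
    py = eligible_person_years(bundle, period, config)
    if not len(py):
        return pd.DataFrame(columns=["person_id", "first_year", "age", "gender"])
    first = py.sort_values(["person_id", "year"]).groupby("person_id", as_index=False).first()
    first = first.rename(columns={"year": "first_year"})
    first = first.merge(bundle.persons[["person_id", "gender"]], on="person_id", how="left")
    return first[["person_id", "first_year", "age", "gender"]]


def _resolve_scope(setting_scope: str | frozenset[str] | set[str]) -> tuple[str, frozenset[str]]:
    if isinstance(setting_scope, str):
        if setting_scope not in _SCOPES:
            raise ValueError(f"unknown setting scope {setting_scope!r}")
        return setting_scope, _SCOPES[setting_scope]
    return "custom", frozenset(setting_scope)


def _qualifying_claims(
    bundle: ClaimsBundle,
    codelist: CodeList,
    period: QueryPeriod,
    scope: frozenset[str],
    config: StudyConfig,
    version: Version | str | None = None,
) -> pd.DataFrame:
    """All era-valid, code-matching, in-scope claims dated inside a fully
    enrolled, age-eligible calendar year of the period."""
    if not codelist.patterns:
        raise ValueError("empty code list")
    dx = bundle.diagnoses
    if not len(dx):
        return dx.copy()
    dates = pd.to_datetime(dx["service_date"])
    mask = (dates >= pd.Timestamp(period.start)) & (dates <= pd.Timestamp(period.end))
    mask &= (dates >= pd.Timestamp(config.study_start)) & (dates <= pd.Timestamp(config.study_end))
    boundary = pd.Timestamp(config.era_boundary)
    is9 = dx["version"] == Version.ICD9CM.value
    mask &= np.where(is9, dates < boundary, dates >= boundary)
    mask &= dx["setting"].isin(scope)
    if version is not None:
        mask &= dx["version"] == Version(version).value
    rx9 = codelist.regex_for(Version.ICD9CM)
    rx10 = codelist.regex_for(Version.ICD10CM)
    code_ok = np.where(
        is9, dx["code"].str.fullmatch(rx9.pattern), dx["code"].str.fullmatch(rx10.pattern)
    )
    mask &= code_ok.astype(bool)
    q = dx[mask].copy()
    if not len(q):
        return q
    q["service_date"] = pd.to_datetime(q["service_date"])
    q["year"] = q["service_date"].dt.year
    py = eligible_person_years(bundle, period, config)
    q = q.merge(py, on=["person_id", "year"], how="inner")
    return q


def build_cohort(
    bundle: ClaimsBundle,
    codelist: CodeList,
    period: QueryPeriod,
    setting_scope: str | frozenset[str] = "any_healthcare",
    config: StudyConfig | None = None,
    version: Version | str | None = None,
) -> Cohort:
    """Extract one cohort: first qualifying claim per eligible person.

    ``version`` optionally restricts matching claims to one ICD version
    (used to build the per-version strata of the demographics table).
    Deterministic regardless of input record order.
    """
    config = config or StudyConfig()
    scope_label, scope = _resolve_scope(setting_scope)
    q = _qualifying_claims(bundle, codelist, period, scope, config, version)
    denom = len(eligible_persons(bundle, period, config))
    if not len(q):
        events = pd.DataFrame(
            columns=["person_id", "index_date", "code", "version", "setting",
                     "age_at_index", "gender"]
        )
        return Cohort(period, scope_label, events, denom, config)
    position_rank = q["position"].map({"principal": 0, "secondary": 1, "unspecified": 2}).fillna(3)
    setting_rank = (q["setting"] != Setting.INPATIENT.value).astype(int)
    q = q.assign(_srank=setting_rank, _prank=position_rank)
    q = q.sort_values(["person_id", "service_date", "_srank", "_prank", "code"],
                      kind="mergesort")
    first = q.groupby("person_id", as_index=False).first()
    persons = bundle.persons[["person_id", "birth_year", "gender"]]
    first = first.merge(persons, on="person_id", how="left")
    first["age_at_index"] = first["service_date"].dt.year - first["birth_year"]
    events = first.rename(columns={"service_date": "index_date"})[
        ["person_id", "index_date", "code", "version", "setting", "age_at_index", "gender"]
    ].sort_values("person_id").reset_index(drop=True)
    return Cohort(period, scope_label, events, denom, config)


def version_attribution(
    bundle: ClaimsBundle,
    codelist: CodeList,
    period: QueryPeriod,
    setting_scope: str | frozenset[str] = "any_healthcare",
    config: StudyConfig | None = None,
) -> dict[str, int]:
    """Split a straddle-period cohort by the ICD version(s) under which each
    person qualified.

    A person is "both" iff they have at least one qualifying era-valid
    claim under each version inside the period; such persons are counted
    once in the cohort.  Satisfies |C9 ∪ C10| = |C9| + |C10| − both.
    """
    config = config or StudyConfig()
    _, scope = _resolve_scope(setting_scope)
    q = _qualifying_claims(bundle, codelist, period, scope, config)
    if not len(q):
        return {"icd9_only": 0, "icd10_only": 0, "both": 0, "total": 0}
    per_person = q.groupby("person_id")["version"].agg(set)
    both = int((per_person.map(len) == 2).sum())
    icd9_only = int((per_person == {Version.ICD9CM.value}).sum())
    icd10_only = int((per_person == {Version.ICD10CM.value}).sum())
    return {
        "icd9_only": icd9_only,
        "icd10_only": icd10_only,
        "both": both,
        "total": icd9_only + icd10_only + both,
    }
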