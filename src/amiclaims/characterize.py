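"""Descriptive characterization of an extracted cohort.

Implements the reporting operations applied to the index events of a
cohort: annual counts and per-1,000 proportions, demographics (age bins,
gender), gender-by-age rate curves, windowed concurrent-diagnosis and
treatment frequency tables, drug-class grouping under the top-100-products
rule, multi-code "any of" queries (e.g. the three electrocardiogram CPT
codes), and inpatient length-of-stay summaries.

All temporal windows are closed intervals in days relative to the index
date: concurrent conditions use (−1, +1); treatments and procedures use
(−1, +14).  Printed percentages are rounded half-away-from-zero to one
decimal; per-1,000 proportions to two decimals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .cohort import Cohort, QueryPeriod, StudyConfig, build_cohort, eligible_persons, version_attribution
from .codes import CodeList
from .model import ClaimsBundle, Version

__all__ = [
    "AGE_BINS",
    "CONDITION_WINDOW",
    "TREATMENT_WINDOW",
    "WindowSpec",
    "CategoryMap",
    "FrequencyTable",
    "LosSummary",
    "DemographicsSummary",
    "round_half_away",
    "pct",
    "per_1000",
    "annual_series",
    "windowed_items",
    "drug_class_table",
    "multi_code_any",
    "los_summary",
    "gender_age_curve",
    "demographics",
    "demographics_table",
]

logger = logging.getLogger(__name__)

#: Age bins used throughout demographic reporting (inclusive bounds; the
#: last bin is open-ended).
AGE_BINS: list[tuple[int, int | None]] = [
    (0, 17), (18, 34), (35, 44), (45, 54), (55, 64), (65, None),
]

LOS_BANDS: list[tuple[int, int | None]] = [(1, 5), (6, 10), (11, 14), (15, None)]
LOS_BAND_LABELS = ["1-5", "6-10", "11-14", ">14"]


def bin_label(lo: int, hi: int | None) -> str:
    return f"{lo}+" if hi is None else f"{lo}-{hi}"


@dataclass(frozen=True)
class WindowSpec:
    """Closed window in days relative to the index date (negative = before)."""

    rel_start: int
    rel_end: int

    def __post_init__(self) -> None:
        if self.rel_start > self.rel_end:
            raise ValueError("rel_start must be <= rel_end")

    def contains(self, index_date, d) -> bool:
        offset = (pd.Timestamp(d) - pd.Timestamp(index_date)).days
        return self.rel_start <= offset <= self.rel_end


CONDITION_WINDOW = WindowSpec(-1, 1)
TREATMENT_WINDOW = WindowSpec(-1, 14)


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (2.5 -> 3, −2.5 -> −3) at ``decimals``."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage 100·n/d, rounded half away from zero."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    value = 100 * Decimal(numerator) / Decimal(denominator)
    q = Decimal(1).scaleb(-decimals)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


def per_1000(numerator: int, denominator: int, decimals: int = 2) -> float:
    """Per-1,000 proportion, rounded half away from zero to two decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    value = 1000 * Decimal(numerator) / Decimal(denominator)
    q = Decimal(1).scaleb(-decimals)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CategoryMap:
    """code/product -> category (and, for drugs, class) lookup.

    Unmapped items fall into ``"other"`` rather than erroring, because
    clinically curated category assignments are never exhaustive.
    """

    kind: str  # condition | drug | procedure
    categories: dict[str, str] = field(default_factory=dict)
    classes: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_csv(cls, path, kind: str) -> "CategoryMap":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        key = df.columns[0]
        categories = dict(zip(df[key], df["category"]))
        classes = dict(zip(df[key], df["drug_class"])) if "drug_class" in df.columns else {}
        return cls(kind=kind, categories=categories, classes=classes)

    def category(self, item: str) -> str:
        return self.categories.get(item, "other")

    def drug_class(self, item: str) -> str:
        return self.classes.get(item, "other")


@dataclass
class FrequencyTable:
    """Ranked per-item person counts for one cohort.

    Each person contributes at most once per item; percentages are of the
    cohort size and need not sum to 100 (items are not mutually
    exclusive).  Ranking: person_count descending, then item ascending.
    """

    table: pd.DataFrame  # columns: item, person_count, pct
    cohort_size: int


def _in_window(claims: pd.DataFrame, events: pd.DataFrame, window: WindowSpec,
               date_col: str) -> pd.DataFrame:
    """Join a claim stream to cohort index dates and keep in-window rows."""
    merged = claims.merge(events[["person_id", "index_date"]], on="person_id", how="inner")
    if not len(merged):
        return merged
    offsets = (pd.to_datetime(merged[date_col]) - pd.to_datetime(merged["index_date"])).dt.days
    return merged[(offsets >= window.rel_start) & (offsets <= window.rel_end)]


def windowed_items(
    cohort: Cohort,
    claims: pd.DataFrame,
    window: WindowSpec,
    item: str = "code",
    date_col: str | None = None,
    top_n: int | None = None,
) -> FrequencyTable:
    """Rank items appearing within ``window`` of each person's index date.

    ``claims`` is any claim stream carrying person_id, a date column, and
    the ``item`` column.  The index claim's own code is *not* excluded:
    additional algorithm codes in-window are counted like any other item.
    """
    if date_col is None:
        date_col = "order_date" if "order_date" in claims.columns else "service_date"
    size = cohort.size
    hits = _in_window(claims, cohort.events, window, date_col)
    if not len(hits):
        return FrequencyTable(pd.DataFrame(columns=["item", "person_count", "pct"]), size)
    counts = (
        hits[["person_id", item]].drop_duplicates().groupby(item).size().rename("person_count")
    )
    df = counts.reset_index().rename(columns={item: "item"})
    df = df.sort_values(["person_count", "item"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df["pct"] = [pct(c, size) if size else 0.0 for c in df["person_count"]]
    if top_n is not None:
        df = df.head(top_n).reset_index(drop=True)
    return FrequencyTable(df, size)


def drug_class_table(
    cohort: Cohort,
    drug_claims: pd.DataFrame,
    window: WindowSpec,
    category_map: CategoryMap,
    top_n_products: int = 100,
    restrict_category: str | None = "cardiac",
) -> pd.DataFrame:
    """Drug-class person counts under the top-100-products rule.

    Products are ranked by in-window person count; only the ``top_n_products``
    most common products contribute to class counts (so class totals are a
    floor, not an exhaustive class assessment).  A person counts once per
    class however many of that class's products they received.

    By default only products in the ``cardiac`` treatment category are
    classified (the class table is a cardiac-medication table); products
    mapped to another category are dropped, while products absent from the
    map entirely fall into the ``other`` class.
    """
    size = cohort.size
    hits = _in_window(drug_claims, cohort.events, window, "order_date")
    cols = ["drug_class", "person_count", "pct"]
    if not len(hits):
        return pd.DataFrame(columns=cols)
    pairs = hits[["person_id", "product_code"]].drop_duplicates()
    ranked = (
        pairs.groupby("product_code").size().rename("n").reset_index()
        .sort_values(["n", "product_code"], ascending=[False, True], kind="mergesort")
    )
    top = set(ranked.head(top_n_products)["product_code"])
    pairs = pairs[pairs["product_code"].isin(top)].copy()
    if restrict_category is not None:
        known = pairs["product_code"].map(category_map.categories)
        pairs = pairs[known.isna() | (known == restrict_category)]
    pairs["drug_class"] = pairs["product_code"].map(category_map.drug_class)
    counts = pairs[["person_id", "drug_class"]].drop_duplicates().groupby("drug_class").size()
    df = counts.rename("person_count").reset_index()
    df = df.sort_values(["person_count", "drug_class"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df["pct"] = [pct(c, size) if size else 0.0 for c in df["person_count"]]
    return df[cols]


def multi_code_any(
    cohort: Cohort,
    claims: pd.DataFrame,
    window: WindowSpec,
    code_set: set[str],
    item: str = "procedure_code",
) -> tuple[int, float]:
    """Persons with ≥1 in-window claim whose code is in ``code_set``.

    Returns (person_count, percentage of the cohort).
    """
    if not code_set:
        raise ValueError("code_set must be non-empty")
    date_col = "order_date" if "order_date" in claims.columns else "service_date"
    hits = _in_window(claims, cohort.events, window, date_col)
    hits = hits[hits[item].isin(code_set)]
    n = hits["person_id"].nunique()
    return int(n), pct(int(n), cohort.size) if cohort.size else 0.0


def _median(values: np.ndarray) -> float:
    return float(np.median(values))


def _quartiles_exclusive(values: np.ndarray) -> tuple[float, float]:
    """Median-exclusive quartiles: the medians of the lower and upper
    halves, excluding the overall median itself when n is odd."""
    x = np.sort(values)
    n = len(x)
    if n == 1:
        return float(x[0]), float(x[0])
    half = n // 2
    lower = x[:half]
    upper = x[half + 1:] if n % 2 else x[half:]
    return _median(lower), _median(upper)


@dataclass
class LosSummary:
    """Length-of-stay summary over one linked admission per person."""

    n: int
    mean: float
    sd: float
    median: float
    iqr: tuple[float, float]
    range: tuple[int, int]
    band_props: dict[str, float]
    band_counts: dict[str, int]
    n_unlinked: int = 0


def los_summary(cohort: Cohort, admissions: pd.DataFrame) -> LosSummary:
    """Summarize inpatient length of stay for an inpatient-scope cohort.

    Each person links to the admission containing (or starting on) their
    index date; when several qualify the earliest admit date wins.  Length
    of stay is ``max(1, discharge − admit)`` in days, so same-day stays
    count as one day.  Persons with no linkable admission are excluded and
    counted in ``n_unlinked`` (also logged).
    """
    ev = cohort.events[["person_id", "index_date"]]
    adm = admissions.copy()
    adm["admit_date"] = pd.to_datetime(adm["admit_date"])
    adm["discharge_date"] = pd.to_datetime(adm["discharge_date"])
    merged = ev.merge(adm, on="person_id", how="left")
    merged["index_date"] = pd.to_datetime(merged["index_date"])
    ok = (merged["admit_date"] <= merged["index_date"]) & (
        merged["discharge_date"] >= merged["index_date"]
    )
    linked = merged[ok].sort_values(["person_id", "admit_date"], kind="mergesort")
    linked = linked.groupby("person_id", as_index=False).first()
    n_unlinked = cohort.size - len(linked)
    if n_unlinked:
        logger.info("los_summary: %d of %d cohort persons had no linkable admission",
                    n_unlinked, cohort.size)
    if not len(linked):
        return LosSummary(0, math.nan, math.nan, math.nan, (math.nan, math.nan),
                          (0, 0), {b: math.nan for b in LOS_BAND_LABELS},
                          {b: 0 for b in LOS_BAND_LABELS}, n_unlinked)
    los = (linked["discharge_date"] - linked["admit_date"]).dt.days.clip(lower=1).to_numpy()
    q1, q3 = _quartiles_exclusive(los)
    band_counts: dict[str, int] = {}
    for (lo, hi), label in zip(LOS_BANDS, LOS_BAND_LABELS):
        upper = np.inf if hi is None else hi
        band_counts[label] = int(((los >= lo) & (los <= upper)).sum())
    n = len(los)
    band_props = {k: v / n for k, v in band_counts.items()}
    sd = float(np.std(los, ddof=1)) if n > 1 else 0.0
    return LosSummary(
        n=n,
        mean=float(np.mean(los)),
        sd=sd,
        median=_median(los),
        iqr=(q1, q3),
        range=(int(los.min()), int(los.max())),
        band_props=band_props,
        band_counts=band_counts,
        n_unlinked=n_unlinked,
    )


def gender_age_curve(
    cohort: Cohort,
    population: pd.DataFrame,
    by_bin: bool = False,
) -> pd.DataFrame:
    """Per-1,000 first-diagnosis proportions by gender and age.

    ``population`` is the person-level denominator frame from
    :func:`amiclaims.cohort.eligible_persons` (columns person_id, age,
    gender).  Cases use age at index.  Cells with zero denominator are
    suppressed.  With ``by_bin`` the standard age bins are used instead of
    single years of age.
    """
    cases = cohort.events[["person_id", "age_at_index", "gender"]].rename(
        columns={"age_at_index": "age"}
    )
    pop = population[["person_id", "age", "gender"]]
    if by_bin:
        def to_bin(a):
            for lo, hi in AGE_BINS:
                if a >= lo and (hi is None or a <= hi):
                    return bin_label(lo, hi)
            return bin_label(*AGE_BINS[0])
        cases = cases.assign(age=cases["age"].map(to_bin))
        pop = pop.assign(age=pop["age"].map(to_bin))
    denom = pop.groupby(["gender", "age"]).size().rename("enrollees")
    numer = cases.groupby(["gender", "age"]).size().rename("cases")
    df = pd.concat([denom, numer], axis=1).fillna({"cases": 0}).reset_index()
    df = df[df["enrollees"] > 0]
    df["cases"] = df["cases"].astype(int)
    df["per_1000"] = [per_1000(c, e) for c, e in zip(df["cases"], df["enrollees"])]
    return df.sort_values(["gender", "age"]).reset_index(drop=True)


@dataclass
class DemographicsSummary:
    """Cohort demographics: size, mean age at index (SD), age-bin counts
    and percentages, male count and percentage."""

    size: int
    mean_age: float
    sd_age: float
    bin_counts: dict[str, int]
    bin_pcts: dict[str, float]
    male_count: int
    male_pct: float


def demographics(cohort: Cohort) -> DemographicsSummary:
    ev = cohort.events
    size = len(ev)
    labels = [bin_label(lo, hi) for lo, hi in AGE_BINS]
    if size == 0:
        return DemographicsSummary(0, math.nan, math.nan,
                                   {b: 0 for b in labels}, {b: 0.0 for b in labels}, 0, 0.0)
    ages = ev["age_at_index"].to_numpy()
    bin_counts = {}
    for (lo, hi), label in zip(AGE_BINS, labels):
        upper = np.inf if hi is None else hi
        bin_counts[label] = int(((ages >= lo) & (ages <= upper)).sum())
    male = int((ev["gender"] == "male").sum())
    return DemographicsSummary(
        size=size,
        mean_age=float(np.mean(ages)),
        sd_age=float(np.std(ages, ddof=1)) if size > 1 else 0.0,
        bin_counts=bin_counts,
        bin_pcts={k: pct(v, size) for k, v in bin_counts.items()},
        male_count=male,
        male_pct=pct(male, size),
    )


def demographics_table(cohorts: dict[str, Cohort]) -> pd.DataFrame:
    """Stack per-stratum demographics (e.g. icd9 / icd10 / combined) into
    one frame shaped like a demographics summary table."""
    rows = []
    for stratum, cohort in cohorts.items():
        d = demographics(cohort)
        row: dict[str, object] = {
            "stratum": stratum, "size": d.size,
            "mean_age": round_half_away(d.mean_age, 1) if d.size else math.nan,
            "sd_age": round_half_away(d.sd_age, 1) if d.size else math.nan,
            "male_n": d.male_count, "male_pct": d.male_pct,
        }
        for label in d.bin_counts:
            row[f"age_{label}_n"] = d.bin_counts[label]
            row[f"age_{label}_pct"] = d.bin_pcts[label]
        rows.append(row)
    return pd.DataFrame(rows)


def annual_series(
    bundle: ClaimsBundle,
    codelist: CodeList,
    years: list[int],
    config: StudyConfig | None = None,
    setting_scope: str = "any_healthcare",
) -> pd.DataFrame:
    """Per-year cohort size, denominator, per-1,000 proportion, and (for
    years straddling the era boundary) the ICD version attribution."""
    config = config or StudyConfig()
    rows = []
    for y in years:
        period = QueryPeriod.year(y)
        cohort = build_cohort(bundle, codelist, period, setting_scope, config)
        row: dict[str, object] = {
            "year": y,
            "size": cohort.size,
            "denominator": cohort.denominator,
            "per_1000": per_1000(cohort.size, cohort.denominator) if cohort.denominator else 0.0,
        }
        straddles = period.start < config.era_boundary <= period.end
        if straddles:
            row.update({k: v for k, v in version_attribution(
                bundle, codelist, period, setting_scope, config).items() if k != "total"})
        else:
            era9 = period.end < config.era_boundary
            row.update({"icd9_only": cohort.size if era9 else 0,
                        "icd10_only": 0 if era9 else cohort.size, "both": 0})
        rows.append(row)
    return pd.DataFrame(rows)
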