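"""Administrative-claims data model and flat-file dialect.

A :class:`ClaimsBundle` holds six linked tables (persons, enrollment spans,
diagnosis claims, drug orders, procedure claims, inpatient admissions) as
pandas DataFrames, mirroring the structure of person-linked commercial /
Medicare-supplemental claims databases: encounters across emergency,
laboratory, pharmacy, inpatient and outpatient settings joined on a person
identifier.

Conventions shared by every downstream stage:

* ICD diagnosis codes are stored *undotted and uppercase* ("I21.4" -> "I214");
  dotted forms are accepted on input only.
* All dates are ISO-8601 calendar dates, and every interval in this package
  is closed on both ends.
* Gender is the binary {male, female} coding that claims enrollment files
  carry; age is computed as ``event_year - birth_year``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "Gender",
    "Plan",
    "Setting",
    "Version",
    "Position",
    "ClaimsBundle",
    "TABLE_COLUMNS",
    "normalize_code",
    "read_bundle",
    "write_bundle",
    "validate_bundle",
    "BundleReadError",
]


class Gender(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Plan(str, enum.Enum):
    COMMERCIAL = "commercial"
    MEDICARE_SUPPLEMENTAL = "medicare_supplemental"


class Setting(str, enum.Enum):
    """The nine healthcare settings a claim can carry.

    "Any healthcare setting" analyses use all nine; inpatient-setting
    analyses restrict to :attr:`INPATIENT`.
    """

    EMERGENCY_DEPARTMENT = "emergency_department"
    INPATIENT = "inpatient"
    LAB_TEST = "lab_test"
    NON_DOCTOR_OFFICE_VISIT = "non_doctor_office_visit"
    OTHER_OUTPATIENT = "other_outpatient"
    OTHER_OUTPATIENT_OFFICE_VISIT = "other_outpatient_office_visit"
    PRIMARY_CARE_OFFICE_VISIT = "primary_care_office_visit"
    PHARMACY = "pharmacy"
    SPECIALTY_OFFICE_VISIT = "specialty_office_visit"


class Version(str, enum.Enum):
    ICD9CM = "icd9cm"
    ICD10CM = "icd10cm"


class Position(str, enum.Enum):
    """Diagnosis code position on a claim; recorded but never used for
    cohort inclusion (a code in any position qualifies)."""

    PRINCIPAL = "principal"
    SECONDARY = "secondary"
    UNSPECIFIED = "unspecified"


#: Column layout of the six-file CSV dialect (UTF-8, header row, comma
#: delimited, dates as YYYY-MM-DD).
TABLE_COLUMNS: dict[str, list[str]] = {
    "persons": ["person_id", "birth_year", "gender"],
    "enrollment": ["person_id", "start_date", "end_date", "plan"],
    "diagnoses": ["person_id", "service_date", "code", "version", "position", "setting"],
    "drugs": ["person_id", "order_date", "product_code", "product_name"],
    "procedures": ["person_id", "service_date", "procedure_code", "setting"],
    "admissions": ["person_id", "admit_date", "discharge_date"],
}

_DATE_COLUMNS: dict[str, list[str]] = {
    "persons": [],
    "enrollment": ["start_date", "end_date"],
    "diagnoses": ["service_date"],
    "drugs": ["order_date"],
    "procedures": ["service_date"],
    "admissions": ["admit_date", "discharge_date"],
}

_ENUM_COLUMNS: dict[str, dict[str, type[enum.Enum]]] = {
    "persons": {"gender": Gender},
    "enrollment": {"plan": Plan},
    "diagnoses": {"version": Version, "position": Position, "setting": Setting},
    "drugs": {},
    "procedures": {"setting": Setting},
    "admissions": {},
}


class BundleReadError(ValueError):
    """Raised when a flat file violates the declared dialect."""


def normalize_code(raw: str, version: Version | str | None = None) -> str:
    """Normalize a diagnosis/procedure code for storage and comparison.

    Strips surrounding whitespace, removes the decimal point, and
    uppercases ("I21.4" -> "I214", "410.71" -> "41071").  Idempotent, and
    the two transformations commute.  ``version`` is accepted for interface
    symmetry; the normalization itself is version independent.
    """
    if raw is None or str(raw).strip() == "":
        raise ValueError("cannot normalize an empty code")
    return str(raw).strip().replace(".", "").upper()


@dataclass
class ClaimsBundle:
    """The six linked claims tables, with person-level referential integrity."""

    persons: pd.DataFrame = field(default_factory=lambda: _empty("persons"))
    enrollment: pd.DataFrame = field(default_factory=lambda: _empty("enrollment"))
    diagnoses: pd.DataFrame = field(default_factory=lambda: _empty("diagnoses"))
    drugs: pd.DataFrame = field(default_factory=lambda: _empty("drugs"))
    procedures: pd.DataFrame = field(default_factory=lambda: _empty("procedures"))
    admissions: pd.DataFrame = field(default_factory=lambda: _empty("admissions"))

    def tables(self) -> dict[str, pd.DataFrame]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    def equals(self, other: "ClaimsBundle") -> bool:
        """Record-level equality, insensitive to row order."""
        for name, df in self.tables().items():
            a = _canonical(df, name)
            b = _canonical(getattr(other, name), name)
            if not a.equals(b):
                return False
        return True

    def copy(self) -> "ClaimsBundle":
        return ClaimsBundle(**{k: v.copy() for k, v in self.tables().items()})


def _empty(table: str) -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype="object") for c in TABLE_COLUMNS[table]})
    for c in _DATE_COLUMNS[table]:
        df[c] = pd.Series(dtype="datetime64[ns]")
    if table == "persons":
        df["birth_year"] = pd.Series(dtype="int64")
    return df


def _canonical(df: pd.DataFrame, table: str) -> pd.DataFrame:
    cols = TABLE_COLUMNS[table]
    out = df[cols].copy()
    for c in _DATE_COLUMNS[table]:
        out[c] = pd.to_datetime(out[c]).astype("datetime64[ns]")
    if table == "persons":
        out["birth_year"] = out["birth_year"].astype("int64")
    for c in cols:
        if c not in _DATE_COLUMNS[table] and c != "birth_year":
            out[c] = out[c].astype(str)
    return out.sort_values(cols).reset_index(drop=True)


def _resolve_paths(paths: str | Path | Mapping[str, str | Path]) -> dict[str, Path]:
    if isinstance(paths, (str, Path)):
        base = Path(paths)
        return {name: base / f"{name}.csv" for name in TABLE_COLUMNS}
    return {name: Path(p) for name, p in paths.items()}


def read_bundle(paths: str | Path | Mapping[str, str | Path]) -> ClaimsBundle:
    """Read the six-file bundle, normalizing codes and parsing dates.

    ``paths`` is a directory containing ``persons.csv`` ... ``admissions.csv``
    or an explicit table-name -> path mapping.  Raises
    :class:`BundleReadError` naming the offending table/row for unknown
    enum values or unparseable dates.
    """
    resolved = _resolve_paths(paths)
    frames: dict[str, pd.DataFrame] = {}
    for name, cols in TABLE_COLUMNS.items():
        path = resolved[name]
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise BundleReadError(f"{path}: missing columns {missing}")
        df = df[cols]
        for c in _DATE_COLUMNS[name]:
            parsed = pd.to_datetime(df[c], format="%Y-%m-%d", errors="coerce")
            bad = df.index[parsed.isna() & (df[c] != "")]
            if len(bad) and len(df):
                i = int(bad[0])
                raise BundleReadError(
                    f"{path}: unparseable date {df.loc[i, c]!r} in column {c!r}, row {i + 2}"
                )
            df[c] = parsed
        for c, enum_cls in _ENUM_COLUMNS[name].items():
            allowed = {e.value for e in enum_cls}
            bad = df.index[~df[c].isin(allowed)]
            if len(bad):
                i = int(bad[0])
                raise BundleReadError(
                    f"{path}: unknown {c} value {df.loc[i, c]!r} in row {i + 2}"
                )
        frames[name] = df
    if len(frames["persons"]):
        frames["persons"]["birth_year"] = frames["persons"]["birth_year"].astype("int64")
    else:
        frames["persons"] = _empty("persons")
    for name in TABLE_COLUMNS:
        if not len(frames[name]):
            frames[name] = _empty(name)
    b = ClaimsBundle(**frames)
    if len(b.diagnoses):
        b.diagnoses["code"] = b.diagnoses["code"].map(normalize_code)
    if len(b.procedures):
        b.procedures["procedure_code"] = b.procedures["procedure_code"].map(normalize_code)
    return b


def write_bundle(bundle: ClaimsBundle, paths: str | Path | Mapping[str, str | Path]) -> None:
    """Write the bundle in the declared dialect; round-trips through
    :func:`read_bundle` record-for-record."""
    resolved = _resolve_paths(paths)
    for name, df in bundle.tables().items():
        path = resolved[name]
        path.parent.mkdir(parents=True, exist_ok=True)
        out = df[TABLE_COLUMNS[name]].copy()
        for c in _DATE_COLUMNS[name]:
            out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)


def validate_bundle(bundle: ClaimsBundle, last_study_year: int = 2100) -> list[str]:
    """Check type invariants and referential integrity.

    Returns a list of human-readable violations (empty iff the bundle is
    valid).  Violations are returned rather than raised so callers can
    audit a whole bundle in one pass.
    """
    v: list[str] = []
    persons = bundle.persons
    ids = persons["person_id"]
    dup = ids[ids.duplicated()]
    for pid in dup.unique():
        v.append(f"persons: duplicate person_id {pid!r}")
    if len(persons):
        bad_year = persons[(persons["birth_year"] < 1900) | (persons["birth_year"] > last_study_year)]
        for _, row in bad_year.iterrows():
            v.append(f"persons: birth_year {row.birth_year} out of range for {row.person_id!r}")
        bad_gender = persons[~persons["gender"].isin({g.value for g in Gender})]
        for _, row in bad_gender.iterrows():
            v.append(f"persons: unknown gender {row.gender!r} for {row.person_id!r}")
    known = set(ids)
    for name in ("enrollment", "diagnoses", "drugs", "procedures", "admissions"):
        df = getattr(bundle, name)
        orphans = df.loc[~df["person_id"].isin(known), "person_id"]
        for pid in orphans.unique():
            v.append(f"{name}: person_id {pid!r} not in persons")
    enr = bundle.enrollment
    if len(enr):
        bad = enr[pd.to_datetime(enr["start_date"]) > pd.to_datetime(enr["end_date"])]
        for i, row in bad.iterrows():
            v.append(f"enrollment: start_date after end_date for {row.person_id!r} (row {i})")
    adm = bundle.admissions
    if len(adm):
        bad = adm[pd.to_datetime(adm["admit_date"]) > pd.to_datetime(adm["discharge_date"])]
        for i, row in bad.iterrows():
            v.append(f"admissions: discharge before admit for {row.person_id!r} (row {i})")
    dx = bundle.diagnoses
    if len(dx):
        raw = dx["code"].astype(str)
        bad = dx[(raw != raw.str.upper()) | raw.str.contains(".", regex=False)]
        for i, row in bad.iterrows():
            v.append(f"diagnoses: code {row.code!r} not normalized (row {i})")
        bad_setting = dx[~dx["setting"].isin({s.value for s in Setting})]
        for i, row in bad_setting.iterrows():
            v.append(f"diagnoses: unknown setting {row.setting!r} (row {i})")
    proc = bundle.procedures
    if len(proc):
        empty = proc[proc["procedure_code"].astype(str).str.strip() == ""]
        for i, row in empty.iterrows():
            v.append(f"procedures: empty procedure_code (row {i})")
    return v
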