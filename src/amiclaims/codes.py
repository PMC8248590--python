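"""Diagnosis code lists, wildcard patterns, and GEM crosswalk mapping.

Two pieces of machinery live here:

* **Wildcard code patterns** — the compact "410.x0" / "I21.xx" notation used
  to define a phenotyping algorithm.  Each lowercase ``x`` matches exactly
  one character; a *trailing* run of wildcards additionally matches absence,
  so ``I21.xx`` covers the whole I21 family (I21, I21x, I21xx shapes) and
  ``I22.x`` covers both I22 and its four-character children.

* **Forward-backward mapping** over the CMS General Equivalence Mappings
  (GEMs): translate a seed set of ICD-9-CM codes to ICD-10-CM (forward),
  then translate the resulting ICD-10-CM codes back (backward) to surface
  related codes with no one-to-one equivalent.  The output is a flat
  candidate list with per-code mapping flags, intended for clinical review,
  not an automatically adjudicated code list.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .model import Version, normalize_code

__all__ = [
    "CodePattern",
    "CodeList",
    "GemEntry",
    "GemTable",
    "GemDirection",
    "MappingReport",
    "expand_pattern",
    "matches",
    "parse_gem",
    "forward_backward",
    "load_ami_codelist",
]

WILDCARD = "x"


def _normalize_pattern(raw: str) -> str:
    # Uppercase everything except the wildcard character itself.
    s = str(raw).strip().replace(".", "")
    if not s:
        raise ValueError("empty code pattern")
    return "".join(c if c == WILDCARD else c.upper() for c in s)


@dataclass(frozen=True)
class CodePattern:
    """A wildcard diagnosis-code pattern tied to one ICD version."""

    pattern: str
    version: Version
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", _normalize_pattern(self.pattern))
        object.__setattr__(self, "version", Version(self.version))

    def regex(self) -> re.Pattern[str]:
        body = self.pattern
        n_trailing = len(body) - len(body.rstrip(WILDCARD))
        head = body[: len(body) - n_trailing]
        parts = ["." if c == WILDCARD else re.escape(c) for c in head]
        if n_trailing:
            parts.append(".{0,%d}" % n_trailing)
        return re.compile("".join(parts) + r"\Z")

    def matches(self, code: str) -> bool:
        return self.regex().match(code) is not None


def expand_pattern(pattern: CodePattern, universe: Iterable[str]) -> set[str]:
    """Members of ``universe`` matched by ``pattern`` (codes must already be
    normalized).  Always a subset of the universe; monotone in it."""
    rx = pattern.regex()
    return {c for c in universe if rx.match(c)}


@dataclass(frozen=True)
class CodeList:
    """A named set of wildcard patterns defining a claims algorithm."""

    name: str
    patterns: tuple[CodePattern, ...]
    provenance: str = ""

    def patterns_for(self, version: Version | str) -> tuple[CodePattern, ...]:
        version = Version(version)
        return tuple(p for p in self.patterns if p.version == version)

    def regex_for(self, version: Version | str) -> re.Pattern[str]:
        pats = self.patterns_for(version)
        if not pats:
            return re.compile(r"(?!)")  # matches nothing
        return re.compile("|".join(f"(?:{p.regex().pattern})" for p in pats))

    def matches(self, code: str, version: Version | str) -> bool:
        return any(p.matches(code) for p in self.patterns_for(version))

    def expand(self, universe: Iterable[str], version: Version | str) -> set[str]:
        universe = set(universe)
        out: set[str] = set()
        for p in self.patterns_for(version):
            out |= expand_pattern(p, universe)
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CodeList":
        data = yaml.safe_load(Path(path).read_text())
        patterns = tuple(
            CodePattern(e["pattern"], Version(e["version"]), e.get("description", ""))
            for e in data["patterns"]
        )
        return cls(name=data["name"], patterns=patterns, provenance=data.get("provenance", ""))


def matches(code: str, version: Version | str, codelist: CodeList) -> bool:
    """True iff any same-version pattern in ``codelist`` matches ``code``."""
    return codelist.matches(code, version)


def load_ami_codelist() -> CodeList:
    """The packaged AMI algorithm: 410.x0 and 410.x1 (ICD-9-CM), I21.xx and
    I22.x (ICD-10-CM).  Subsequent-episode (410.x2), old-MI, angina and
    chronic ischaemic heart disease codes are deliberately absent."""
    from importlib.resources import files

    with files("amiclaims").joinpath("data/ami_codelist.yaml").open() as fh:
        data = yaml.safe_load(fh)
    patterns = tuple(
        CodePattern(e["pattern"], Version(e["version"]), e.get("description", ""))
        for e in data["patterns"]
    )
    return CodeList(name=data["name"], patterns=patterns, provenance=data.get("provenance", ""))


# ---------------------------------------------------------------------------
# GEM crosswalk


class GemDirection(str, enum.Enum):
    ICD9_TO_ICD10 = "icd9_to_icd10"
    ICD10_TO_ICD9 = "icd10_to_icd9"


_OPPOSITE = {
    GemDirection.ICD9_TO_ICD10: GemDirection.ICD10_TO_ICD9,
    GemDirection.ICD10_TO_ICD9: GemDirection.ICD9_TO_ICD10,
}


@dataclass(frozen=True)
class GemEntry:
    """One GEM line: source code, target code, and the five positional flags
    (approximate, no-map, combination, scenario, choice list)."""

    source: str
    target: str
    approximate: int
    no_map: int
    combination: int
    scenario: int
    choice_list: int


@dataclass
class GemTable:
    direction: GemDirection
    entries: list[GemEntry] = field(default_factory=list)

    @property
    def source_version(self) -> Version:
        return Version.ICD9CM if self.direction == GemDirection.ICD9_TO_ICD10 else Version.ICD10CM

    @property
    def target_version(self) -> Version:
        return Version.ICD10CM if self.direction == GemDirection.ICD9_TO_ICD10 else Version.ICD9CM

    def mapping(self) -> dict[str, list[GemEntry]]:
        out: dict[str, list[GemEntry]] = {}
        for e in self.entries:
            out.setdefault(e.source, []).append(e)
        return out


def _looks_icd10(code: str) -> bool:
    # ICD-10-CM: letter + digit prefix; ICD-9-CM is numeric or E/V + digits
    # with total length <= 5.
    return len(code) >= 3 and code[0].isalpha() and code[1].isdigit() and not (
        code[0] in "EV" and code[1:].isdigit() and len(code) <= 5
    )


def parse_gem(path: str | Path, direction: GemDirection | str | None = None) -> GemTable:
    """Parse a CMS-style GEM flat file (source, target, 5-digit flag string
    per line, whitespace separated).

    ``direction`` may be given explicitly; otherwise it is inferred from the
    shape of the source codes (ICD-10-CM codes start letter+digit).
    Malformed flag strings raise with the offending line number.
    """
    entries: list[GemEntry] = []
    sources: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) != 3:
            raise ValueError(f"{path}: line {lineno}: expected 'source target flags', got {line!r}")
        src, tgt, flags = tokens
        if len(flags) != 5 or not flags.isdigit():
            raise ValueError(f"{path}: line {lineno}: flag string {flags!r} is not 5 digits")
        src = normalize_code(src)
        tgt = normalize_code(tgt)
        entries.append(
            GemEntry(
                source=src,
                target=tgt,
                approximate=int(flags[0]),
                no_map=int(flags[1]),
                combination=int(flags[2]),
                scenario=int(flags[3]),
                choice_list=int(flags[4]),
            )
        )
        sources.append(src)
    if direction is None:
        n10 = sum(_looks_icd10(s) for s in sources)
        direction = (
            GemDirection.ICD10_TO_ICD9 if sources and n10 * 2 >= len(sources) else GemDirection.ICD9_TO_ICD10
        )
    return GemTable(direction=GemDirection(direction), entries=entries)


@dataclass
class MappingReport:
    """Outcome of a forward-backward crosswalk pass.

    ``newly_discovered`` are backward-mapped source-version codes outside
    the seed — the candidates the procedure exists to surface.
    ``flags_per_code`` records, for every code touched, the GEM entries
    (with flags) that introduced it, as review provenance.
    """

    seed_codes: frozenset[str]
    forward_set: frozenset[str]
    backward_set: frozenset[str]
    newly_discovered: frozenset[str]
    flags_per_code: dict[str, list[dict]]
    iterations: int = 1

    def to_dict(self) -> dict:
        return {
            "seed_codes": sorted(self.seed_codes),
            "forward_set": sorted(self.forward_set),
            "backward_set": sorted(self.backward_set),
            "newly_discovered": sorted(self.newly_discovered),
            "iterations": self.iterations,
        }

    def to_frame(self):
        import pandas as pd

        rows = []
        for code, provs in sorted(self.flags_per_code.items()):
            for p in provs:
                rows.append({"code": code, **p})
        return pd.DataFrame(rows, columns=["code", "role", "direction", "source", "target",
                                           "approximate", "no_map", "combination",
                                           "scenario", "choice_list"])


def _apply(
    codes: Iterable[str],
    table: GemTable,
    flags_per_code: dict[str, list[dict]],
    role: str,
) -> set[str]:
    mapping = table.mapping()
    out: set[str] = set()
    for code in sorted(set(codes)):
        for e in mapping.get(code, []):
            prov = {
                "role": role,
                "direction": table.direction.value,
                "source": e.source,
                "target": e.target,
                "approximate": e.approximate,
                "no_map": e.no_map,
                "combination": e.combination,
                "scenario": e.scenario,
                "choice_list": e.choice_list,
            }
            # no-map entries are surfaced for review but contribute no code
            key = e.source if e.no_map else e.target
            flags_per_code.setdefault(key, []).append(prov)
            if not e.no_map:
                out.add(e.target)
    return out


def forward_backward(
    seed: Iterable[str],
    forward: GemTable,
    backward: GemTable,
    iterations: int = 1,
) -> MappingReport:
    """Forward-backward crosswalk of a seed code set.

    Forward-map the seed, backward-map the result, and report codes the
    round trip discovered beyond the seed.  With ``iterations > 1`` the
    newly discovered source-version codes are fed back through the forward
    step until the requested number of passes (or a fixed point); at the
    limit this equals transitive reachability over the two GEM relations.
    Deterministic and independent of seed iteration order.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if _OPPOSITE[forward.direction] != backward.direction:
        raise ValueError(
            f"forward ({forward.direction.value}) and backward ({backward.direction.value}) "
            "tables must have opposite directions"
        )
    seed_set = frozenset(normalize_code(c) for c in seed)
    flags: dict[str, list[dict]] = {}
    forward_set: set[str] = set()
    backward_set: set[str] = set()
    fed: set[str] = set(seed_set)
    frontier: set[str] = set(seed_set)
    for _ in range(iterations):
        if not frontier:
            break
        new_fwd = _apply(frontier, forward, flags, role="forward")
        fwd_frontier = new_fwd - forward_set
        forward_set |= new_fwd
        new_back = _apply(fwd_frontier, backward, flags, role="backward")
        backward_set |= new_back
        frontier = new_back - fed
        fed |= frontier
    return MappingReport(
        seed_codes=seed_set,
        forward_set=frozenset(forward_set),
        backward_set=frozenset(backward_set),
        newly_discovered=frozenset(backward_set - seed_set),
        flags_per_code=flags,
        iterations=iterations,
    )
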