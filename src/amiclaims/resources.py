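"""Accessors for the packaged reference fixtures: the AMI code list,
category maps, toy GEM files, and generator profiles.

The GEM fixtures are synthetic desk-scale stand-ins for the CMS General
Equivalence Mapping releases (which are inputs, not package contents).
"""

from __future__ import annotations

from importlib.resources import as_file, files
from pathlib import Path

from .characterize import CategoryMap
from .codes import GemDirection, GemTable, parse_gem

__all__ = [
    "data_path",
    "load_condition_categories",
    "load_drug_classes",
    "load_procedure_categories",
    "load_toy_gems",
    "EKG_CODE_SET",
]

#: CPT codes for routine electrocardiogram services: interpretation and
#: report only, tracing only, tracing with interpretation and report.
EKG_CODE_SET: frozenset[str] = frozenset({"93010", "93005", "93000"})


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file (for handing to CLIs)."""
    res = files("amiclaims").joinpath(f"data/{name}")
    with as_file(res) as p:
        return Path(p)


def load_condition_categories() -> CategoryMap:
    return CategoryMap.from_csv(data_path("condition_categories.csv"), kind="condition")


def load_drug_classes() -> CategoryMap:
    return CategoryMap.from_csv(data_path("drug_classes.csv"), kind="drug")


def load_procedure_categories() -> CategoryMap:
    return CategoryMap.from_csv(data_path("procedure_categories.csv"), kind="procedure")


def load_toy_gems() -> tuple[GemTable, GemTable]:
    """(forward, backward) toy GEM tables."""
    fwd = parse_gem(data_path("gem_toy_forward.txt"), GemDirection.ICD9_TO_ICD10)
    back = parse_gem(data_path("gem_toy_backward.txt"), GemDirection.ICD10_TO_ICD9)
    return fwd, back
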