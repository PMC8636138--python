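"""The hepatotoxicity event universe and its clinical categories.

Hepatotoxicity-related adverse events are defined on MedDRA preferred
terms (PTs) by a double criterion: a PT belongs to the event universe
iff it is in at least one of two Standardized MedDRA Queries ("liver
injury", "acute hepatic failure") AND in the hepatobiliary-disorders
System Organ Class.  The selected PTs are further grouped by dominant
clinical feature into hepatocellular injury, cholestasis and liver
failure; PTs outside those three lists stay ``uncategorized``.

MedDRA itself is licensed, so the catalog is user-supplied
configuration (a TSV).  The packaged catalog covers the 31 PTs of the
published all-PPI signal table with their category assignments; it is a
partial reconstruction, not the full 40-PT SMQ/SOC intersection.
PT comparison is case-insensitive exact text match throughout.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import AbstractSet, Iterable

CATEGORIES = ("hepatocellular_injury", "cholestasis", "liver_failure", "uncategorized")


def _canon(pt: str) -> str:
    return " ".join(str(pt).split()).casefold()


def select_pts(
    smq_a: AbstractSet[str], smq_b: AbstractSet[str], soc: AbstractSet[str]
) -> set[str]:
    """(smq_a | smq_b) & soc, case-insensitively; returns SOC spellings."""
    in_smq = {_canon(p) for p in smq_a} | {_canon(p) for p in smq_b}
    return {p for p in soc if _canon(p) in in_smq}


@dataclass
class PTCatalog:
    """The event universe plus per-PT clinical category.

    ``pts`` is always the SMQ-union intersected with the SOC set; the
    constructor enforces that and that every selected PT carries exactly
    one category.
    """

    smq_liver_injury: set[str]
    smq_acute_hepatic_failure: set[str]
    soc_hepatobiliary: set[str]
    category: dict[str, str]
    pts: set[str] = field(init=False)
    _canon_category: dict[str, str] = field(init=False, repr=False)
    _canon_pts: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.pts = select_pts(self.smq_liver_injury, self.smq_acute_hepatic_failure, self.soc_hepatobiliary)
        self._canon_pts = {_canon(p): p for p in self.pts}
        cat = {_canon(p): c for p, c in self.category.items()}
        self._canon_category = {}
        for p in self.pts:
            c = cat.get(_canon(p), "uncategorized")
            if c not in CATEGORIES:
                raise ValueError(f"unknown category {c!r} for PT {p!r}")
            self._canon_category[_canon(p)] = c

    def __contains__(self, pt: str) -> bool:
        return _canon(pt) in self._canon_pts

    def sorted_pts(self) -> list[str]:
        return sorted(self.pts)

    def categorize(self, pt: str) -> str:
        return categorize_pt(pt, self)

    @classmethod
    def from_tsv(cls, path) -> "PTCatalog":
        """Load a catalog TSV: pt, smq/soc membership flags, category."""
        smq_a: set[str] = set()
        smq_b: set[str] = set()
        soc: set[str] = set()
        category: dict[str, str] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            needed = {"pt", "smq_liver_injury", "smq_acute_hepatic_failure", "soc_hepatobiliary", "category"}
            if reader.fieldnames is None or needed - set(reader.fieldnames):
                raise ValueError(f"{path}: catalog TSV must have columns {sorted(needed)}")
            for row in reader:
                pt = row["pt"].strip()
                if row["smq_liver_injury"] == "1":
                    smq_a.add(pt)
                if row["smq_acute_hepatic_failure"] == "1":
                    smq_b.add(pt)
                if row["soc_hepatobiliary"] == "1":
                    soc.add(pt)
                category[pt] = row["category"].strip() or "uncategorized"
        return cls(smq_a, smq_b, soc, category)


def builtin_hepatotoxicity_catalog() -> PTCatalog:
    """The packaged 31-PT hepatotoxicity catalog."""
    with resources.as_file(resources.files("pvsignal.data") / "hepatotoxicity_catalog.tsv") as p:
        return PTCatalog.from_tsv(p)


def categorize_pt(pt: str, catalog: PTCatalog) -> str:
    """Clinical category of ``pt``; error if the PT is outside the universe."""
    key = _canon(pt)
    if key not in catalog._canon_pts:
        raise KeyError(f"PT {pt!r} is not in the event universe")
    return catalog._canon_category[key]
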