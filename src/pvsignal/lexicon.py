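"""Drug-name normalisation and brand-to-generic mapping.

FAERS drug entries are verbatim free text ("Protonix 40 mg tablet",
"PANTOPRAZOLE SODIUM").  Mining a target drug therefore needs (i) a
deterministic normaliser collapsing formatting, dose and salt-form
noise, and (ii) a lexicon mapping brand names and spellings to generic
names.  Matching is exact after normalisation — no fuzzy matching — so
every mapping decision is auditable.

Exposure to a target generic is restricted, by default, to drug entries
carrying a suspect role (PS or SS); concomitant and interacting entries
do not count as exposure.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .faers_model import Report, ReportSet

#: sentinel returned when nothing survives normalisation
UNMAPPABLE = ""

#: suspect roles used for exposure by default
SUSPECT_ROLES = frozenset({"PS", "SS"})

#: trailing tokens stripped during normalisation: dose units, dosage
#: forms, salt/ester forms and release-modifier codes.  Configuration,
#: not ground truth — extend per dataset.
DEFAULT_STOP_TOKENS = frozenset(
    {
        "MG", "MCG", "G", "ML", "MG/ML", "IU",
        "TABLET", "TABLETS", "TAB", "TABS", "CAPSULE", "CAPSULES", "CAP", "CAPS",
        "INJECTION", "INJ", "SOLUTION", "SUSPENSION", "ORAL", "IV", "GRANULES",
        "DR", "ER", "XR", "SR", "EC", "ODT", "DELAYED", "RELEASE",
        "SODIUM", "MAGNESIUM", "STRONTIUM", "POTASSIUM", "CALCIUM",
        "SESQUIHYDRATE", "TRIHYDRATE", "MONOHYDRATE", "HYDRATE", "ANHYDROUS",
    }
)

_DOSE_RE = re.compile(r"^\d+(\.\d+)?(MG|MCG|G|ML|IU)?$")
_PUNCT_RE = re.compile(r"[.,\-/()]")
_WS_RE = re.compile(r"\s+")


def normalize_name(raw: str, stop_tokens: frozenset[str] = DEFAULT_STOP_TOKENS) -> str:
    """Canonicalise a free-text drug name.

    Uppercases, trims, collapses whitespace, strips punctuation, then
    repeatedly removes trailing dose/form/salt tokens.  Returns
    :data:`UNMAPPABLE` (the empty string) when nothing survives.
    """
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return UNMAPPABLE
    text = _PUNCT_RE.sub(" ", str(raw).upper())
    tokens = _WS_RE.split(text.strip())
    while tokens and (tokens[-1] in stop_tokens or _DOSE_RE.match(tokens[-1])):
        tokens.pop()
    return " ".join(t for t in tokens if t) if tokens else UNMAPPABLE


@dataclass
class DrugLexicon:
    """Mapping generic name -> set of synonyms (brands + spellings).

    All names are stored in canonical (normalised) form.  Every generic
    is its own synonym, and no synonym may point at two generics.
    """

    entries: dict[str, set[str]] = field(default_factory=dict)
    _reverse: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        normalised: dict[str, set[str]] = {}
        reverse: dict[str, str] = {}
        for generic, synonyms in self.entries.items():
            g = normalize_name(generic)
            if g == UNMAPPABLE:
                raise ValueError(f"generic name {generic!r} normalises to nothing")
            syns = {normalize_name(s) for s in synonyms} | {g}
            syns.discard(UNMAPPABLE)
            for s in syns:
                if reverse.get(s, g) != g:
                    raise ValueError(f"synonym {s!r} maps to both {reverse[s]!r} and {g!r}")
                reverse[s] = g
            normalised[g] = syns
        self.entries = normalised
        self._reverse = reverse

    @property
    def generics(self) -> tuple[str, ...]:
        return tuple(sorted(self.entries))

    @classmethod
    def from_tsv(cls, path) -> "DrugLexicon":
        """Load a two-column TSV with header ``generic<TAB>synonym``."""
        entries: dict[str, set[str]] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None or {"generic", "synonym"} - set(reader.fieldnames):
                raise ValueError(f"{path}: expected columns 'generic' and 'synonym'")
            for row in reader:
                entries.setdefault(row["generic"], set()).add(row["synonym"])
        return cls(entries=entries)

    def to_tsv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["generic", "synonym"])
            for generic in sorted(self.entries):
                for syn in sorted(self.entries[generic]):
                    writer.writerow([generic, syn])


def builtin_ppi_lexicon() -> DrugLexicon:
    """The packaged proton-pump-inhibitor lexicon (7 generics with brands)."""
    with resources.as_file(resources.files("pvsignal.data") / "ppi_lexicon.tsv") as p:
        return DrugLexicon.from_tsv(p)


def map_to_generic(name: str, lexicon: DrugLexicon) -> str | None:
    """Exact lookup of a normalised name; ``None`` when unmatched."""
    if name == UNMAPPABLE:
        return None
    return lexicon._reverse.get(name)


def flag_exposure(
    report: Report,
    generic: str,
    lexicon: DrugLexicon,
    roles: frozenset[str] = SUSPECT_ROLES,
) -> bool:
    """True iff some drug entry maps to ``generic`` with a role in ``roles``."""
    target = normalize_name(generic)
    for name, role in report.drugs:
        if role in roles and map_to_generic(normalize_name(name), lexicon) == target:
            return True
    return False


def map_drug_names(drugs: pd.DataFrame, lexicon: DrugLexicon) -> pd.Series:
    """Vectorised generic mapping for a long drug frame; NA when unmatched."""
    unique = drugs["drugname"].dropna().unique()
    mapping = {raw: map_to_generic(normalize_name(raw), lexicon) for raw in unique}
    return drugs["drugname"].map(mapping)


def exposure_mask(
    rs: ReportSet,
    lexicon: DrugLexicon,
    generics: Iterable[str] | None = None,
    roles: frozenset[str] = SUSPECT_ROLES,
) -> pd.Series:
    """Boolean Series over ``rs.primaryids``: exposed to any of ``generics``.

    ``generics=None`` means any generic in the lexicon (the pooled
    target-class exposure).
    """
    drugs = rs.drugs
    generic = map_drug_names(drugs, lexicon)
    if generics is None:
        wanted = generic.notna()
    else:
        targets = {normalize_name(g) for g in generics}
        wanted = generic.isin(targets)
    hit = drugs.loc[wanted & drugs["role_cod"].isin(roles), "primaryid"]
    mask = pd.Series(False, index=rs.primaryids)
    mask.loc[mask.index.isin(set(hit))] = True
    return mask
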