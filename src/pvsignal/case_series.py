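"""Case-series profiling of the reports behind one (drug, PT) pair.

Once a signal is flagged, the underlying reports are profiled the way a
clinical case series is: yearly report counts, sex and age structure,
how many other medications were co-reported, and which indications the
drugs were given for.  Percentages are rounded half-away-from-zero to
two decimals, the convention used in published report tables.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd

from .faers_model import ReportSet
from .lexicon import DrugLexicon, SUSPECT_ROLES, UNMAPPABLE, exposure_mask, map_to_generic, normalize_name

#: the FAERS literal kept as its own indication category
UNKNOWN_INDICATION = "PRODUCT USED FOR UNKNOWN INDICATION"

AGE_BINS = ("<18", "18-<35", "35-<60", ">=60", "unknown")
SEX_BINS = ("M", "F", "unknown")
CONCOMITANT_BINS = ("0", "1", "2", "3", ">3")


def round2(value: float) -> float:
    """Round to 2 decimals, halves away from zero."""
    return float(Decimal(repr(float(value))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def percentages(counts: Mapping[str, int], total: int | None = None) -> dict[str, float]:
    """Per-category percentages of ``counts`` under the rounding rule."""
    n = sum(counts.values()) if total is None else total
    if n == 0:
        return {k: 0.0 for k in counts}
    return {k: round2(100.0 * v / n) for k, v in counts.items()}


@dataclass
class CaseSeriesSummary:
    """Counts and percentages describing one case series."""

    n_reports: int
    by_year: dict[int, int] = field(default_factory=dict)
    by_sex: dict[str, int] = field(default_factory=dict)
    by_sex_pct: dict[str, float] = field(default_factory=dict)
    by_age_bin: dict[str, int] = field(default_factory=dict)
    by_age_bin_pct: dict[str, float] = field(default_factory=dict)
    concomitant_bins: dict[str, int] = field(default_factory=dict)
    concomitant_bins_pct: dict[str, float] = field(default_factory=dict)
    top_concomitants: list[tuple[str, int]] = field(default_factory=list)
    top_indications: list[tuple[str, int]] = field(default_factory=list)


def extract_case_series(
    rs: ReportSet,
    lexicon: DrugLexicon,
    generic: str,
    pt: str,
    roles: frozenset[str] = SUSPECT_ROLES,
) -> ReportSet:
    """Reports exposed to ``generic`` (in ``roles``) that mention ``pt``."""
    exposed = exposure_mask(rs, lexicon, generics=[generic], roles=roles)
    key = " ".join(pt.split()).casefold()
    with_pt = set(rs.reactions.loc[rs.reactions["pt"].str.casefold().str.strip() == key, "primaryid"])
    ids = [pid for pid, ok in exposed.items() if ok and pid in with_pt]
    return rs.subset(ids)


def _age_bin(age: float | None) -> str:
    if age is None or pd.isna(age):
        return "unknown"
    if age < 18:
        return "<18"
    if age < 35:
        return "18-<35"
    if age < 60:
        return "35-<60"
    return ">=60"


def summarize_demographics(subset: ReportSet) -> CaseSeriesSummary:
    """Year, sex and age structure of a case series (empty-safe)."""
    n = len(subset)
    summary = CaseSeriesSummary(n_reports=n)
    years = subset.reports["year"].dropna().astype(int)
    summary.by_year = {int(y): int(c) for y, c in years.value_counts().sort_index().items()}

    sex = subset.reports["sex"].map(lambda s: s if s in ("M", "F") else "unknown")
    sex_counts = sex.value_counts()
    summary.by_sex = {k: int(sex_counts.get(k, 0)) for k in SEX_BINS}
    summary.by_sex_pct = percentages(summary.by_sex, n)

    bins = subset.reports["age_years"].map(_age_bin)
    bin_counts = bins.value_counts()
    summary.by_age_bin = {k: int(bin_counts.get(k, 0)) for k in AGE_BINS}
    summary.by_age_bin_pct = percentages(summary.by_age_bin, n)
    return summary


def summarize_concomitants(
    subset: ReportSet, lexicon: DrugLexicon, generic: str, top_k: int = 10
) -> tuple[dict[str, int], dict[str, float], list[tuple[str, int]]]:
    """Concomitant-medication bins and the most frequent co-reported drugs.

    Per report, the count is over distinct normalised drug names that do
    not map to the target generic, regardless of role (role codes on
    concomitants are unreliable in spontaneous reports).  Bins are
    {0 (the target alone), 1, 2, 3, >3}; frequencies are report-level.
    """
    target = normalize_name(generic)
    n = len(subset)
    per_report: dict[str, set[str]] = {pid: set() for pid in subset.primaryids}
    for pid, raw in subset.drugs[["primaryid", "drugname"]].itertuples(index=False):
        name = normalize_name(raw)
        if name == UNMAPPABLE:
            continue
        if map_to_generic(name, lexicon) == target:
            continue
        per_report[pid].add(name)

    bins = Counter()
    freq: Counter[str] = Counter()
    for names in per_report.values():
        k = len(names)
        bins[CONCOMITANT_BINS[k] if k <= 3 else ">3"] += 1
        freq.update(names)
    counts = {k: int(bins.get(k, 0)) for k in CONCOMITANT_BINS}
    ranked = sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    return counts, percentages(counts, n), ranked


def top_indications(subset: ReportSet, k: int) -> list[tuple[str, int]]:
    """Indication PTs ranked by report frequency, ties alphabetical.

    A report with no usable indication entries counts once under the
    literal unknown-indication category, which is kept as a category of
    its own rather than dropped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seen: dict[str, set[str]] = {pid: set() for pid in subset.primaryids}
    for pid, ipt in subset.indications[["primaryid", "indi_pt"]].itertuples(index=False):
        if ipt is None or pd.isna(ipt) or not str(ipt).strip():
            continue
        seen[pid].add(" ".join(str(ipt).upper().split()))
    freq: Counter[str] = Counter()
    for pid, terms in seen.items():
        if not terms:
            freq[UNKNOWN_INDICATION] += 1
        else:
            freq.update(terms)
    ranked = sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def summarize_case_series(
    rs: ReportSet,
    lexicon: DrugLexicon,
    generic: str,
    pt: str,
    roles: frozenset[str] = SUSPECT_ROLES,
    top_k: int = 10,
) -> CaseSeriesSummary:
    """Full profile for one (drug, PT) pair."""
    subset = extract_case_series(rs, lexicon, generic, pt, roles)
    summary = summarize_demographics(subset)
    counts, pct, ranked = summarize_concomitants(subset, lexicon, generic, top_k)
    summary.concomitant_bins = counts
    summary.concomitant_bins_pct = pct
    summary.top_concomitants = ranked
    summary.top_indications = top_indications(subset, top_k)
    return summary
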