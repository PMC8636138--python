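"""Reporting-odds-ratio disproportionality statistics.

For each (drug exposure, preferred term) pair the deduplicated report
set is cross-classified as a 2x2 table::

                      PT reported     other events only
    exposed               a                  b
    not exposed           c                  d

The reporting odds ratio is the cross-product ratio

    ROR = (a * d) / (b * c)

with the Wald 95% confidence interval on the log scale,

    exp( ln ROR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d) ).

When any cell is zero the Haldane–Anscombe correction adds 0.5 to all
four cells (the result is flagged ``corrected``).  Statistical support
is assessed with the Pearson chi-square on 1 df, without continuity
correction by default.

Signal classification: a PT is a signal when it has at least
``min_reports`` exposed cases and its disproportionality exceeds 1 —
under the default ``ci_lower`` rule the CI lower bound must exceed 1
(the literal point-estimate rule, ROR > 1, is available by
configuration); a signal is *strong* when additionally ROR >= 5.
An ROR measures reporting disproportionality, not risk: there is no
denominator in a spontaneous-report database.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from .event_catalog import PTCatalog, _canon
from .faers_model import ReportSet
from .lexicon import DrugLexicon, SUSPECT_ROLES, exposure_mask

Z_95 = 1.96  # the conventional two-sided 95% normal quantile used in ROR mining


@dataclass(frozen=True)
class ContingencyTable:
    """The 2x2 cell counts for one (exposure, PT) pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class SignalThresholds:
    """Signal-detection thresholds.

    min_reports: minimum exposed case count ``a`` (default 3).
    strong_ror: point-estimate cut for a strong signal (default 5).
    rule: ``ci_lower`` requires the CI lower bound > 1; the literal
        ``point_estimate`` rule requires only ROR > 1.
    """

    min_reports: int = 3
    strong_ror: float = 5.0
    rule: Literal["ci_lower", "point_estimate"] = "ci_lower"

    def __post_init__(self) -> None:
        if self.min_reports < 1:
            raise ValueError("min_reports must be >= 1")
        if self.strong_ror <= 1:
            raise ValueError("strong_ror must be > 1")
        if self.rule not in ("ci_lower", "point_estimate"):
            raise ValueError(f"unknown rule {self.rule!r}")


@dataclass
class SignalResult:
    """ROR, CI, chi-square and signal class for one PT."""

    pt: str
    drug_scope: str
    table: ContingencyTable
    ror: float
    ci_low: float
    ci_high: float
    chi2: float
    p_value: float
    signal_class: str = "none"
    corrected: bool = False
    chi2_defined: bool = True


def compute_ror(table: ContingencyTable) -> tuple[float, float, float, bool]:
    """ROR point estimate and Wald 95% CI; returns (ror, low, high, corrected).

    Zero cells trigger the Haldane–Anscombe +0.5 correction on all four
    cells; an all-zero table is an error.
    """
    if table.n == 0:
        raise ValueError("cannot compute an ROR from an all-zero table")
    a, b, c, d = (float(x) for x in table.cells())
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_ror = math.log(ror)
    return ror, math.exp(log_ror - Z_95 * se), math.exp(log_ror + Z_95 * se), corrected


def chi_square(table: ContingencyTable, yates: bool = False) -> tuple[float, float, bool]:
    """Pearson chi-square on 1 df; returns (chi2, p, defined).

    Computed from the closed form N*(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)).
    A zero margin leaves the statistic undefined (NaN, flagged).  The
    optional Yates continuity correction subtracts N/2 from |ad-bc|.
    """
    a, b, c, d = (float(x) for x in table.cells())
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        return float("nan"), float("nan"), False
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2, 0.0)
    chi2 = n * diff * diff / margins
    return chi2, float(stats.chi2.sf(chi2, df=1)), True


def classify_signal(
    a: int,
    ror: float,
    ci_low: float,
    thresholds: SignalThresholds = SignalThresholds(),
) -> str:
    """Classify one PT as ``none`` / ``signal`` / ``strong``."""
    if thresholds.rule == "ci_lower":
        is_signal = a >= thresholds.min_reports and ci_low > 1.0
    else:
        is_signal = a >= thresholds.min_reports and ror > 1.0
    if not is_signal:
        return "none"
    return "strong" if ror >= thresholds.strong_ror else "signal"


def classify_result(result: SignalResult, thresholds: SignalThresholds = SignalThresholds()) -> str:
    return classify_signal(result.table.a, result.ror, result.ci_low, thresholds)


def _pt_mask(rs: ReportSet, pt: str) -> pd.Series:
    """Boolean Series over primaryids: report mentions ``pt`` (case-insensitive)."""
    key = _canon(pt)
    hits = rs.reactions.loc[rs.reactions["pt"].map(_canon) == key, "primaryid"]
    mask = pd.Series(False, index=rs.primaryids)
    mask.loc[mask.index.isin(set(hits))] = True
    return mask


def build_contingency(rs: ReportSet, exposure: pd.Series, pt: str) -> ContingencyTable:
    """Count the 2x2 cells at report level (a PT listed twice counts once)."""
    if len(rs) == 0:
        raise ValueError("cannot build a contingency table from zero reports")
    exposure = exposure.reindex(rs.primaryids, fill_value=False).astype(bool)
    event = _pt_mask(rs, pt)
    a = int((exposure & event).sum())
    b = int((exposure & ~event).sum())
    c = int((~exposure & event).sum())
    d = int((~exposure & ~event).sum())
    return ContingencyTable(a, b, c, d)


def _result_for_table(
    pt: str, drug_scope: str, table: ContingencyTable, thresholds: SignalThresholds, yates: bool
) -> SignalResult:
    ror, lo, hi, corrected = compute_ror(table)
    chi2, p, defined = chi_square(table, yates=yates)
    res = SignalResult(
        pt=pt,
        drug_scope=drug_scope,
        table=table,
        ror=ror,
        ci_low=lo,
        ci_high=hi,
        chi2=chi2,
        p_value=p,
        corrected=corrected,
        chi2_defined=defined,
    )
    res.signal_class = classify_result(res, thresholds)
    return res


def mine_signals(
    rs: ReportSet,
    exposure: pd.Series,
    catalog: PTCatalog,
    thresholds: SignalThresholds = SignalThresholds(),
    drug_scope: str = "all",
    yates: bool = False,
) -> list[SignalResult]:
    """One :class:`SignalResult` per catalog PT with a >= 1, sorted by PT.

    ``exposure`` is a per-report boolean Series (see
    :func:`pvsignal.lexicon.exposure_mask`).
    """
    if len(rs) == 0:
        return []
    exposure = exposure.reindex(rs.primaryids, fill_value=False).astype(bool)
    n_exposed = int(exposure.sum())
    n_total = len(rs)

    # one pass over the reactions frame instead of one scan per PT
    canon_pts = {_canon(p): p for p in catalog.pts}
    reac = rs.reactions.assign(_canon=rs.reactions["pt"].map(_canon))
    reac = reac[reac["_canon"].isin(canon_pts)]
    exposed_ids = set(rs.primaryids[exposure.values])
    reac = reac.assign(_exposed=reac["primaryid"].isin(exposed_ids))
    counts = reac.groupby("_canon")["_exposed"].agg(["sum", "count"])

    results = []
    for key in sorted(counts.index, key=lambda k: canon_pts[k]):
        a = int(counts.loc[key, "sum"])
        with_pt = int(counts.loc[key, "count"])
        c = with_pt - a
        table = ContingencyTable(a, n_exposed - a, c, (n_total - n_exposed) - c)
        results.append(_result_for_table(canon_pts[key], drug_scope, table, thresholds, yates))
    return results


def results_frame(results: Iterable[SignalResult]) -> pd.DataFrame:
    """Tabular view of signal results (the emitted signal-table shape)."""
    rows = [
        {
            "drug_scope": r.drug_scope,
            "pt": r.pt,
            "a": r.table.a,
            "b": r.table.b,
            "c": r.table.c,
            "d": r.table.d,
            "ror": r.ror,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "chi2": r.chi2,
            "p_value": r.p_value,
            "signal_class": r.signal_class,
            "corrected": r.corrected,
        }
        for r in results
    ]
    cols = [
        "drug_scope", "pt", "a", "b", "c", "d", "ror", "ci_low", "ci_high",
        "chi2", "p_value", "signal_class", "corrected",
    ]
    return pd.DataFrame(rows, columns=cols)


def per_drug_strong_signals(
    rs: ReportSet,
    lexicon: DrugLexicon,
    catalog: PTCatalog,
    thresholds: SignalThresholds = SignalThresholds(),
    roles: frozenset[str] = SUSPECT_ROLES,
) -> pd.DataFrame:
    """Strong signals mined drug by drug.

    For each generic the exposure is that generic alone (suspect roles)
    and the comparator is every report not exposed to it; only rows with
    ``signal_class == "strong"`` are kept.
    """
    frames = []
    for generic in lexicon.generics:
        mask = exposure_mask(rs, lexicon, generics=[generic], roles=roles)
        if not mask.any():
            continue
        results = [r for r in mine_signals(rs, mask, catalog, thresholds, drug_scope=generic) if r.signal_class == "strong"]
        if results:
            frames.append(results_frame(results))
    if not frames:
        return results_frame([])
    return pd.concat(frames, ignore_index=True)


def coowned_strong_signals(per_drug: pd.DataFrame, min_drugs: int = 2) -> pd.DataFrame:
    """PTs that are strong signals for at least ``min_drugs`` drugs."""
    if per_drug.empty:
        return per_drug.copy()
    counts = per_drug.groupby("pt")["drug_scope"].nunique()
    keep = counts[counts >= min_drugs].index
    out = per_drug[per_drug["pt"].isin(keep)].copy()
    return out.sort_values(["pt", "drug_scope"], kind="mergesort").reset_index(drop=True)
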