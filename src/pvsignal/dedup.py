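"""Two-stage duplicate-report removal.

Spontaneous-report databases carry two kinds of duplication.  A case is
revised over time, so one ``caseid`` accumulates several ``primaryid``
versions of which only the latest should be analysed.  Separately, the
same patient event reaches the database through different reporters
under different case numbers; following the standard record-linkage
practice, reports that agree on the receipt date of the first case
version, the patient's age and sex, and the reporter country are
treated as duplicates of one another.

Both stages are deterministic: within a duplicate group the report with
the greatest ``primaryid`` survives (numeric comparison when the ids are
numeric).  A linkage key with any missing component never matches
anything.
"""

from __future__ import annotations

import pandas as pd

from .faers_model import ReportSet

LINKAGE_FIELDS = ("fda_first_dt", "age_years", "sex", "reporter_country")


def _id_order(ids: pd.Index | pd.Series) -> pd.Series:
    """Sort key for primaryids: numeric when possible, else lexicographic."""
    s = pd.Series(list(ids), index=None, dtype=object).astype(str)
    num = pd.to_numeric(s, errors="coerce")
    if num.notna().all():
        return num
    return s


def latest_case_version(rs: ReportSet) -> ReportSet:
    """Keep exactly one report per ``caseid``: the greatest ``caseversion``.

    Ties on ``caseversion`` are broken by greatest ``primaryid``.
    """
    df = rs.reports.copy()
    df["_order"] = _id_order(df.index).values
    df = df.sort_values(["caseversion", "_order"], kind="mergesort")
    survivors = df.groupby("caseid", sort=False).tail(1).index
    out = rs.subset(survivors)
    out.log["dedup_version_removed"] = len(rs) - len(out)
    return out


def linkage_dedup(rs: ReportSet) -> ReportSet:
    """Collapse reports sharing a complete linkage key.

    The key is (first-version receipt date, age rounded to whole years,
    sex, reporter country).  Only reports with all four components
    present can be grouped; the greatest ``primaryid`` in each group is
    retained.  Ages are compared after rounding to whole years to avoid
    spurious mismatches from unit conversion.
    """
    df = rs.reports
    key = pd.DataFrame(
        {
            "fda_first_dt": df["fda_first_dt"],
            "age": df["age_years"].round(0),
            "sex": df["sex"],
            "country": df["reporter_country"],
        },
        index=df.index,
    )
    complete = key.notna().all(axis=1)
    grp = key[complete]
    order = _id_order(grp.index)
    grp = grp.assign(_order=order.values).sort_values("_order", kind="mergesort")
    survivors_complete = grp.groupby(["fda_first_dt", "age", "sex", "country"], sort=False).tail(1).index
    survivors = df.index[~complete].union(survivors_complete)
    out = rs.subset(df.index[df.index.isin(survivors)])
    out.log["dedup_linkage_removed"] = len(rs) - len(out)
    return out


def deduplicate(rs: ReportSet) -> ReportSet:
    """Run both stages: latest case version, then record linkage."""
    return linkage_dedup(latest_case_version(rs))
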