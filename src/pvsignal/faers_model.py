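"""Report data model and the FAERS quarterly ASCII table dialect.

FAERS (the FDA Adverse Event Reporting System) distributes spontaneous
adverse-event reports as quarterly ``$``-delimited ASCII tables.  Four of
them carry everything disproportionality mining needs:

* ``DEMO`` — one row per report version: case identifiers, receipt date,
  patient age/sex, reporter country;
* ``DRUG`` — one row per drug entry with a role code (PS = primary
  suspect, SS = secondary suspect, C = concomitant, I = interacting);
* ``REAC`` — one MedDRA preferred term (PT) per adverse-reaction row;
* ``INDI`` — one indication PT per treated drug entry.

This module reads and writes that dialect, and assembles the four tables
into per-report records keyed by ``primaryid``.
"""

from __future__ import annotations

import dataclasses
import glob
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

DELIMITER = "$"

#: role codes a drug entry may carry
ROLES = ("PS", "SS", "C", "I")

#: mandatory columns per table, in canonical emission order
TABLE_COLUMNS: dict[str, tuple[str, ...]] = {
    "demo": (
        "primaryid",
        "caseid",
        "caseversion",
        "fda_dt",
        "age",
        "age_cod",
        "sex",
        "reporter_country",
    ),
    "drug": ("primaryid", "drug_seq", "role_cod", "drugname"),
    "reac": ("primaryid", "pt"),
    "indi": ("primaryid", "indi_drug_seq", "indi_pt"),
}

#: age unit code -> factor converting the stated age to years
AGE_UNIT_TO_YEARS = {"YR": 1.0, "MON": 1.0 / 12.0, "DY": 1.0 / 365.25}


class MissingColumnError(ValueError):
    """A mandatory column is absent from an input table."""


@dataclass
class RawTables:
    """The four quarterly tables, typed but not yet joined.

    ``notes`` collects per-table counts of malformed rows that were
    dropped at parse time, so nothing disappears silently.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    indi: pd.DataFrame
    notes: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {"demo": self.demo, "drug": self.drug, "reac": self.reac, "indi": self.indi}


@dataclass(frozen=True)
class Report:
    """One assembled safety report (a single case version)."""

    primaryid: str
    caseid: str
    caseversion: int
    fda_first_dt: pd.Timestamp | None
    age_years: float | None
    sex: str | None
    reporter_country: str | None
    year: int | None
    drugs: tuple[tuple[str, str], ...]  # (drugname, role)
    reactions: frozenset[str]
    indications: tuple[tuple[str, str], ...]  # (drugname or "", indication PT)


@dataclass
class ReportSet:
    """A collection of assembled reports, held as indexed frames.

    ``reports`` is indexed by ``primaryid`` with columns ``caseid``,
    ``caseversion``, ``fda_first_dt``, ``age_years``, ``sex``,
    ``reporter_country`` and ``year``; ``drugs``/``reactions``/
    ``indications`` are long frames keyed by ``primaryid``.  Keeping the
    collection columnar makes dedup and 2x2 counting vectorisable while
    :meth:`to_reports` still yields per-report records for inspection.
    """

    reports: pd.DataFrame
    drugs: pd.DataFrame
    reactions: pd.DataFrame
    indications: pd.DataFrame
    log: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reports)

    @property
    def primaryids(self) -> pd.Index:
        return self.reports.index

    def subset(self, primaryids: Iterable[str]) -> "ReportSet":
        ids = pd.Index(primaryids)
        return ReportSet(
            reports=self.reports.loc[self.reports.index.isin(ids)],
            drugs=self.drugs[self.drugs["primaryid"].isin(ids)].reset_index(drop=True),
            reactions=self.reactions[self.reactions["primaryid"].isin(ids)].reset_index(drop=True),
            indications=self.indications[self.indications["primaryid"].isin(ids)].reset_index(drop=True),
            log=dict(self.log),
        )

    def to_reports(self) -> list[Report]:
        drugs_by_id: dict[str, list] = {}
        for pid, name, role in self.drugs[["primaryid", "drugname", "role_cod"]].itertuples(index=False):
            drugs_by_id.setdefault(pid, []).append((name, role))
        reac_by_id: dict[str, set] = {}
        for pid, pt in self.reactions[["primaryid", "pt"]].itertuples(index=False):
            reac_by_id.setdefault(pid, set()).add(pt)
        indi_by_id: dict[str, list] = {}
        for pid, dname, ipt in self.indications[["primaryid", "drugname", "indi_pt"]].itertuples(index=False):
            indi_by_id.setdefault(pid, []).append((dname, ipt))
        out = []
        for pid, row in self.reports.iterrows():
            out.append(
                Report(
                    primaryid=pid,
                    caseid=row["caseid"],
                    caseversion=int(row["caseversion"]),
                    fda_first_dt=None if pd.isna(row["fda_first_dt"]) else row["fda_first_dt"],
                    age_years=None if pd.isna(row["age_years"]) else float(row["age_years"]),
                    sex=None if pd.isna(row["sex"]) else row["sex"],
                    reporter_country=None if pd.isna(row["reporter_country"]) else row["reporter_country"],
                    year=None if pd.isna(row["year"]) else int(row["year"]),
                    drugs=tuple(drugs_by_id.get(pid, [])),
                    reactions=frozenset(reac_by_id.get(pid, set())),
                    indications=tuple(indi_by_id.get(pid, [])),
                )
            )
        return out


def _read_table(path: str, name: str) -> tuple[pd.DataFrame, int]:
    """Parse one ``$``-delimited table; returns (frame, n_malformed_rows)."""
    bad = []

    def _on_bad(row):  # rows with the wrong field count
        bad.append(row)
        return None

    df = pd.read_csv(
        path,
        sep=DELIMITER,
        dtype=str,
        engine="python",
        quoting=3,  # csv.QUOTE_NONE: the dialect has no quoting
        keep_default_na=False,
        on_bad_lines=_on_bad,
    )
    df.columns = [c.strip().lower() for c in df.columns]
    for col in TABLE_COLUMNS[name]:
        if col not in df.columns:
            raise MissingColumnError(f"{path}: mandatory column {col!r} missing from {name.upper()} table")
    df = df.loc[:, list(TABLE_COLUMNS[name])]
    # empty string means missing throughout the dialect
    df = df.replace({"": pd.NA})
    return df, len(bad)


def _age_to_years(age: pd.Series, age_cod: pd.Series) -> pd.Series:
    """Convert FAERS (age, unit-code) pairs to years; unknown codes -> missing."""
    value = pd.to_numeric(age, errors="coerce")
    factor = age_cod.str.strip().str.upper().map(AGE_UNIT_TO_YEARS)
    years = value * factor
    return years.where(years >= 0)


def read_quarter(source: str | Mapping[str, str]) -> RawTables:
    """Read DEMO/DRUG/REAC/INDI files into typed :class:`RawTables`.

    ``source`` is either a directory containing files whose names start
    with the table name (``DEMO*``, case-insensitive) or an explicit
    mapping ``{"demo": path, ...}``.  Ages are converted to years from
    the ``age_cod`` unit column; unparseable dates become missing but
    the rows are kept; rows with the wrong field count are dropped and
    counted in ``RawTables.notes``.
    """
    if isinstance(source, (str, os.PathLike)):
        paths = {}
        for name in TABLE_COLUMNS:
            hits = sorted(
                p
                for p in glob.glob(os.path.join(str(source), "*"))
                if os.path.basename(p).lower().startswith(name)
            )
            if not hits:
                raise FileNotFoundError(f"no {name.upper()} file found under {source}")
            paths[name] = hits[0]
    else:
        paths = dict(source)

    frames: dict[str, pd.DataFrame] = {}
    notes: dict = {}
    for name in TABLE_COLUMNS:
        frames[name], n_bad = _read_table(paths[name], name)
        if n_bad:
            notes[f"{name}_malformed_rows"] = n_bad

    demo = frames["demo"]
    demo["caseversion"] = pd.to_numeric(demo["caseversion"], errors="coerce").astype("Int64")
    demo["fda_dt"] = pd.to_datetime(demo["fda_dt"], format="%Y%m%d", errors="coerce")
    demo["age_years"] = _age_to_years(demo["age"], demo["age_cod"])

    drug = frames["drug"]
    drug["drug_seq"] = pd.to_numeric(drug["drug_seq"], errors="coerce").astype("Int64")
    drug["role_cod"] = drug["role_cod"].str.strip().str.upper()

    indi = frames["indi"]
    indi["indi_drug_seq"] = pd.to_numeric(indi["indi_drug_seq"], errors="coerce").astype("Int64")

    return RawTables(demo=demo, drug=drug, reac=frames["reac"], indi=indi, notes=notes)


def write_quarter(raw: RawTables, directory: str) -> dict[str, str]:
    """Emit ``raw`` in the quarterly dialect; returns the paths written."""
    os.makedirs(directory, exist_ok=True)
    paths = {}
    for name, df in raw.tables().items():
        out = df.loc[:, list(TABLE_COLUMNS[name])].copy()
        if name == "demo":
            out["fda_dt"] = pd.to_datetime(out["fda_dt"]).dt.strftime("%Y%m%d")
        path = os.path.join(directory, f"{name.upper()}.txt")
        out.to_csv(path, sep=DELIMITER, index=False, na_rep="")
        paths[name] = path
    return paths


def assemble_reports(raw: RawTables) -> ReportSet:
    """Join the raw tables into a :class:`ReportSet`, one entry per DEMO row.

    Reports with no reaction rows cannot contribute to any contingency
    cell and are excluded (counted in ``log["excluded_no_reactions"]``);
    DRUG/REAC/INDI rows whose ``primaryid`` is absent from DEMO are
    skipped and counted likewise.
    """
    demo = raw.demo.copy()
    demo["primaryid"] = demo["primaryid"].astype(str)
    known = pd.Index(demo["primaryid"])

    log: dict = {}

    def _attach(df: pd.DataFrame, label: str) -> pd.DataFrame:
        df = df.copy()
        df["primaryid"] = df["primaryid"].astype(str)
        orphan = ~df["primaryid"].isin(known)
        if orphan.any():
            log[f"skipped_orphan_{label}_rows"] = int(orphan.sum())
        return df[~orphan].reset_index(drop=True)

    drug = _attach(raw.drug, "drug")
    reac = _attach(raw.reac.dropna(subset=["pt"]), "reac")
    indi = _attach(raw.indi.dropna(subset=["indi_pt"]), "indi")

    has_reac = demo["primaryid"].isin(set(reac["primaryid"]))
    n_excluded = int((~has_reac).sum())
    if n_excluded:
        log["excluded_no_reactions"] = n_excluded
    demo = demo[has_reac]

    reports = pd.DataFrame(
        {
            "caseid": demo["caseid"].astype(str).values,
            "caseversion": demo["caseversion"].fillna(1).astype(int).values,
            "fda_first_dt": demo["fda_dt"].values,
            "age_years": demo["age_years"].astype(float).values,
            "sex": demo["sex"].values,
            "reporter_country": demo["reporter_country"].values,
            "year": pd.to_datetime(demo["fda_dt"]).dt.year.values,
        },
        index=pd.Index(demo["primaryid"].values, name="primaryid"),
    )
    keep = reports.index
    drug = drug[drug["primaryid"].isin(keep)].reset_index(drop=True)
    reac = reac[reac["primaryid"].isin(keep)].reset_index(drop=True)
    indi = indi[indi["primaryid"].isin(keep)].reset_index(drop=True)

    # resolve indication drug_seq -> drug name so case series can rank by drug
    seq_map = drug.set_index(["primaryid", "drug_seq"])["drugname"]
    key = pd.MultiIndex.from_frame(indi[["primaryid", "indi_drug_seq"]].rename(columns={"indi_drug_seq": "drug_seq"}))
    indi = indi.assign(drugname=seq_map.reindex(key).fillna("").values)

    reactions = reac[["primaryid", "pt"]].drop_duplicates().reset_index(drop=True)
    n_dup_reac = len(reac) - len(reactions)
    if n_dup_reac:
        log["collapsed_duplicate_reaction_rows"] = n_dup_reac
    return ReportSet(
        reports=reports,
        drugs=drug[["primaryid", "drug_seq", "role_cod", "drugname"]],
        reactions=reactions,
        indications=indi[["primaryid", "drugname", "indi_pt"]],
        log=log,
    )
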