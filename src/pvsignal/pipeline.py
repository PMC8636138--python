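"""End-to-end orchestration: raw tables in, signal tables out.

The full analysis runs in a fixed order: read (or simulate) the raw
quarterly tables, assemble reports, deduplicate (latest case version,
then record linkage), flag target-drug exposure, mine the pooled
all-drug signal table, mine per-drug strong signals and their co-owned
intersection, profile requested case series, and count exposed reports
per drug and year.  Every artifact is a TSV plus one plain-text run log
carrying dedup statistics and row-exclusion counts; a failed stage
aborts the run, names itself, and removes partial outputs.
"""

from __future__ import annotations

import dataclasses
import os
import re
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
import yaml

from . import case_series as cs
from . import dedup as dd
from .event_catalog import PTCatalog, builtin_hepatotoxicity_catalog
from .faers_model import ReportSet, assemble_reports, read_quarter
from .lexicon import DrugLexicon, builtin_ppi_lexicon, exposure_mask
from .signal_stats import (
    SignalThresholds,
    coowned_strong_signals,
    mine_signals,
    per_drug_strong_signals,
    results_frame,
)
from .synthetic_data import SimConfig, default_ppi_config, simulate_cohort, write_simulation


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one analysis run needs."""

    out_dir: str
    input_dir: str | None = None  # read this quarter directory ...
    simulate: SimConfig | None = None  # ... or simulate a cohort
    lexicon_path: str | None = None  # None -> packaged PPI lexicon
    catalog_path: str | None = None  # None -> packaged hepatotoxicity catalog
    thresholds: SignalThresholds = field(default_factory=SignalThresholds)
    target_drugs: tuple[str, ...] | None = None  # None -> every lexicon generic
    case_series: tuple[tuple[str, str], ...] = ()  # (generic, pt) pairs
    coowned_min_drugs: int = 2

    def validate(self) -> None:
        if (self.input_dir is None) == (self.simulate is None):
            raise ValueError("exactly one of input_dir / simulate must be set")
        if self.coowned_min_drugs < 1:
            raise ValueError("coowned_min_drugs must be >= 1")


def load_run_config(path: str, out_dir: str | None = None, seed: int | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file (CLI surface)."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    sim = None
    input_dir = None
    src = doc.get("input", {})
    if src.get("kind", "simulate") == "simulate":
        sim = default_ppi_config(
            n_reports=int(src.get("n_reports", 20_000)),
            seed=int(src.get("seed", 0) if seed is None else seed),
        )
    else:
        input_dir = src["path"]
    thr = doc.get("thresholds", {})
    return RunConfig(
        out_dir=out_dir or doc.get("out_dir", "pvsignal_out"),
        input_dir=input_dir,
        simulate=sim,
        lexicon_path=doc.get("lexicon"),
        catalog_path=doc.get("catalog"),
        thresholds=SignalThresholds(
            min_reports=int(thr.get("min_reports", 3)),
            strong_ror=float(thr.get("strong_ror", 5.0)),
            rule=thr.get("rule", "ci_lower"),
        ),
        target_drugs=tuple(doc["target_drugs"]) if doc.get("target_drugs") else None,
        case_series=tuple((d["generic"], d["pt"]) for d in doc.get("case_series", [])),
        coowned_min_drugs=int(doc.get("coowned_min_drugs", 2)),
    )


def _slug(text: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", text.lower()).strip("_")


def _case_series_frame(summary: cs.CaseSeriesSummary) -> pd.DataFrame:
    rows = [("total", "n_reports", summary.n_reports, "")]
    for year, n in sorted(summary.by_year.items()):
        rows.append(("year", str(year), n, ""))
    for k in cs.SEX_BINS:
        rows.append(("sex", k, summary.by_sex[k], f"{summary.by_sex_pct[k]:.2f}"))
    for k in cs.AGE_BINS:
        rows.append(("age", k, summary.by_age_bin[k], f"{summary.by_age_bin_pct[k]:.2f}"))
    for k in cs.CONCOMITANT_BINS:
        rows.append(("concomitant_bin", k, summary.concomitant_bins.get(k, 0),
                     f"{summary.concomitant_bins_pct.get(k, 0.0):.2f}"))
    for name, n in summary.top_concomitants:
        rows.append(("top_concomitant", name, n, ""))
    for name, n in summary.top_indications:
        rows.append(("top_indication", name, n, ""))
    return pd.DataFrame(rows, columns=["section", "key", "count", "pct"])


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute the full analysis; returns the artifact paths written."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    written: list[str] = []
    log_lines: list[str] = []
    stage = "setup"

    def _write(name: str, df: pd.DataFrame) -> str:
        path = os.path.join(config.out_dir, name)
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(path)
        return path

    try:
        stage = "input"
        if config.simulate is not None:
            sim = simulate_cohort(config.simulate)
            sim_dir = os.path.join(config.out_dir, "simulated_input")
            for p in write_simulation(sim, sim_dir).values():
                written.append(p)
            raw = sim.raw
            log_lines.append(f"input: simulated cohort, n_reports={config.simulate.n_reports}, seed={config.simulate.seed}")
        else:
            raw = read_quarter(config.input_dir)
            log_lines.append(f"input: quarterly tables from {config.input_dir}")
            for k, v in raw.notes.items():
                log_lines.append(f"input note: {k}={v}")

        stage = "assemble"
        rs = assemble_reports(raw)
        for k, v in rs.log.items():
            log_lines.append(f"assemble: {k}={v}")
        log_lines.append(f"assemble: reports={len(rs)}")

        stage = "dedup"
        rs = dd.latest_case_version(rs)
        log_lines.append(f"dedup: version_removed={rs.log['dedup_version_removed']}")
        rs = dd.linkage_dedup(rs)
        log_lines.append(f"dedup: linkage_removed={rs.log['dedup_linkage_removed']}")
        log_lines.append(f"dedup: reports_remaining={len(rs)}")

        stage = "lexicon"
        lexicon = DrugLexicon.from_tsv(config.lexicon_path) if config.lexicon_path else builtin_ppi_lexicon()
        catalog = PTCatalog.from_tsv(config.catalog_path) if config.catalog_path else builtin_hepatotoxicity_catalog()
        targets = config.target_drugs or lexicon.generics

        stage = "signals_all"
        pooled = exposure_mask(rs, lexicon, generics=targets)
        log_lines.append(f"exposure: pooled_exposed_reports={int(pooled.sum())}")
        all_results = mine_signals(rs, pooled, catalog, config.thresholds, drug_scope="all")
        all_frame = results_frame(all_results)
        _write("signals_all.tsv", all_frame)
        n_sig = int((all_frame["signal_class"] != "none").sum()) if len(all_frame) else 0
        log_lines.append(f"signals_all: pts_with_cases={len(all_frame)} signals={n_sig} non_signals={len(all_frame) - n_sig}")

        stage = "signals_per_drug"
        per_drug = per_drug_strong_signals(rs, lexicon, catalog, config.thresholds)
        per_drug = per_drug[per_drug["drug_scope"].isin(targets)].reset_index(drop=True)
        _write("strong_signals_per_drug.tsv", per_drug)

        stage = "coowned"
        coowned = coowned_strong_signals(per_drug, config.coowned_min_drugs)
        _write("coowned_strong_signals.tsv", coowned)

        stage = "case_series"
        for generic, pt in config.case_series:
            summary = cs.summarize_case_series(rs, lexicon, generic, pt)
            _write(f"case_series_{_slug(generic)}_{_slug(pt)}.tsv", _case_series_frame(summary))
            log_lines.append(f"case_series: {generic}/{pt} n={summary.n_reports}")

        stage = "yearly_counts"
        rows = []
        for generic in targets:
            mask = exposure_mask(rs, lexicon, generics=[generic])
            years = rs.reports.loc[mask.values, "year"].dropna().astype(int)
            for year, n in years.value_counts().sort_index().items():
                rows.append({"generic": generic, "year": int(year), "n_reports": int(n)})
        _write("yearly_report_counts.tsv", pd.DataFrame(rows, columns=["generic", "year", "n_reports"]))

        stage = "run_log"
        log_path = os.path.join(config.out_dir, "run_log.txt")
        with open(log_path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(log_lines) + "\n")
        written.append(log_path)
    except Exception as exc:
        for path in written:
            if os.path.exists(path):
                os.unlink(path)
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {os.path.basename(p): p for p in written}
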