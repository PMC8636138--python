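"""FAERS-like cohort simulation with known ground truth.

Real quarterly safety data cannot ship with a package, and the true
drug–event dependence structure behind it is unknowable.  This module
generates raw DEMO/DRUG/REAC/INDI tables from an explicit generative
model so every pipeline stage — parsing, deduplication, name mapping,
2x2 mining, case series — can be exercised against known truth:

* each report draws demographics, per-drug exposure with a role code,
  and per-PT reaction indicators;
* a configured (drug, PT) effect multiplies that PT's reporting *odds*
  by the target ROR whenever the drug is present in a suspect role, so
  the population reporting odds ratio equals the configured value
  exactly (a risk-ratio injection would not have that property);
* duplicate reports are injected in both real-world flavours — extra
  case versions under the same caseid, and cross-source clones with new
  caseids but identical linkage keys — and labelled in a truth sidecar
  so dedup precision/recall are measurable;
* accidental complete-linkage-key collisions between distinct base
  reports are resolved by nudging receipt dates, so the duplicate
  labels are exact ground truth rather than high-probability truth.

Everything is drawn from one seeded generator in a fixed documented
order, so a (config, seed) pair reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .faers_model import RawTables

FILLER_PT = "Drug ineffective"  # keeps every report's reaction list nonempty

_COUNTRIES = ("US", "JP", "GB", "FR", "DE", "CA", "IT")
_COUNTRY_W = (0.55, 0.10, 0.09, 0.07, 0.07, 0.07, 0.05)
_DOSE_SUFFIXES = (" 20MG", " 40MG", " 40 MG TABLET", " TABLET", " CAPSULE", " SODIUM")


@dataclass(frozen=True)
class DrugSpec:
    """One simulated drug: identity, naming and exposure behaviour."""

    generic: str
    brands: tuple[str, ...] = ()
    exposure_prob: float = 0.01
    role_dist: tuple[float, float, float] = (0.6, 0.2, 0.2)  # P(PS), P(SS), P(C)


@dataclass(frozen=True)
class PTSpec:
    """One preferred term and its background reporting probability."""

    name: str
    background_prob: float


@dataclass(frozen=True)
class EffectSpec:
    """An injected (drug, PT) association on the odds scale."""

    generic: str
    pt: str
    ror: float


@dataclass
class SimConfig:
    """Full parameterisation of the cohort generator."""

    n_reports: int
    seed: int
    drugs: tuple[DrugSpec, ...]
    pts: tuple[PTSpec, ...]
    effects: tuple[EffectSpec, ...] = ()
    duplicate_version_rate: float = 0.0
    linkage_duplicate_rate: float = 0.0
    brand_name_rate: float = 0.5
    dose_suffix_rate: float = 0.2
    missing_age_rate: float = 0.15
    missing_sex_rate: float = 0.08
    missing_country_rate: float = 0.05
    year_range: tuple[int, int] = (2013, 2019)
    concomitant_dist: dict[int, float] = field(default_factory=lambda: {0: 1.0})
    concomitant_pool: tuple[str, ...] = ()
    indication_vocab: tuple[str, ...] = ()
    unknown_indication_prob: float = 0.5

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        rates = {
            "duplicate_version_rate": self.duplicate_version_rate,
            "linkage_duplicate_rate": self.linkage_duplicate_rate,
            "brand_name_rate": self.brand_name_rate,
            "dose_suffix_rate": self.dose_suffix_rate,
            "missing_age_rate": self.missing_age_rate,
            "missing_sex_rate": self.missing_sex_rate,
            "missing_country_rate": self.missing_country_rate,
            "unknown_indication_prob": self.unknown_indication_prob,
        }
        for name, v in rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.duplicate_version_rate + self.linkage_duplicate_rate > 1.0:
            raise ValueError("duplicate rates must sum to <= 1 (kinds are exclusive per report)")
        for d in self.drugs:
            if not 0.0 <= d.exposure_prob <= 1.0:
                raise ValueError(f"exposure_prob out of [0,1] for {d.generic}")
            if abs(sum(d.role_dist) - 1.0) > 1e-9 or min(d.role_dist) < 0:
                raise ValueError(f"role_dist must be a distribution for {d.generic}")
        names = [d.generic for d in self.drugs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate generic names in drugs")
        for p in self.pts:
            if not 0.0 < p.background_prob < 1.0:
                raise ValueError(f"background_prob must be in (0,1) for {p.name}")
        pt_names = {p.name for p in self.pts}
        for e in self.effects:
            if e.ror <= 0:
                raise ValueError(f"target ROR must be > 0 for ({e.generic}, {e.pt})")
            if e.generic not in names:
                raise ValueError(f"effect references unknown drug {e.generic!r}")
            if e.pt not in pt_names:
                raise ValueError(f"effect references unknown PT {e.pt!r}")
        if abs(sum(self.concomitant_dist.values()) - 1.0) > 1e-9:
            raise ValueError("concomitant_dist must sum to 1")
        if max(self.concomitant_dist) > len(self.concomitant_pool) and max(self.concomitant_dist) > 0:
            if any(p > 0 for k, p in self.concomitant_dist.items() if k > len(self.concomitant_pool)):
                raise ValueError("concomitant_dist asks for more drugs than the pool holds")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be (first, last) with first <= last")


@dataclass
class SimResult:
    """Raw tables plus the duplicate-truth sidecar."""

    raw: RawTables
    truth: pd.DataFrame  # primaryid, caseid, is_duplicate, duplicate_kind
    config: SimConfig


@dataclass(frozen=True)
class ExpectedCells:
    """Real-valued expected 2x2 cells under the generative model."""

    a: float
    b: float
    c: float
    d: float

    @property
    def ror(self) -> float:
        return (self.a * self.d) / (self.b * self.c)


def _render_names(rng: np.random.Generator, spec: DrugSpec, size: int, cfg: SimConfig) -> np.ndarray:
    """Verbatim drug-name strings: brand vs generic, optional dose/form noise."""
    names = np.full(size, spec.generic.upper(), dtype=object)
    if spec.brands and cfg.brand_name_rate > 0:
        use_brand = rng.random(size) < cfg.brand_name_rate
        brand_idx = rng.integers(0, len(spec.brands), size)
        for i in np.flatnonzero(use_brand):
            names[i] = spec.brands[brand_idx[i]].upper()
    if cfg.dose_suffix_rate > 0:
        noisy = rng.random(size) < cfg.dose_suffix_rate
        suffix_idx = rng.integers(0, len(_DOSE_SUFFIXES), size)
        for i in np.flatnonzero(noisy):
            names[i] = names[i] + _DOSE_SUFFIXES[suffix_idx[i]]
    return names


def simulate_cohort(config: SimConfig) -> SimResult:
    """Draw one synthetic cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    # --- 1. demographics ------------------------------------------------
    y0, y1 = config.year_range
    start = np.datetime64(f"{y0}-01-01")
    span = int((np.datetime64(f"{y1 + 1}-01-01") - start) / np.timedelta64(1, "D"))
    dates = start + rng.integers(0, span, n).astype("timedelta64[D]")
    ages = np.clip(np.round(rng.normal(58.0, 18.0, n)), 0, 100).astype(int)
    age_missing = rng.random(n) < config.missing_age_rate
    sexes = np.where(rng.random(n) < 0.48, "M", "F").astype(object)
    sex_missing = rng.random(n) < config.missing_sex_rate
    countries = rng.choice(_COUNTRIES, size=n, p=_COUNTRY_W).astype(object)
    country_missing = rng.random(n) < config.missing_country_rate

    # --- 2. per-drug exposure and roles --------------------------------
    present = np.zeros((n, len(config.drugs)), dtype=bool)
    roles = np.empty((n, len(config.drugs)), dtype=object)
    for j, spec in enumerate(config.drugs):
        present[:, j] = rng.random(n) < spec.exposure_prob
        roles[:, j] = rng.choice(np.array(["PS", "SS", "C"], dtype=object), size=n, p=spec.role_dist)
    suspect = present & np.isin(roles, ("PS", "SS"))

    # --- 3. reactions: odds-scaled effect injection --------------------
    pt_names = [p.name for p in config.pts]
    base_odds = np.array([p.background_prob / (1.0 - p.background_prob) for p in config.pts])
    odds = np.tile(base_odds, (n, 1))
    drug_index = {d.generic: j for j, d in enumerate(config.drugs)}
    pt_index = {p.name: k for k, p in enumerate(config.pts)}
    for eff in config.effects:
        j, k = drug_index[eff.generic], pt_index[eff.pt]
        odds[suspect[:, j], k] *= eff.ror
    occur = rng.random((n, len(config.pts))) < odds / (1.0 + odds)

    # --- 4. concomitant counts and names -------------------------------
    conc_keys = np.array(sorted(config.concomitant_dist), dtype=int)
    conc_probs = np.array([config.concomitant_dist[k] for k in conc_keys], dtype=float)
    conc_counts = rng.choice(conc_keys, size=n, p=conc_probs)
    pool = np.array(config.concomitant_pool, dtype=object)

    # --- 5. emit per-report rows (columnar) ----------------------------
    base_pid = 1_000_000
    base_cid = 5_000_000
    pids = np.array([str(base_pid + i) for i in range(n)], dtype=object)
    cids = np.array([str(base_cid + i) for i in range(n)], dtype=object)

    demo = pd.DataFrame(
        {
            "primaryid": pids,
            "caseid": cids,
            "caseversion": np.ones(n, dtype=int),
            "fda_dt": pd.Series(dates).dt.strftime("%Y%m%d").to_numpy(dtype=object),
            "age": np.where(age_missing, "", ages.astype(str)).astype(object),
            "age_cod": np.where(age_missing, "", "YR").astype(object),
            "sex": np.where(sex_missing, "", sexes).astype(object),
            "reporter_country": np.where(country_missing, "", countries).astype(object),
        }
    )

    rendered = {spec.generic: _render_names(rng, spec, n, config) for spec in config.drugs}

    # target-drug entries: sequence number = rank of the drug within the report
    seq_in_report = np.cumsum(present, axis=1)
    drug_parts: list[pd.DataFrame] = []
    indi_parts: list[pd.DataFrame] = []
    for j, spec in enumerate(config.drugs):
        idx = np.flatnonzero(present[:, j])
        if idx.size == 0:
            continue
        drug_parts.append(
            pd.DataFrame(
                {
                    "primaryid": pids[idx],
                    "drug_seq": seq_in_report[idx, j],
                    "role_cod": roles[idx, j],
                    "drugname": rendered[spec.generic][idx],
                }
            )
        )
        sus = idx[np.isin(roles[idx, j], ("PS", "SS"))]
        if sus.size:
            terms = np.full(sus.size, "Product used for unknown indication", dtype=object)
            if config.indication_vocab:
                known = rng.random(sus.size) >= config.unknown_indication_prob
                vocab_idx = rng.integers(0, len(config.indication_vocab), sus.size)
                for t, vi in zip(np.flatnonzero(known), vocab_idx[known]):
                    terms[t] = config.indication_vocab[vi]
            indi_parts.append(
                pd.DataFrame(
                    {"primaryid": pids[sus], "indi_drug_seq": seq_in_report[sus, j], "indi_pt": terms}
                )
            )

    # concomitant entries: k distinct pool drugs via the random-matrix trick
    active = np.flatnonzero(np.minimum(conc_counts, len(pool)) > 0)
    if active.size:
        k_active = np.minimum(conc_counts[active], len(pool))
        order = np.argsort(rng.random((active.size, len(pool))), axis=1)
        base_seq = present.sum(axis=1)
        rows_pid, rows_seq, rows_name = [], [], []
        for row, (i, k) in enumerate(zip(active, k_active)):
            for m in range(k):
                rows_pid.append(pids[i])
                rows_seq.append(base_seq[i] + m + 1)
                rows_name.append(pool[order[row, m]])
        drug_parts.append(
            pd.DataFrame({"primaryid": rows_pid, "drug_seq": rows_seq, "role_cod": "C", "drugname": rows_name})
        )

    drug = (
        pd.concat(drug_parts, ignore_index=True)
        if drug_parts
        else pd.DataFrame(columns=["primaryid", "drug_seq", "role_cod", "drugname"])
    )
    drug = drug.sort_values(["primaryid", "drug_seq"], kind="mergesort", ignore_index=True)
    indi = (
        pd.concat(indi_parts, ignore_index=True)
        if indi_parts
        else pd.DataFrame(columns=["primaryid", "indi_drug_seq", "indi_pt"])
    )
    indi = indi.sort_values(["primaryid", "indi_drug_seq"], kind="mergesort", ignore_index=True)

    ii, kk = np.nonzero(occur)
    no_pt = np.flatnonzero(~occur.any(axis=1))
    reac = pd.DataFrame(
        {
            "primaryid": np.concatenate([pids[ii], pids[no_pt]]),
            "pt": np.concatenate(
                [np.array(pt_names, dtype=object)[kk], np.full(no_pt.size, FILLER_PT, dtype=object)]
            ),
        }
    ).sort_values("primaryid", kind="mergesort", ignore_index=True)

    # --- 6. de-collide accidental complete linkage keys ----------------
    complete = (demo["age"] != "") & (demo["sex"] != "") & (demo["reporter_country"] != "")
    for _ in range(64):
        sub = demo.loc[complete]
        key = sub["fda_dt"] + "|" + sub["age"] + "|" + sub["sex"] + "|" + sub["reporter_country"]
        dup = key.duplicated(keep="first")
        if not dup.any():
            break
        idx = key.index[dup]
        bumped = (
            pd.to_datetime(demo.loc[idx, "fda_dt"], format="%Y%m%d") + pd.Timedelta(days=1)
        ).dt.strftime("%Y%m%d")
        demo.loc[idx, "fda_dt"] = bumped
    else:  # pragma: no cover - 64 passes always suffice at supported sizes
        raise RuntimeError("could not de-collide linkage keys")

    # --- 7. duplicate injection (kinds exclusive per report) -----------
    u = rng.random(n)
    make_version = u < config.duplicate_version_rate
    make_linkage = (
        (u >= config.duplicate_version_rate)
        & (u < config.duplicate_version_rate + config.linkage_duplicate_rate)
        & complete.values
    )

    truth_kind = np.full(n, "", dtype=object)
    dup_idx = np.flatnonzero(make_version | make_linkage)
    truth_kind[dup_idx] = np.where(make_version[dup_idx], "version", "linkage")

    if dup_idx.size:
        new_pids = np.array([str(base_pid + n + j) for j in range(dup_idx.size)], dtype=object)
        is_ver = make_version[dup_idx]
        n_link = int((~is_ver).sum())
        new_cids = np.empty(dup_idx.size, dtype=object)
        # a revision keeps its caseid; a cross-source clone gets a fresh one
        new_cids[is_ver] = demo["caseid"].to_numpy(dtype=object)[dup_idx[is_ver]]
        new_cids[~is_ver] = np.array([str(base_cid + n + j) for j in range(n_link)], dtype=object)

        extra = demo.iloc[dup_idx].copy()
        extra["primaryid"] = new_pids
        extra["caseid"] = new_cids
        extra["caseversion"] = np.where(is_ver, 2, 1)
        demo = pd.concat([demo, extra], ignore_index=True)

        pid_map = dict(zip(pids[dup_idx], new_pids))

        def _clone(df: pd.DataFrame) -> pd.DataFrame:
            sel = df[df["primaryid"].isin(pid_map)].copy()
            sel["primaryid"] = sel["primaryid"].map(pid_map)
            return pd.concat([df, sel], ignore_index=True)

        drug, reac, indi = _clone(drug), _clone(reac), _clone(indi)
        extra_truth = pd.DataFrame(
            {"primaryid": new_pids, "caseid": new_cids, "is_duplicate": 0, "duplicate_kind": ""}
        )
    else:
        extra_truth = None

    truth = pd.DataFrame(
        {
            "primaryid": pids,
            "caseid": cids,
            "is_duplicate": (truth_kind != "").astype(int),
            "duplicate_kind": truth_kind,
        }
    )
    if extra_truth is not None:
        truth = pd.concat([truth, extra_truth], ignore_index=True)

    raw = RawTables(
        demo=_type_demo(demo),
        drug=drug.assign(drug_seq=drug["drug_seq"].astype("Int64")),
        reac=reac,
        indi=indi.assign(indi_drug_seq=indi["indi_drug_seq"].astype("Int64")),
    )
    return SimResult(raw=raw, truth=truth, config=config)


def _type_demo(demo: pd.DataFrame) -> pd.DataFrame:
    """Apply the same typing read_quarter would (dates, age in years)."""
    out = demo.replace({"": pd.NA}).copy()
    out["caseversion"] = pd.to_numeric(out["caseversion"], errors="coerce").astype("Int64")
    out["fda_dt"] = pd.to_datetime(out["fda_dt"], format="%Y%m%d", errors="coerce")
    value = pd.to_numeric(out["age"], errors="coerce")
    factor = out["age_cod"].map({"YR": 1.0, "MON": 1 / 12, "DY": 1 / 365.25})
    out["age_years"] = value * factor
    return out


def expected_table(config: SimConfig, generic: str, pt: str) -> ExpectedCells:
    """Closed-form expected 2x2 cells (pre-duplication, real-valued).

    Enumerates suspect-exposure patterns over the target drug and every
    drug with an effect on ``pt``; all other drugs cannot influence the
    cells.  ``a + b`` equals the expected number of suspect-exposed
    reports for ``generic``; ``a + b + c + d == n_reports``.
    """
    config.validate()
    drug_index = {d.generic: d for d in config.drugs}
    pt_index = {p.name: p for p in config.pts}
    if generic not in drug_index:
        raise KeyError(f"unknown drug {generic!r}")
    if pt not in pt_index:
        raise KeyError(f"unknown PT {pt!r}")

    def p_suspect(d: DrugSpec) -> float:
        return d.exposure_prob * (d.role_dist[0] + d.role_dist[1])

    effects = {e.generic: e.ror for e in config.effects if e.pt == pt}
    enum = sorted(set(effects) | {generic})
    base_odds = pt_index[pt].background_prob / (1.0 - pt_index[pt].background_prob)

    cells = [0.0, 0.0, 0.0, 0.0]  # a, b, c, d as fractions
    for mask in range(1 << len(enum)):
        prob = 1.0
        odds = base_odds
        exposed_target = False
        for bit, name in enumerate(enum):
            ps = p_suspect(drug_index[name])
            if mask >> bit & 1:
                prob *= ps
                odds *= effects.get(name, 1.0)
                if name == generic:
                    exposed_target = True
            else:
                prob *= 1.0 - ps
        p_event = odds / (1.0 + odds)
        if exposed_target:
            cells[0] += prob * p_event
            cells[1] += prob * (1.0 - p_event)
        else:
            cells[2] += prob * p_event
            cells[3] += prob * (1.0 - p_event)
    n = float(config.n_reports)
    return ExpectedCells(*(n * x for x in cells))


def default_ppi_config(n_reports: int = 20_000, seed: int = 0) -> SimConfig:
    """A cohort emulating the proton-pump-inhibitor hepatotoxicity study.

    Five marketed PPIs (the two without any retrieved reports are left
    out), hepatotoxicity PTs at plausible background reporting rates
    plus common non-hepatic PTs, and injected per-drug effects at the
    reporting odds ratios the published per-drug analyses found
    (cholestasis, hepatitis cholestatic, coma hepatic, hepatitis
    fulminant).  Exposure probabilities are scaled up relative to a real
    multi-million-report database so that desk-scale cohorts contain
    enough exposed reports for stable 2x2 cells; relative drug
    frequencies are preserved.
    """
    drugs = (
        DrugSpec("omeprazole", ("Prilosec", "Losec", "Zegerid"), 0.030),
        DrugSpec("esomeprazole", ("Nexium",), 0.020),
        DrugSpec("lansoprazole", ("Prevacid", "Zoton"), 0.015),
        DrugSpec("rabeprazole", ("AcipHex", "Pariet"), 0.004),
        DrugSpec("pantoprazole", ("Protonix", "Pantoloc", "Controloc"), 0.025),
    )
    pts = (
        PTSpec("Cholestasis", 0.0030),
        PTSpec("Hepatitis cholestatic", 0.0010),
        PTSpec("Hepatitis fulminant", 0.0005),
        PTSpec("Coma hepatic", 0.0005),
        PTSpec("Hepatic encephalopathy", 0.0015),
        PTSpec("Hepatitis acute", 0.0015),
        PTSpec("Liver injury", 0.0040),
        PTSpec("Transaminases increased", 0.0060),
        PTSpec("Jaundice cholestatic", 0.0008),
        PTSpec("Nausea", 0.0900),
        PTSpec("Headache", 0.0700),
        PTSpec("Diarrhoea", 0.0600),
        PTSpec("Drug ineffective", 0.1200),
    )
    effects = (
        EffectSpec("esomeprazole", "Cholestasis", 21.556),
        EffectSpec("pantoprazole", "Cholestasis", 15.0),
        EffectSpec("pantoprazole", "Hepatitis cholestatic", 22.611),
        EffectSpec("lansoprazole", "Coma hepatic", 10.424),
        EffectSpec("rabeprazole", "Hepatitis fulminant", 40.240),
        EffectSpec("pantoprazole", "Hepatitis fulminant", 17.399),
        EffectSpec("pantoprazole", "Hepatic encephalopathy", 2.7),
    )
    return SimConfig(
        n_reports=n_reports,
        seed=seed,
        drugs=drugs,
        pts=pts,
        effects=effects,
        duplicate_version_rate=0.05,
        linkage_duplicate_rate=0.02,
        brand_name_rate=0.5,
        dose_suffix_rate=0.2,
        missing_age_rate=0.15,
        missing_sex_rate=0.08,
        missing_country_rate=0.05,
        year_range=(2013, 2019),
        concomitant_dist={0: 0.15, 1: 0.10, 2: 0.15, 3: 0.15, 4: 0.20, 5: 0.15, 6: 0.10},
        concomitant_pool=(
            "ASPIRIN", "ATORVASTATIN", "METFORMIN", "LISINOPRIL", "AMLODIPINE",
            "SIMVASTATIN", "FUROSEMIDE", "CEFTRIAXONE", "CIPROFLOXACIN",
            "AMOXICILLIN", "PREDNISONE", "WARFARIN", "CLOPIDOGREL", "INSULIN",
            "LEVOTHYROXINE", "IOPROMIDE", "METRONIDAZOLE", "SPIRONOLACTONE",
            "PARACETAMOL", "IBUPROFEN",
        ),
        indication_vocab=(
            "GASTROOESOPHAGEAL REFLUX DISEASE", "GASTRIC ULCER", "DUODENAL ULCER",
            "DYSPEPSIA", "HELICOBACTER INFECTION", "OESOPHAGITIS",
            "SKIN INFECTION", "HEPATIC CIRRHOSIS", "PROPHYLAXIS",
        ),
        unknown_indication_prob=0.5,
    )


def write_simulation(result: SimResult, directory: str) -> dict[str, str]:
    """Emit the quarterly dialect plus truth sidecar and config echo."""
    import os

    import yaml

    from .faers_model import write_quarter

    paths = write_quarter(result.raw, directory)
    truth_path = os.path.join(directory, "TRUTH.tsv")
    result.truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    cfg = dataclasses.asdict(result.config)
    cfg_path = os.path.join(directory, "simconfig.yaml")
    with open(cfg_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    paths["config"] = cfg_path
    return paths
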