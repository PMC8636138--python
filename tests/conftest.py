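import pandas as pd
import pytest

from pvsignal.event_catalog import builtin_hepatotoxicity_catalog
from pvsignal.faers_model import ReportSet
from pvsignal.lexicon import builtin_ppi_lexicon


@pytest.fixture(scope="session")
def ppi_lexicon():
    return builtin_ppi_lexicon()


@pytest.fixture(scope="session")
def hepatotox_catalog():
    return builtin_hepatotoxicity_catalog()


@pytest.fixture(scope="session")
def published_signal_table():
    """The published all-PPI ROR table (31 PT rows with footnote flags)."""
    from importlib import resources

    with resources.as_file(resources.files("pvsignal.data") / "published_ppi_signal_table.tsv") as p:
        return pd.read_csv(p, sep="\t")


def build_report_set(rows):
    """Construct a ReportSet from compact per-report dicts.

    Each dict may carry: primaryid, caseid, caseversion, fda_dt
    ("YYYY-MM-DD" or None), age_years, sex, country, drugs
    (list of (name, role)), reactions (list of PT), indications
    (list of (drugname, indication PT)).
    """
    reports, drugs, reacs, indis = [], [], [], []
    for i, r in enumerate(rows):
        pid = str(r.get("primaryid", i + 1))
        dt = r.get("fda_dt")
        ts = pd.Timestamp(dt) if dt else pd.NaT
        reports.append(
            {
                "primaryid": pid,
                "caseid": str(r.get("caseid", pid)),
                "caseversion": int(r.get("caseversion", 1)),
                "fda_first_dt": ts,
                "age_years": r.get("age_years"),
                "sex": r.get("sex"),
                "reporter_country": r.get("country"),
                "year": ts.year if dt else None,
            }
        )
        for seq, (name, role) in enumerate(r.get("drugs", []), start=1):
            drugs.append({"primaryid": pid, "drug_seq": seq, "role_cod": role, "drugname": name})
        for pt in r.get("reactions", ["Nausea"]):
            reacs.append({"primaryid": pid, "pt": pt})
        for dname, ipt in r.get("indications", []):
            indis.append({"primaryid": pid, "drugname": dname, "indi_pt": ipt})
    columns = ["primaryid", "caseid", "caseversion", "fda_first_dt", "age_years", "sex", "reporter_country", "year"]
    rep = pd.DataFrame(reports, columns=columns).set_index("primaryid")
    rep["age_years"] = pd.to_numeric(rep["age_years"])
    rep["year"] = rep["year"].astype("Int64")
    return ReportSet(
        reports=rep,
        drugs=pd.DataFrame(drugs, columns=["primaryid", "drug_seq", "role_cod", "drugname"]),
        reactions=pd.DataFrame(reacs, columns=["primaryid", "pt"]).drop_duplicates(),
        indications=pd.DataFrame(indis, columns=["primaryid", "drugname", "indi_pt"]),
    )


@pytest.fixture
def make_report_set():
    return build_report_set
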