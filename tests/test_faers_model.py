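import numpy as np
import pandas as pd
import pytest

from pvsignal.faers_model import (
    MissingColumnError,
    RawTables,
    assemble_reports,
    read_quarter,
    write_quarter,
)
from pvsignal.synthetic_data import default_ppi_config, simulate_cohort


def _write(tmp_path, name, lines):
    path = tmp_path / f"{name.upper()}.txt"
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return str(path)


@pytest.fixture
def quarter_dir(tmp_path):
    _write(
        tmp_path,
        "demo",
        [
            "primaryid$caseid$caseversion$fda_dt$age$age_cod$sex$reporter_country",
            "101$11$1$20150304$24$MON$F$US",
            "102$12$2$not-a-date$65$YR$M$JP",
            "103$13$1$20180101$730$DY$$",
        ],
    )
    _write(
        tmp_path,
        "drug",
        [
            "primaryid$drug_seq$role_cod$drugname",
            "101$1$PS$PROTONIX",
            "101$2$C$ASPIRIN",
            "102$1$SS$omeprazole 20mg",
        ],
    )
    _write(
        tmp_path,
        "reac",
        [
            "primaryid$pt",
            "101$Cholestasis",
            "101$Nausea",
            "101$Jaundice",
            "102$Hepatitis",
            "103$Headache",
        ],
    )
    _write(tmp_path, "indi", ["primaryid$indi_drug_seq$indi_pt", "101$1$GASTRIC ULCER"])
    return tmp_path


class TestReadQuarter:
    def test_row_counts_match_data_lines(self, quarter_dir):
        raw = read_quarter(str(quarter_dir))
        assert len(raw.demo) == 3
        assert len(raw.drug) == 3
        assert len(raw.reac) == 5

    def test_age_unit_conversion(self, quarter_dir):
        raw = read_quarter(str(quarter_dir))
        by_id = raw.demo.set_index("primaryid")["age_years"]
        assert by_id["101"] == pytest.approx(24 / 12)  # months
        assert by_id["102"] == pytest.approx(65.0)  # years
        assert by_id["103"] == pytest.approx(730 / 365.25)  # days

    def test_unknown_age_unit_becomes_missing(self, tmp_path):
        _write(tmp_path, "demo", [
            "primaryid$caseid$caseversion$fda_dt$age$age_cod$sex$reporter_country",
            "1$1$1$20150101$50$DEC$M$US",
        ])
        _write(tmp_path, "drug", ["primaryid$drug_seq$role_cod$drugname"])
        _write(tmp_path, "reac", ["primaryid$pt", "1$Nausea"])
        _write(tmp_path, "indi", ["primaryid$indi_drug_seq$indi_pt"])
        raw = read_quarter(str(tmp_path))
        assert pd.isna(raw.demo["age_years"].iloc[0])

    def test_unparseable_date_kept_as_missing(self, quarter_dir):
        raw = read_quarter(str(quarter_dir))
        assert pd.isna(raw.demo.set_index("primaryid")["fda_dt"]["102"])

    def test_missing_mandatory_column_raises(self, tmp_path):
        _write(tmp_path, "demo", ["caseid$caseversion$fda_dt$age$age_cod$sex$reporter_country", "1$1$20150101$50$YR$M$US"])
        _write(tmp_path, "drug", ["primaryid$drug_seq$role_cod$drugname"])
        _write(tmp_path, "reac", ["primaryid$pt"])
        _write(tmp_path, "indi", ["primaryid$indi_drug_seq$indi_pt"])
        with pytest.raises(MissingColumnError, match="primaryid"):
            read_quarter(str(tmp_path))

    def test_malformed_rows_counted_not_silent(self, tmp_path):
        _write(tmp_path, "demo", [
            "primaryid$caseid$caseversion$fda_dt$age$age_cod$sex$reporter_country",
            "1$1$1$20150101$50$YR$M$US",
            "2$2$1$20150101$40$YR$F$US$EXTRA$FIELDS",  # too many fields
        ])
        _write(tmp_path, "drug", ["primaryid$drug_seq$role_cod$drugname"])
        _write(tmp_path, "reac", ["primaryid$pt", "1$Nausea"])
        _write(tmp_path, "indi", ["primaryid$indi_drug_seq$indi_pt"])
        raw = read_quarter(str(tmp_path))
        assert len(raw.demo) == 1
        assert raw.notes["demo_malformed_rows"] == 1


class TestRoundTrip:
    def test_write_then_read_preserves_fields(self, tmp_path):
        sim = simulate_cohort(default_ppi_config(n_reports=300, seed=5))
        out = tmp_path / "quarter"
        write_quarter(sim.raw, str(out))
        back = read_quarter(str(out))
        for name in ("demo", "drug", "reac", "indi"):
            a = sim.raw.tables()[name].reset_index(drop=True)
            b = back.tables()[name].reset_index(drop=True)
            assert len(a) == len(b)
        pd.testing.assert_series_equal(
            sim.raw.demo["fda_dt"], back.demo["fda_dt"], check_names=False
        )
        pd.testing.assert_series_equal(
            sim.raw.demo["age_years"].astype(float),
            back.demo["age_years"].astype(float),
            check_names=False,
        )
        assert list(sim.raw.reac["pt"]) == list(back.reac["pt"])


class TestAssembleReports:
    def test_hand_counted_attachment(self, quarter_dir):
        rs = assemble_reports(read_quarter(str(quarter_dir)))
        rep = rs.to_reports()
        by_id = {r.primaryid: r for r in rep}
        assert len(by_id["101"].drugs) == 2
        assert len(by_id["101"].reactions) == 3
        assert by_id["101"].year == 2015
        assert by_id["102"].year is None  # bad date
        assert by_id["101"].indications == (("PROTONIX", "GASTRIC ULCER"),)

    def test_report_without_reactions_excluded_and_counted(self, tmp_path):
        _write(tmp_path, "demo", [
            "primaryid$caseid$caseversion$fda_dt$age$age_cod$sex$reporter_country",
            "1$1$1$20150101$50$YR$M$US",
            "2$2$1$20150101$40$YR$F$US",
        ])
        _write(tmp_path, "drug", ["primaryid$drug_seq$role_cod$drugname"])
        _write(tmp_path, "reac", ["primaryid$pt", "1$Nausea"])
        _write(tmp_path, "indi", ["primaryid$indi_drug_seq$indi_pt"])
        rs = assemble_reports(read_quarter(str(tmp_path)))
        assert len(rs) == 1
        assert rs.log["excluded_no_reactions"] == 1

    def test_orphan_reaction_rows_skipped_and_logged(self, tmp_path):
        _write(tmp_path, "demo", [
            "primaryid$caseid$caseversion$fda_dt$age$age_cod$sex$reporter_country",
            "1$1$1$20150101$50$YR$M$US",
        ])
        _write(tmp_path, "drug", ["primaryid$drug_seq$role_cod$drugname"])
        _write(tmp_path, "reac", ["primaryid$pt", "1$Nausea", "999$Headache"])
        _write(tmp_path, "indi", ["primaryid$indi_drug_seq$indi_pt"])
        rs = assemble_reports(read_quarter(str(tmp_path)))
        assert len(rs) == 1
        assert rs.log["skipped_orphan_reac_rows"] == 1

    def test_empty_tables_give_empty_collection(self):
        cols = {
            "demo": ["primaryid", "caseid", "caseversion", "fda_dt", "age", "age_cod", "sex", "reporter_country", "age_years"],
            "drug": ["primaryid", "drug_seq", "role_cod", "drugname"],
            "reac": ["primaryid", "pt"],
            "indi": ["primaryid", "indi_drug_seq", "indi_pt"],
        }
        raw = RawTables(**{k: pd.DataFrame(columns=v) for k, v in cols.items()})
        assert len(assemble_reports(raw)) == 0

    def test_reaction_count_preserved_on_synthetic_cohort(self):
        sim = simulate_cohort(default_ppi_config(n_reports=500, seed=9))
        rs = assemble_reports(sim.raw)
        distinct_pairs = sim.raw.reac.drop_duplicates().shape[0]
        assert len(rs.reactions) + rs.log.get("skipped_orphan_reac_rows", 0) == distinct_pairs
        assert sum(len(r.reactions) for r in rs.to_reports()) == len(rs.reactions)
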