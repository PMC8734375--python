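"""Readers: accounting (accepted + rejected = input), dedup, conflicts."""

import csv
import random

import pytest

from conftest import PDPI_HEADER, TABLE1_ROWS, write_pdpi
from rxmass.ingest import (
    MissingColumnError,
    combine_monthly,
    read_dmd,
    read_practices,
    read_prescriptions,
    read_snomed_map,
    read_unit_table,
    write_prescriptions,
)

# The six printed mapping rows: one clarithromycin brand tablet (2 pack codes)
# and a clarithromycin IV infusion presentation owning four product codes.
TABLE2_ROWS = [
    ["'0501050B0BEAAAE'", "18149311000001103", "Clarie XL_Tab 500 mg"],
    ["'0501050B0BEAAAE'", "18149411000001105", "Clarie XL_Tab 500 mg"],
    ["'0501050B0AAACAC'", "34751711000001107", "Clarithromycin_I/V Inf 500 mg Vl"],
    ["'0501050B0AAACAC'", "13469811000001104", "Clarithromycin_I/V Inf 500 mg Vl"],
    ["'0501050B0AAACAC'", "17997811000001100", "Clarithromycin_I/V Inf 500 mg Vl"],
    ["'0501050B0AAACAC'", "13613011000001105", "Clarithromycin_I/V Inf 500 mg Vl"],
]


def write_snomed(path, rows):
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["bnf_code", "snomed_code", "description"])
        w.writerows(rows)
    return path


class TestReadPrescriptions:
    def test_worked_example_rows_all_accepted(self, table1_csv):
        records, rejects = read_prescriptions(table1_csv)
        assert len(records) == 5 and rejects.empty
        assert records.loc[0, "bnf_name"] == "Phenergan_Tab 25 mg"
        assert records.loc[0, "quantity"] == 98.0
        assert list(records["items"]) == [3, 7, 5, 3, 1]

    def test_header_only_file_is_empty(self, tmp_path):
        path = write_pdpi(tmp_path / "empty.csv", [])
        records, rejects = read_prescriptions(path)
        assert records.empty and rejects.empty

    def test_bad_month_routed_to_reject_log(self, tmp_path):
        row = list(TABLE1_ROWS[0])
        row[9] = "201813"
        records, rejects = read_prescriptions(write_pdpi(tmp_path / "bad.csv", [row]))
        assert len(records) == 0 and len(rejects) == 1
        assert "month" in rejects.loc[0, "reason"]

    def test_short_bnf_code_rejected_not_dropped(self, tmp_path):
        row = list(TABLE1_ROWS[0])
        row[3] = "0304010W0"
        records, rejects = read_prescriptions(write_pdpi(tmp_path / "short.csv", [row]))
        assert len(records) == 0 and len(rejects) == 1
        assert "BNF code" in rejects.loc[0, "reason"]

    def test_missing_column_is_hard_error_naming_it(self, tmp_path):
        path = tmp_path / "nohdr.csv"
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow([c for c in PDPI_HEADER if c != "QUANTITY"])
        with pytest.raises(MissingColumnError, match="QUANTITY"):
            read_prescriptions(path)

    def test_column_order_insensitive(self, tmp_path):
        path = tmp_path / "shuffled.csv"
        order = list(range(len(PDPI_HEADER)))
        random.Random(3).shuffle(order)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow([PDPI_HEADER[i] for i in order])
            for row in TABLE1_ROWS:
                w.writerow([row[i] for i in order])
        records, rejects = read_prescriptions(path)
        assert len(records) == 5 and rejects.empty

    def test_accounting_accepted_plus_rejected_equals_input(self, tmp_path):
        bad = list(TABLE1_ROWS[1]); bad[9] = "999999"
        rows = TABLE1_ROWS + [bad]
        records, rejects = read_prescriptions(write_pdpi(tmp_path / "mix.csv", rows))
        assert len(records) + len(rejects) == len(rows)

    def test_write_read_round_trip(self, table1_csv, tmp_path):
        records, _ = read_prescriptions(table1_csv)
        out = tmp_path / "out.csv"
        write_prescriptions(records, out)
        assert open(out).read() == open(table1_csv).read()


class TestCombineMonthly:
    def test_row_count_additivity(self, tmp_path):
        for n, name in [(5, "a"), (7, "b"), (2, "c")]:
            write_pdpi(tmp_path / f"{name}.csv", [TABLE1_ROWS[i % 5] for i in range(n)])
        combined, rejects = combine_monthly(tmp_path)
        assert len(combined) == 14 and rejects.empty

    def test_duplicate_file_rows_kept_with_provenance(self, tmp_path):
        write_pdpi(tmp_path / "m1.csv", TABLE1_ROWS)
        write_pdpi(tmp_path / "m2.csv", TABLE1_ROWS)
        combined, _ = combine_monthly(tmp_path)
        assert len(combined) == 10
        assert set(combined["source_file"]) == {"m1.csv", "m2.csv"}

    def test_empty_directory_is_hard_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            combine_monthly(tmp_path)

    def test_fixture_counts_match_generator_ledger(self, small_bundle):
        combined, rejects = combine_monthly(small_bundle.pdpi_dir)
        ledger = small_bundle.ledger()
        assert len(combined) == ledger["total_input_rows"]
        assert rejects.empty
        per_file = combined.groupby("source_file").size().to_dict()
        assert per_file == ledger["per_file_rows"]


class TestReadSnomedMap:
    def test_printed_mapping_rows(self, tmp_path):
        rows, rejects, n_dupes = read_snomed_map(write_snomed(tmp_path / "map.csv", TABLE2_ROWS))
        assert len(rows) == 6 and rejects.empty and n_dupes == 0
        owned = rows[rows["bnf_code"] == "0501050B0AAACAC"]
        assert len(owned) == 4

    def test_duplicate_pair_collapsed_and_counted(self, tmp_path):
        rows, _, n_dupes = read_snomed_map(
            write_snomed(tmp_path / "dup.csv", TABLE2_ROWS + [TABLE2_ROWS[0]])
        )
        assert len(rows) == 6 and n_dupes == 1

    def test_non_numeric_snomed_code_rejected(self, tmp_path):
        bad = [["'0501050B0BEAAAE'", "NOTANUMBER", "x"]]
        rows, rejects, _ = read_snomed_map(write_snomed(tmp_path / "bad.csv", bad))
        assert rows.empty and len(rejects) == 1
        assert "numeric" in rejects.loc[0, "reason"]


class TestReadDmd:
    def test_fixture_node_counts_match_ledger(self, small_bundle):
        graph, rejects = read_dmd(small_bundle.dmd_dir)
        counts = small_bundle.ledger()["node_counts"]
        assert len(graph.ingredients) == counts["ingredients"]
        assert len(graph.vmps) == counts["vmps"]
        assert len(graph.vpi) == counts["vpi"]
        assert len(graph.amps) == counts["amps"]
        assert len(graph.vmpps) == counts["vmpps"]
        assert len(graph.ampps) == counts["ampps"]
        assert rejects.empty

    def test_missing_table_is_hard_error_naming_it(self, small_bundle, tmp_path):
        import shutil

        partial = tmp_path / "dmd"
        shutil.copytree(small_bundle.dmd_dir, partial)
        (partial / "vpi.csv").unlink()
        with pytest.raises(FileNotFoundError, match="vpi"):
            read_dmd(partial)

    def test_zero_strength_vpi_row_rejected(self, small_bundle, tmp_path):
        import shutil

        broken = tmp_path / "dmd"
        shutil.copytree(small_bundle.dmd_dir, broken)
        with open(broken / "vpi.csv", "a", newline="") as fh:
            csv.writer(fh).writerow(["200000", "100000", "0", "mg", "", ""])
        graph, rejects = read_dmd(broken)
        assert len(rejects) == 1
        assert "not positive" in rejects.loc[0, "reason"]


class TestReadPractices:
    def _addr(self, path, rows):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["PERIOD", "PRACTICE", "NAME", "ADDRESS", "POSTCODE"])
            w.writerows(rows)
        return path

    def test_same_postcode_across_periods_collapses(self, tmp_path):
        a = self._addr(tmp_path / "a.csv", [["201801", "P1", "One", "x", "BA1 1AA"]])
        b = self._addr(tmp_path / "b.csv", [["201802", "P1", "One", "x", "BA1 1AA"]])
        directory, conflicts = read_practices([a, b])
        assert len(directory) == 1 and conflicts.empty

    def test_conflicting_postcodes_latest_period_wins_and_logged(self, tmp_path):
        a = self._addr(
            tmp_path / "a.csv",
            [["201801", "P1", "One", "x", "BA1 1AA"], ["201803", "P1", "One", "x", "BA2 2BB"]],
        )
        directory, conflicts = read_practices(a)
        assert directory.loc[0, "postcode"] == "BA2 2BB"
        assert len(conflicts) == 1
        assert conflicts.loc[0, "postcode_superseded"] == "BA1 1AA"

    def test_empty_addr_gives_empty_directory(self, tmp_path):
        directory, conflicts = read_practices(self._addr(tmp_path / "e.csv", []))
        assert directory.empty and conflicts.empty


class TestReadUnitTable:
    def _units(self, path, rows):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["unit", "factor_to_kg", "kind"])
            w.writerows(rows)
        return path

    def test_mass_factors_definitional(self, tmp_path):
        from decimal import Decimal

        table, rejects = read_unit_table(
            self._units(tmp_path / "u.csv", [["mg", "1e-6", ""], ["microgram", "1e-9", ""]])
        )
        assert rejects.empty
        assert table.factor_to_kg("mg") == Decimal("1e-6")
        assert table.factor_to_kg("microgram") == Decimal("1e-9")

    def test_negative_factor_rejected(self, tmp_path):
        table, rejects = read_unit_table(
            self._units(tmp_path / "neg.csv", [["mg", "-1e-6", ""]])
        )
        assert not table.is_mass("mg")
        assert len(rejects) == 1

    def test_unknown_kind_rejected(self, tmp_path):
        table, rejects = read_unit_table(self._units(tmp_path / "k.csv", [["blob", "", "mystery"]]))
        assert len(rejects) == 1
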