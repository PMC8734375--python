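import pandas as pd
import pytest

from rxmass.synth import FixtureConfig, generate_fixture
from rxmass.units import default_unit_table

# Five worked-example prescribing rows in the ten-column extract dialect:
# an antihistamine tablet, a hypnotic, a benzodiazepine and two strengths of
# an antipsychotic, all dispensed by one practice in January 2018.
TABLE1_ROWS = [
    ["Q44", "RTV", "Y04937", "0304010W0BBABAL", "Phenergan_Tab 25 mg", "3", "8.15", "7.89", "98", "201801"],
    ["Q44", "RTV", "Y04937", "0401010Z0AAAAAA", "Zopiclone_Tab 7.5 mg", "7", "2.88", "3.35", "98", "201801"],
    ["Q44", "RTV", "Y04937", "0401020K0AAAHAH", "Diazepam_Tab 2 mg", "5", "3.76", "3.94", "191", "201801"],
    ["Q44", "RTV", "Y04937", "0402010ADAAAAAA", "Aripiprazole_Tab 10 mg", "3", "13.64", "12.88", "63", "201801"],
    ["Q44", "RTV", "Y04937", "0402010ADAAADAD", "Aripiprazole_Tab 5 mg", "1", "1.36", "1.37", "7", "201801"],
]

PDPI_HEADER = ["SHA", "PCT", "PRACTICE", "BNF CODE", "BNF NAME", "ITEMS", "NIC", "ACT COST", "QUANTITY", "PERIOD"]


def write_pdpi(path, rows):
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(PDPI_HEADER)
        w.writerows(rows)
    return path


@pytest.fixture
def table1_csv(tmp_path):
    return write_pdpi(tmp_path / "pdpi_201801.csv", TABLE1_ROWS)


@pytest.fixture(scope="session")
def units():
    return default_unit_table()


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """Small deterministic fixture bundle shared across tests."""
    cfg = FixtureConfig(seed=11, n_practices=5, n_months=3, rows_per_practice_month=8)
    return generate_fixture(cfg, tmp_path_factory.mktemp("bundle"))


@pytest.fixture(scope="session")
def small_pipeline(small_bundle):
    """Full pipeline run over the small bundle; reused by several tests."""
    from helpers import run_pipeline

    return run_pipeline(small_bundle)


def as_df(rows, columns):
    return pd.DataFrame(rows, columns=columns)
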