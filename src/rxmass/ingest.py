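"""Readers for every input dialect.

All readers follow the same contract: rows are processed one at a time
(streaming), well-formed rows become records, malformed rows land in a reject
log with a reason, and ``accepted + rejected == input rows`` always holds.
Header matching is name-based and order-insensitive, since real extracts vary
column order across years.

Input dialects
--------------
* PDPI prescribing extract: CSV, columns SHA, PCT, PRACTICE, BNF CODE,
  BNF NAME, ITEMS, NIC, ACT COST, QUANTITY, PERIOD.
* BNF↔SNOMED map: CSV, columns bnf_code, snomed_code, description.
* dm+d-style hierarchy: six CSVs (ingredient, vmp, vpi, amp, vmpp, ampp)
  plus an optional form table — a tabular stand-in for the real XML releases.
* ADDR practice directory: CSV, columns PERIOD, PRACTICE, NAME, ADDRESS,
  POSTCODE.
* Postcode lookup (NSPL subset): CSV, columns pcds, long, lat.
* Unit table: CSV, columns unit, factor_to_kg, kind (factor for mass units,
  kind for the rest).
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import pandas as pd

from .core import (
    DMD_TABLES,
    GRAPH_COLUMNS,
    PDPI_COLUMNS,
    ProductGraph,
    RecordError,
    normalise_postcode,
    parse_period,
    record_from_row,
    record_to_row,
    reject_frame,
)
from .units import UnitTable

logger = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "sha", "pct", "practice", "bnf_code", "bnf_name",
    "items", "nic", "act_cost", "quantity", "period",
]


class MissingColumnError(ValueError):
    pass


def _open_reader(path: Path):
    return open(path, newline="", encoding="utf-8")


def _check_header(header: list[str], required: list[str], path: Path) -> None:
    have = {h.strip().upper() for h in header}
    for col in required:
        if col.upper() not in have:
            raise MissingColumnError(f"{path}: missing required column {col!r}")


def read_prescriptions(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read one PDPI file → (records table, reject log).

    Every input row is accounted for: it either becomes a record or a reject
    row with a reason.  An empty file (header only) yields an empty table.
    """
    path = Path(path)
    records, rejects = [], []
    with _open_reader(path) as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            logger.warning("%s: empty file", path)
            return pd.DataFrame(columns=RECORD_COLUMNS), reject_frame([])
        _check_header(reader.fieldnames, PDPI_COLUMNS, path)
        key = {h.strip().upper(): h for h in reader.fieldnames}
        for i, raw in enumerate(reader, start=2):
            row = {c: raw.get(key[c.upper()], "") for c in PDPI_COLUMNS}
            try:
                rec = record_from_row(row)
            except RecordError as exc:
                rejects.append(
                    {"source": str(path), "row_number": i, "reason": str(exc), "raw": row}
                )
                continue
            records.append(
                {
                    "sha": rec.sha, "pct": rec.pct, "practice": rec.practice,
                    "bnf_code": rec.bnf_code, "bnf_name": rec.bnf_name,
                    "items": rec.items, "nic": rec.nic, "act_cost": rec.act_cost,
                    "quantity": rec.quantity, "period": rec.period,
                }
            )
    if not records:
        logger.warning("%s: no accepted rows", path)
    return pd.DataFrame(records, columns=RECORD_COLUMNS), reject_frame(rejects)


def write_prescriptions(records: pd.DataFrame, path: str | Path) -> None:
    """Write records back out in the PDPI dialect (round-trips bit-identically)."""
    from .core import PrescriptionRecord

    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=PDPI_COLUMNS)
        writer.writeheader()
        for _, r in records.iterrows():
            rec = PrescriptionRecord(
                sha=r["sha"], pct=r["pct"], practice=r["practice"],
                bnf_code=r["bnf_code"], bnf_name=r["bnf_name"], items=int(r["items"]),
                nic=r["nic"], act_cost=r["act_cost"],
                quantity=float(r["quantity"]), period=r["period"],
            )
            writer.writerow(record_to_row(rec))


def combine_monthly(
    directory: str | Path, pattern: str = "*.csv"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concatenate every monthly PDPI file in *directory*.

    Adds a ``source_file`` provenance column; duplicated files stay duplicated
    (provenance distinguishes them).  Raises FileNotFoundError when nothing
    matches.
    """
    directory = Path(directory)
    files = sorted(directory.glob(pattern))
    if not files:
        raise FileNotFoundError(f"no files matching {pattern!r} in {directory}")
    tables, rejects = [], []
    for f in files:
        tab, rej = read_prescriptions(f)
        tab = tab.assign(source_file=f.name)
        tables.append(tab)
        rejects.append(rej)
    combined = pd.concat(tables, ignore_index=True)
    return combined, pd.concat(rejects, ignore_index=True)


def read_snomed_map(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Read the BNF↔SNOMED mapping → (rows, rejects, n_duplicates_collapsed).

    (bnf_code, snomed_code) pairs are unique after deduplication; the collapsed
    count is returned so nothing disappears silently.  SNOMED codes must be
    integer-like.
    """
    path = Path(path)
    rows, rejects = [], []
    with _open_reader(path) as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return pd.DataFrame(columns=["bnf_code", "snomed_code", "description"]), reject_frame([]), 0
        _check_header(reader.fieldnames, ["bnf_code", "snomed_code"], path)
        key = {h.strip().upper(): h for h in reader.fieldnames}
        for i, raw in enumerate(reader, start=2):
            bnf_raw = raw.get(key["BNF_CODE"], "")
            sno = str(raw.get(key["SNOMED_CODE"], "")).strip().strip("'\"")
            desc = str(raw.get(key.get("DESCRIPTION", ""), "") or "").strip()
            try:
                from .core import normalise_bnf_code

                bnf = normalise_bnf_code(bnf_raw)
                if not sno.isdigit():
                    raise RecordError(f"snomed code {sno!r} is not numeric")
            except RecordError as exc:
                rejects.append(
                    {"source": str(path), "row_number": i, "reason": str(exc), "raw": dict(raw)}
                )
                continue
            rows.append({"bnf_code": bnf, "snomed_code": sno, "description": desc})
    df = pd.DataFrame(rows, columns=["bnf_code", "snomed_code", "description"])
    before = len(df)
    df = df.drop_duplicates(subset=["bnf_code", "snomed_code"], keep="first").reset_index(drop=True)
    n_dupes = before - len(df)
    if n_dupes:
        logger.info("%s: collapsed %d duplicate (bnf, snomed) pairs", path, n_dupes)
    return df, reject_frame(rejects), n_dupes


_DMD_FILE_COLUMNS = {
    "ingredient": GRAPH_COLUMNS["ingredients"],
    "vmp": GRAPH_COLUMNS["vmps"],
    "vpi": GRAPH_COLUMNS["vpi"],
    "amp": GRAPH_COLUMNS["amps"],
    "vmpp": GRAPH_COLUMNS["vmpps"],
    "ampp": GRAPH_COLUMNS["ampps"],
    "form": GRAPH_COLUMNS["forms"],
}


def read_dmd(directory: str | Path) -> tuple[ProductGraph, pd.DataFrame]:
    """Load the six dm+d-style tables from *directory* → (graph, reject log).

    Expects ``<table>.csv`` for ingredient, vmp, vpi, amp, vmpp, ampp (form
    optional).  A missing mandatory table is a hard error naming it.  VPI rows
    with non-positive strength are rejected, not loaded.
    """
    directory = Path(directory)
    frames: dict[str, pd.DataFrame] = {}
    rejects = []
    for table in DMD_TABLES + ["form"]:
        f = directory / f"{table}.csv"
        if not f.exists():
            if table == "form":
                continue
            raise FileNotFoundError(f"missing dm+d table {table!r} ({f})")
        df = pd.read_csv(f, dtype=str, keep_default_na=False)
        missing = [c for c in _DMD_FILE_COLUMNS[table] if c not in df.columns]
        # denominator columns may be absent in discrete-only datasets
        missing = [c for c in missing if not c.startswith("denominator")]
        if missing:
            raise MissingColumnError(f"{f}: missing columns {missing}")
        frames[table] = df
    vpi = frames["vpi"].copy()
    for col in ("denominator_value", "denominator_unit"):
        if col not in vpi.columns:
            vpi[col] = ""
    vpi["strength_value"] = pd.to_numeric(vpi["strength_value"], errors="coerce")
    bad = vpi["strength_value"].isna() | (vpi["strength_value"] <= 0)
    for _, row in vpi[bad].iterrows():
        rejects.append(
            {
                "source": str(directory / "vpi.csv"),
                "row_number": -1,
                "reason": f"strength_value {row['strength_value']!r} not positive",
                "raw": row.to_dict(),
            }
        )
    vpi = vpi[~bad].reset_index(drop=True)
    vpi["denominator_value"] = pd.to_numeric(vpi["denominator_value"], errors="coerce")
    graph = ProductGraph(
        ingredients=frames["ingredient"],
        vmps=frames["vmp"],
        vpi=vpi,
        amps=frames["amp"],
        vmpps=frames["vmpp"],
        ampps=frames["ampp"],
        forms=frames.get("form", ProductGraph().forms),
    )
    return graph, reject_frame(rejects)


ADDR_COLUMNS = ["PERIOD", "PRACTICE", "NAME", "ADDRESS", "POSTCODE"]


def read_practices(paths: list[str | Path] | str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combine ADDR files → (practice directory, conflict log).

    One row per practice code; when postcodes conflict across periods the
    latest period wins and earlier values are logged (practices move; the
    extracts are silent about it).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    rows = []
    for path in paths:
        path = Path(path)
        with _open_reader(path) as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                continue
            _check_header(reader.fieldnames, ["PERIOD", "PRACTICE", "POSTCODE"], path)
            key = {h.strip().upper(): h for h in reader.fieldnames}
            for raw in reader:
                rows.append(
                    {
                        "period": parse_period(raw[key["PERIOD"]]),
                        "practice": str(raw[key["PRACTICE"]]).strip(),
                        "name": str(raw.get(key.get("NAME", ""), "") or "").strip(),
                        "address": str(raw.get(key.get("ADDRESS", ""), "") or "").strip(),
                        "postcode": normalise_postcode(raw[key["POSTCODE"]]),
                    }
                )
    df = pd.DataFrame(rows, columns=["period", "practice", "name", "address", "postcode"])
    conflicts = []
    if not df.empty:
        df = df.sort_values(["practice", "period"], kind="stable")
        for practice, grp in df.groupby("practice", sort=True):
            if grp["postcode"].nunique() > 1:
                kept = grp.iloc[-1]
                for _, old in grp[grp["postcode"] != kept["postcode"]].iterrows():
                    conflicts.append(
                        {
                            "practice": practice,
                            "period": old["period"],
                            "postcode_superseded": old["postcode"],
                            "postcode_kept": kept["postcode"],
                        }
                    )
        df = df.drop_duplicates(subset=["practice"], keep="last").reset_index(drop=True)
        df = df.drop(columns=["period"])
    else:
        df = pd.DataFrame(columns=["practice", "name", "address", "postcode"])
    return df[["practice", "name", "address", "postcode"]], pd.DataFrame(
        conflicts, columns=["practice", "period", "postcode_superseded", "postcode_kept"]
    )


def read_postcode_lookup(path: str | Path) -> pd.DataFrame:
    """NSPL-style lookup: pcds, long, lat → normalised unique postcodes."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"pcds": str})
    for col in ("pcds", "long", "lat"):
        if col not in df.columns:
            raise MissingColumnError(f"{path}: missing required column {col!r}")
    df["postcode"] = df["pcds"].map(normalise_postcode)
    df = df.drop_duplicates(subset=["postcode"], keep="first")
    return df[["postcode", "long", "lat"]].rename(columns={"long": "lon"}).reset_index(drop=True)


def read_unit_table(path: str | Path) -> tuple[UnitTable, pd.DataFrame]:
    """Unit-of-measure multiplication-factor file → (UnitTable, reject log).

    Rows carry either a positive ``factor_to_kg`` (mass units) or a ``kind``
    tag (volume | count | percent).  Anything else is rejected.
    """
    path = Path(path)
    table = UnitTable()
    rejects = []
    with _open_reader(path) as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return table, reject_frame([])
        _check_header(reader.fieldnames, ["unit"], path)
        key = {h.strip().upper(): h for h in reader.fieldnames}
        for i, raw in enumerate(reader, start=2):
            unit = str(raw[key["UNIT"]]).strip()
            factor = str(raw.get(key.get("FACTOR_TO_KG", ""), "") or "").strip()
            kind = str(raw.get(key.get("KIND", ""), "") or "").strip()
            try:
                if factor:
                    table.add_mass(unit, factor)
                elif kind:
                    table.add_kind(unit, kind)
                else:
                    raise ValueError("row has neither factor_to_kg nor kind")
            except (ValueError, ArithmeticError) as exc:
                rejects.append(
                    {"source": str(path), "row_number": i, "reason": str(exc), "raw": dict(raw)}
                )
    return table, reject_frame(rejects)
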