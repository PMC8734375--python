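"""Shared domain types for the prescribing-mass pipeline.

The pipeline turns monthly practice-level prescribing extracts (the ten-column
PDPI dialect) into per-ingredient dispensed mass in kilograms.  Everything
downstream consumes the types defined here:

* :class:`PrescriptionRecord` — one dispensed line of the PDPI extract.
* :class:`ProductGraph` — a dm+d-style product hierarchy (ingredients, virtual
  and actual medicinal products, their packs, and medicinal forms) held as
  plain DataFrames with referential links between them.
* :func:`validate_graph` — referential-integrity scan over a ProductGraph.

Normalisation helpers (BNF codes, postcodes, periods) live here because every
reader and every join relies on the same canonical forms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from typing import Iterable

import pandas as pd

#: Presentation codes in the national prescribing extract are fixed-width:
#: chapter/section/paragraph + chemical + product + strength/formulation.
BNF_CODE_LENGTH = 15

#: Column order of the monthly prescribing extract (PDPI dialect).
PDPI_COLUMNS = [
    "SHA",
    "PCT",
    "PRACTICE",
    "BNF CODE",
    "BNF NAME",
    "ITEMS",
    "NIC",
    "ACT COST",
    "QUANTITY",
    "PERIOD",
]

#: The six mandatory dm+d-style interchange tables plus the optional form table.
DMD_TABLES = ["ingredient", "vmp", "vpi", "amp", "vmpp", "ampp"]
DMD_OPTIONAL_TABLES = ["form"]


class RecordError(ValueError):
    """A field failed validation; carries the reason used in reject logs."""


def normalise_bnf_code(raw: str) -> str:
    """Canonicalise a BNF presentation code.

    Strips surrounding whitespace and quote characters and upper-cases.
    Raises :class:`RecordError` unless exactly 15 characters remain — short or
    padded codes are routed to reject logs by callers, never silently fixed.
    """
    code = str(raw).strip().strip("'\"").strip().upper()
    if len(code) != BNF_CODE_LENGTH:
        raise RecordError(
            f"BNF code {code!r} has {len(code)} characters, expected {BNF_CODE_LENGTH}"
        )
    if not code.isalnum():
        raise RecordError(f"BNF code {code!r} contains non-alphanumeric characters")
    return code


def normalise_postcode(raw: str) -> str:
    """Upper-case, single internal space (outward and inward halves).

    ``"ba1  1aa"`` → ``"BA1 1AA"``; an unspaced ``"BA11AA"`` has the 3-character
    inward half split off.  Empty input stays empty.
    """
    s = re.sub(r"\s+", " ", str(raw).strip().upper())
    if " " not in s and len(s) >= 5:
        s = s[:-3] + " " + s[-3:]
    return s


_PERIOD_RE = re.compile(r"^(\d{4})(\d{2})$")


def parse_period(raw: str) -> str:
    """Validate a YYYYMM period string; returns it canonicalised.

    Raises :class:`RecordError` if not six digits or the month is outside 1–12.
    """
    m = _PERIOD_RE.match(str(raw).strip())
    if not m:
        raise RecordError(f"period {raw!r} is not YYYYMM")
    month = int(m.group(2))
    if not 1 <= month <= 12:
        raise RecordError(f"period {raw!r} has month {month} outside 1..12")
    return m.group(0)


def period_year(period: str) -> int:
    return int(period[:4])


def parse_decimal(raw: str, name: str) -> Decimal:
    try:
        return Decimal(str(raw).strip())
    except InvalidOperation as exc:
        raise RecordError(f"{name} {raw!r} is not a decimal number") from exc


@dataclass(frozen=True)
class PrescriptionRecord:
    """One dispensed line of the monthly prescribing extract.

    ``quantity`` is the dispensed quantity in formulation-dependent units
    (tablets, ml, g …); ``items`` counts prescription items and is never used
    in mass computation.  Cost fields are carried as exact decimals but play
    no computational role.
    """

    sha: str
    pct: str
    practice: str
    bnf_code: str
    bnf_name: str
    items: int
    nic: Decimal
    act_cost: Decimal
    quantity: float
    period: str

    def __post_init__(self) -> None:
        if self.items < 0:
            raise RecordError(f"items {self.items} is negative")
        if self.quantity < 0:
            raise RecordError(f"quantity {self.quantity} is negative")


def record_from_row(row: dict) -> PrescriptionRecord:
    """Build a validated record from a raw PDPI row (dict keyed by column name)."""
    items_raw = str(row["ITEMS"]).strip()
    try:
        items = int(items_raw)
    except ValueError as exc:
        raise RecordError(f"items {items_raw!r} is not an integer") from exc
    qty_raw = str(row["QUANTITY"]).strip()
    try:
        quantity = float(qty_raw)
    except ValueError as exc:
        raise RecordError(f"quantity {qty_raw!r} is not a number") from exc
    return PrescriptionRecord(
        sha=str(row["SHA"]).strip(),
        pct=str(row["PCT"]).strip(),
        practice=str(row["PRACTICE"]).strip(),
        bnf_code=normalise_bnf_code(row["BNF CODE"]),
        bnf_name=str(row["BNF NAME"]).strip(),
        items=items,
        nic=parse_decimal(row["NIC"], "NIC"),
        act_cost=parse_decimal(row["ACT COST"], "ACT COST"),
        quantity=quantity,
        period=parse_period(row["PERIOD"]),
    )


def record_to_row(rec: PrescriptionRecord) -> dict:
    """Inverse of :func:`record_from_row`; round-trips bit-identically."""
    return {
        "SHA": rec.sha,
        "PCT": rec.pct,
        "PRACTICE": rec.practice,
        "BNF CODE": rec.bnf_code,
        "BNF NAME": rec.bnf_name,
        "ITEMS": str(rec.items),
        "NIC": str(rec.nic),
        "ACT COST": str(rec.act_cost),
        "QUANTITY": (
            str(int(rec.quantity)) if float(rec.quantity).is_integer() else repr(rec.quantity)
        ),
        "PERIOD": rec.period,
    }


# --------------------------------------------------------------------------
# Product hierarchy
# --------------------------------------------------------------------------

GRAPH_COLUMNS = {
    "ingredients": ["ingredient_id", "name"],
    "vmps": ["vmp_id", "name", "form_id"],
    "vpi": [
        "vmp_id",
        "ingredient_id",
        "strength_value",
        "strength_unit",
        "denominator_value",
        "denominator_unit",
    ],
    "amps": ["amp_id", "vmp_id", "name", "supplier"],
    "vmpps": ["vmpp_id", "vmp_id", "pack_size", "pack_unit"],
    "ampps": ["ampp_id", "amp_id", "vmpp_id"],
    "forms": ["form_id", "name"],
}


def _empty(table: str) -> pd.DataFrame:
    return pd.DataFrame(columns=GRAPH_COLUMNS[table])


@dataclass
class ProductGraph:
    """dm+d-style product hierarchy.

    Tables (all id columns are strings; SNOMED identifiers are integer-like
    strings):

    * ``ingredients``: ingredient_id, name
    * ``vmps``: vmp_id, name, form_id — virtual medicinal products
    * ``vpi``: vmp_id, ingredient_id, strength_value, strength_unit,
      denominator_value, denominator_unit — ingredient strengths per VMP;
      the denominator pair is present only for concentration products
      (e.g. 5 mg per 1 ml)
    * ``amps``: amp_id, vmp_id, name, supplier — actual (branded) products
    * ``vmpps``/``ampps``: pack-level counterparts
    * ``forms``: form_id, name — medicinal forms (tablet, capsule, …)
    """

    ingredients: pd.DataFrame = field(default_factory=lambda: _empty("ingredients"))
    vmps: pd.DataFrame = field(default_factory=lambda: _empty("vmps"))
    vpi: pd.DataFrame = field(default_factory=lambda: _empty("vpi"))
    amps: pd.DataFrame = field(default_factory=lambda: _empty("amps"))
    vmpps: pd.DataFrame = field(default_factory=lambda: _empty("vmpps"))
    ampps: pd.DataFrame = field(default_factory=lambda: _empty("ampps"))
    forms: pd.DataFrame = field(default_factory=lambda: _empty("forms"))

    def form_name(self, form_id: str) -> str | None:
        hit = self.forms[self.forms["form_id"] == str(form_id)]
        if hit.empty:
            return None
        return str(hit.iloc[0]["name"])


@dataclass(frozen=True)
class GraphViolation:
    """One dangling link or invariant breach found by :func:`validate_graph`."""

    table: str
    node_id: str
    problem: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.table}[{self.node_id}]: {self.problem}"


def validate_graph(graph: ProductGraph) -> list[GraphViolation]:
    """Referential-integrity scan; empty list iff every link resolves.

    Violations are returned as data (sorted, order-independent of input row
    order), never raised — a broken row is a finding, not a crash.
    """
    violations: list[GraphViolation] = []
    ing_ids = set(graph.ingredients["ingredient_id"].astype(str))
    vmp_ids = set(graph.vmps["vmp_id"].astype(str))
    amp_ids = set(graph.amps["amp_id"].astype(str))
    vmpp_ids = set(graph.vmpps["vmpp_id"].astype(str))
    form_ids = set(graph.forms["form_id"].astype(str))

    def check(table: str, df: pd.DataFrame, id_col: str, fk_col: str, targets: set, target_name: str):
        for _, row in df.iterrows():
            fk = row.get(fk_col)
            if fk is None or (isinstance(fk, float) and pd.isna(fk)) or str(fk) == "":
                continue
            if str(fk) not in targets:
                violations.append(
                    GraphViolation(table, str(row[id_col]), f"{fk_col} {fk!r} not in {target_name}")
                )

    check("amps", graph.amps, "amp_id", "vmp_id", vmp_ids, "vmps")
    check("vmpps", graph.vmpps, "vmpp_id", "vmp_id", vmp_ids, "vmps")
    check("ampps", graph.ampps, "ampp_id", "amp_id", amp_ids, "amps")
    check("ampps", graph.ampps, "ampp_id", "vmpp_id", vmpp_ids, "vmpps")
    check("vpi", graph.vpi, "vmp_id", "vmp_id", vmp_ids, "vmps")
    check("vpi", graph.vpi, "vmp_id", "ingredient_id", ing_ids, "ingredients")
    if form_ids:
        check("vmps", graph.vmps, "vmp_id", "form_id", form_ids, "forms")
    for _, row in graph.vpi.iterrows():
        sv = row.get("strength_value")
        if sv is not None and not pd.isna(sv) and float(sv) <= 0:
            violations.append(
                GraphViolation("vpi", str(row["vmp_id"]), f"strength_value {sv} not positive")
            )
    violations.sort(key=lambda v: (v.table, v.node_id, v.problem))
    return violations


def reject_frame(rows: Iterable[dict]) -> pd.DataFrame:
    """Standard reject-log shape: source locator, reason, raw payload."""
    out = pd.DataFrame(list(rows), columns=["source", "row_number", "reason", "raw"])
    return out
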