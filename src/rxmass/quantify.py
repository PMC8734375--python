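"""Per-record ingredient-mass computation and roll-ups.

Second pipeline step: each prescribing record is joined to its BNF catalog
components and every (record × component) pair becomes one mass contribution

    mass_kg = quantity × strength_value × factor_to_kg(strength_unit)

for discrete forms, and for concentration products (strength per denominator,
e.g. 5 mg per 1 ml, quantity dispensed in ml)

    mass_kg = quantity × strength_value × factor_to_kg(unit) / denominator_value.

Mass uses the dispensed QUANTITY only, never the ITEMS count.  Multi-ingredient
codes contribute once per ingredient from the same record.  Ambiguous catalog
entries, unmapped codes, percent strengths and unit-kind mismatches are routed
to a reject log — contributions + rejects account for every pair.

Arithmetic is done in Decimal and rounded to float once per contribution, so
results are independent of evaluation order; aggregation sorts rows
deterministically before summing, making fixture comparisons exact.
"""

from __future__ import annotations

from decimal import Decimal

import pandas as pd

from .mapping import BnfCatalog
from .units import UnitTable, UnknownUnitError

CONTRIBUTION_COLUMNS = [
    "practice", "postcode", "api", "api_full", "period", "year", "form",
    "bnf_code", "quantity", "items", "mass_kg",
]

AGGREGATE_KEYS = {"api", "practice", "postcode", "region", "period", "year", "form"}


class QuantifyReject(ValueError):
    """A (record × component) pair that cannot be quantified; reason carried."""


def unit_to_kg(value: float, unit: str, units: UnitTable) -> float:
    """Convert a mass *value* in *unit* to kilograms.

    Linear by construction; unknown or non-mass units raise
    :class:`~rxmass.units.UnknownUnitError` naming the unit.
    """
    factor = units.factor_to_kg(unit)
    return float(Decimal(str(value)) * factor)


def _mass_kg(
    quantity: float,
    strength_value: float,
    strength_unit: str,
    denominator_value: float | None,
    units: UnitTable,
) -> float:
    m = Decimal(str(quantity)) * Decimal(str(strength_value)) * units.factor_to_kg(strength_unit)
    if denominator_value is not None:
        m /= Decimal(str(denominator_value))
    return float(m)


def record_mass(record, component: dict | pd.Series, units: UnitTable) -> dict:
    """One record × one catalog component → one mass contribution dict.

    *record* needs practice / bnf_code / quantity / items / period attributes
    or keys.  Raises :class:`QuantifyReject` for ambiguous components, percent
    or non-mass strength units, and concentration strengths whose denominator
    unit is a count while the quantity cannot be interpreted in it.
    """
    get = component.get if hasattr(component, "get") else component.__getitem__

    def rget(k):
        # subscript first: attribute access on a Series collides with methods
        # (e.g. .items); dataclass records only support attributes
        try:
            return record[k]
        except (KeyError, TypeError, IndexError):
            return getattr(record, k)

    if bool(get("ambiguous")):
        raise QuantifyReject("ambiguous catalog entry (conflicting strength variants)")
    unit = str(get("strength_unit"))
    kind = units.kind_of(unit)
    if kind == "percent":
        raise QuantifyReject("percent strength has no mass conversion without density")
    if kind != "mass":
        raise QuantifyReject(f"strength unit {unit!r} is not a mass unit")
    denom_v = get("denominator_value")
    if denom_v is not None and pd.isna(denom_v):
        denom_v = None
    denom_u = get("denominator_unit")
    if denom_u is not None and (pd.isna(denom_u) or str(denom_u) == ""):
        denom_u = None
    if denom_v is not None and denom_u is not None:
        if units.kind_of(str(denom_u)) == "mass":
            # mass-per-mass concentration: quantity is a mass in denominator units
            pass
        elif units.kind_of(str(denom_u)) not in ("volume", "count"):
            raise QuantifyReject(f"denominator unit {denom_u!r} has unknown kind")
    quantity = float(rget("quantity"))
    mass = _mass_kg(quantity, float(get("strength_value")), unit, denom_v, units)
    period = str(rget("period"))
    return {
        "practice": str(rget("practice")),
        "postcode": None,
        "api": str(get("api")),
        "api_full": str(get("api_full")),
        "period": period,
        "year": int(period[:4]),
        "form": get("form"),
        "bnf_code": str(rget("bnf_code")),
        "quantity": quantity,
        "items": int(rget("items")),
        "mass_kg": mass,
    }


def quantify(
    prescriptions: pd.DataFrame,
    catalog: BnfCatalog,
    units: UnitTable,
    practice_postcodes: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All records × their catalog components → (contributions, reject log).

    Records whose BNF code is absent from the catalog are rejected with reason
    ``unmapped``.  *practice_postcodes* (columns practice, postcode) attaches
    the dispensing practice's postcode to each contribution when supplied.
    """
    comp_by_code: dict[str, list[dict]] = {}
    for _, row in catalog.components.iterrows():
        comp_by_code.setdefault(str(row["bnf_code"]), []).append(row.to_dict())

    postcode_of: dict[str, str] = {}
    if practice_postcodes is not None:
        postcode_of = dict(
            zip(practice_postcodes["practice"].astype(str), practice_postcodes["postcode"])
        )

    contributions, rejects = [], []
    for _, rec in prescriptions.iterrows():
        code = str(rec["bnf_code"])
        comps = comp_by_code.get(code)
        if not comps:
            rejects.append(
                {
                    "practice": rec["practice"], "bnf_code": code,
                    "period": rec["period"], "reason": "unmapped",
                }
            )
            continue
        for comp in comps:
            try:
                contrib = record_mass(rec, comp, units)
            except (QuantifyReject, UnknownUnitError) as exc:
                rejects.append(
                    {
                        "practice": rec["practice"], "bnf_code": code,
                        "period": rec["period"], "reason": str(exc),
                    }
                )
                continue
            contrib["postcode"] = postcode_of.get(contrib["practice"])
            contributions.append(contrib)
    contrib_df = pd.DataFrame(contributions, columns=CONTRIBUTION_COLUMNS)
    reject_df = pd.DataFrame(rejects, columns=["practice", "bnf_code", "period", "reason"])
    return contrib_df, reject_df


def aggregate(contributions: pd.DataFrame, keys: list[str] | tuple[str, ...]) -> pd.DataFrame:
    """Group-sum mass_kg over *keys* ⊆ {api, practice, postcode, region,
    period, year, form}.

    Rows are sorted deterministically before summing so the result is
    invariant under input permutation, bit for bit.  Sums over a finer
    partition always reconcile with the coarser total (conservation).
    """
    keys = list(keys)
    bad = [k for k in keys if k not in AGGREGATE_KEYS]
    if bad:
        raise KeyError(f"unsupported aggregation keys {bad}; allowed: {sorted(AGGREGATE_KEYS)}")
    df = contributions.copy()
    if "year" in keys and "year" not in df.columns:
        df["year"] = df["period"].astype(str).str[:4].astype(int)
    missing = [k for k in keys if k not in df.columns]
    if missing:
        raise KeyError(f"contribution table lacks columns {missing}")
    df = df.sort_values(keys + ["mass_kg"], kind="stable")
    out = df.groupby(keys, dropna=False, sort=True)["mass_kg"].sum().reset_index()
    return out


def summarize_series(monthly_kg) -> dict:
    """Mean and sample (n−1) standard deviation of a monthly kg series."""
    s = pd.Series(list(monthly_kg), dtype=float)
    return {
        "mean_kg_per_month": float(s.mean()),
        "sd_kg_per_month": float(s.std(ddof=1)) if len(s) > 1 else 0.0,
        "n_months": int(len(s)),
    }


def write_per_practice(contributions: pd.DataFrame, out_dir) -> list:
    """One CSV per practice, named by the practice code."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for practice, grp in contributions.groupby("practice", sort=True):
        p = out_dir / f"{practice}.csv"
        grp.sort_values(["period", "api", "bnf_code"], kind="stable").to_csv(p, index=False)
        written.append(p)
    return written
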