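"""Resolve SNOMED product codes through the hierarchy and build the BNF catalog.

This is the first of the pipeline's two steps: every (BNF code, SNOMED code)
pair from the mapping file is chased through the product hierarchy — actual
product first, then virtual product, then the pack levels — down to the
virtual product's ingredient-strength rows.  Each ingredient becomes one
catalog component carrying the active-ingredient name, strength with unit,
optional concentration denominator, and medicinal form.

Multi-ingredient presentations (e.g. a co-amoxiclav-style 500 mg/125 mg
tablet) yield one component per ingredient under the same BNF code.  A BNF
code whose SNOMED codes disagree on (ingredient, unit-normalised strength)
keeps every variant but is flagged ambiguous; downstream quantification
refuses flagged codes rather than average them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import Decimal

import pandas as pd

from .core import ProductGraph
from .units import UnitTable, default_unit_table

#: Resolution precedence: product levels before pack levels.
RESOLUTION_LEVELS = ("AMP", "VMP", "VMPP", "AMPP")

CATALOG_COLUMNS = [
    "bnf_code", "api", "api_full", "strength_value", "strength_unit",
    "denominator_value", "denominator_unit", "form", "provenance", "ambiguous",
]


@dataclass(frozen=True)
class Resolution:
    """Where in the hierarchy a SNOMED code matched, and the VMP it leads to."""

    level: str  # one of RESOLUTION_LEVELS
    vmp_id: str
    amp_id: str | None = None
    pack_id: str | None = None


def resolve_snomed(code: str, graph: ProductGraph) -> Resolution | None:
    """Match *code* against AMP, then VMP, then VMPP, then AMPP identifiers.

    Pack-level hits are traversed up to their VMP so ingredient strengths can
    be reached.  Returns None when the code is absent from all four id
    spaces — unresolved is a value, never an exception.
    """
    code = str(code).strip()
    amp = graph.amps[graph.amps["amp_id"].astype(str) == code]
    if not amp.empty:
        return Resolution("AMP", str(amp.iloc[0]["vmp_id"]), amp_id=code)
    if (graph.vmps["vmp_id"].astype(str) == code).any():
        return Resolution("VMP", code)
    vmpp = graph.vmpps[graph.vmpps["vmpp_id"].astype(str) == code]
    if not vmpp.empty:
        return Resolution("VMPP", str(vmpp.iloc[0]["vmp_id"]), pack_id=code)
    ampp = graph.ampps[graph.ampps["ampp_id"].astype(str) == code]
    if not ampp.empty:
        amp_id = str(ampp.iloc[0]["amp_id"])
        parent = graph.amps[graph.amps["amp_id"].astype(str) == amp_id]
        if not parent.empty:
            return Resolution("AMPP", str(parent.iloc[0]["vmp_id"]), amp_id=amp_id, pack_id=code)
        # fall back through the pack's VMPP side
        vmpp_id = str(ampp.iloc[0]["vmpp_id"])
        pk = graph.vmpps[graph.vmpps["vmpp_id"].astype(str) == vmpp_id]
        if not pk.empty:
            return Resolution("AMPP", str(pk.iloc[0]["vmp_id"]), pack_id=code)
    return None


_PAREN_RE = re.compile(r"\s*\([^)]*\)")


def api_grouping_key(name: str) -> str:
    """Grouping stem of an ingredient name: the unparenthesised part.

    Salt qualifiers like ``"Amoxicillin (as amoxicillin trihydrate)"`` keep
    their display form but group under ``"Amoxicillin"``.  Matching is
    case-insensitive; the first-seen casing is kept for display.
    """
    return _PAREN_RE.sub("", str(name)).strip()


def _components_for_vmp(
    vmp_id: str, graph: ProductGraph
) -> list[dict]:
    rows = graph.vpi[graph.vpi["vmp_id"].astype(str) == str(vmp_id)]
    vmp = graph.vmps[graph.vmps["vmp_id"].astype(str) == str(vmp_id)]
    form = None
    if not vmp.empty:
        form_id = vmp.iloc[0].get("form_id")
        if form_id is not None and str(form_id) != "" and not pd.isna(form_id):
            form = graph.form_name(str(form_id))
    out = []
    for _, r in rows.iterrows():
        ing = graph.ingredients[
            graph.ingredients["ingredient_id"].astype(str) == str(r["ingredient_id"])
        ]
        name = str(ing.iloc[0]["name"]) if not ing.empty else str(r["ingredient_id"])
        denom_v = r.get("denominator_value")
        denom_u = r.get("denominator_unit")
        out.append(
            {
                "api": api_grouping_key(name),
                "api_full": name,
                "strength_value": float(r["strength_value"]),
                "strength_unit": str(r["strength_unit"]).strip(),
                "denominator_value": (
                    float(denom_v) if denom_v is not None and not pd.isna(denom_v) else None
                ),
                "denominator_unit": (
                    str(denom_u).strip()
                    if denom_u is not None and not pd.isna(denom_u) and str(denom_u) != ""
                    else None
                ),
                "form": form,
            }
        )
    return out


def _component_signature(comp: dict, units: UnitTable) -> tuple:
    """Exact comparison key after unit normalisation (Decimal, no epsilon)."""
    unit = comp["strength_unit"]
    if units.is_mass(unit):
        strength = Decimal(str(comp["strength_value"])) * units.factor_to_kg(unit)
        unit_key = "kg"
    else:
        strength = Decimal(str(comp["strength_value"]))
        unit_key = units.canon(unit)
    denom = (
        (Decimal(str(comp["denominator_value"])), units.canon(comp["denominator_unit"]))
        if comp["denominator_value"] is not None
        else None
    )
    return (comp["api"].lower(), strength, unit_key, denom, comp["form"])


@dataclass
class BnfCatalog:
    """Resolved map BNF code → ingredient components with strength and form."""

    components: pd.DataFrame  # CATALOG_COLUMNS

    def for_code(self, bnf_code: str) -> pd.DataFrame:
        return self.components[self.components["bnf_code"] == bnf_code]

    @property
    def codes(self) -> set[str]:
        return set(self.components["bnf_code"])

    def to_csv(self, path) -> None:
        self.components.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BnfCatalog":
        df = pd.read_csv(
            path,
            dtype={"bnf_code": str, "strength_unit": str, "form": str},
            keep_default_na=False,
            na_values=[""],
            float_precision="round_trip",
        )
        df["ambiguous"] = df["ambiguous"].astype(bool)
        return cls(components=df.reindex(columns=CATALOG_COLUMNS))


def build_bnf_catalog(
    map_rows: pd.DataFrame,
    graph: ProductGraph,
    units: UnitTable | None = None,
) -> tuple[BnfCatalog, pd.DataFrame]:
    """Build the catalog from mapping rows → (catalog, unresolved report).

    For each (bnf_code, snomed_code) pair the hierarchy yields the VMP's
    ingredient-strength rows; identical component sets across a BNF code's
    many SNOMED codes are deduplicated; disagreeing sets are all kept and
    flagged ambiguous.  Output is independent of input row order.
    """
    units = units or default_unit_table()
    unresolved = []
    per_code: dict[str, dict] = {}
    rows = map_rows.sort_values(["bnf_code", "snomed_code"], kind="stable")
    for _, mrow in rows.iterrows():
        bnf, sno = str(mrow["bnf_code"]), str(mrow["snomed_code"])
        res = resolve_snomed(sno, graph)
        if res is None:
            unresolved.append(
                {"bnf_code": bnf, "snomed_code": sno, "reason": "no hierarchy match"}
            )
            continue
        comps = _components_for_vmp(res.vmp_id, graph)
        if not comps:
            unresolved.append(
                {"bnf_code": bnf, "snomed_code": sno, "reason": f"vmp {res.vmp_id} has no ingredients"}
            )
            continue
        sig = tuple(sorted(_component_signature(c, units) for c in comps))
        entry = per_code.setdefault(bnf, {"variants": {}})
        variant = entry["variants"].setdefault(sig, {"components": comps, "provenance": res.level})
        # keep the highest-precedence provenance seen for this variant
        if RESOLUTION_LEVELS.index(res.level) < RESOLUTION_LEVELS.index(variant["provenance"]):
            variant["provenance"] = res.level

    out_rows = []
    for bnf in sorted(per_code):
        variants = per_code[bnf]["variants"]
        ambiguous = len(variants) > 1
        for sig in sorted(variants, key=repr):
            v = variants[sig]
            for comp in sorted(v["components"], key=lambda c: (c["api"].lower(), c["strength_value"])):
                out_rows.append(
                    {
                        "bnf_code": bnf,
                        **comp,
                        "provenance": v["provenance"],
                        "ambiguous": ambiguous,
                    }
                )
    catalog = BnfCatalog(pd.DataFrame(out_rows, columns=CATALOG_COLUMNS))
    return catalog, pd.DataFrame(unresolved, columns=["bnf_code", "snomed_code", "reason"])


# --------------------------------------------------------------------------
# Product-description parsing
# --------------------------------------------------------------------------

_STRENGTH_RE = re.compile(
    r"(\d+(?:\.\d+)?)\s*(kg|g|mg|microgram|micrograms|mcg|ug|µg|ng)\b",
    re.IGNORECASE,
)


@dataclass(frozen=True)
class ParsedDescription:
    stem: str
    form_token: str | None
    strength_value: float | None
    strength_unit: str | None


def parse_product_description(text: str) -> ParsedDescription:
    """Extract stem, underscore-delimited form token and trailing strength.

    ``"Phenergan_Tab 25 mg"`` → stem ``Phenergan``, form token ``Tab``,
    strength 25 mg.  This is validation/display metadata only: where the
    hierarchy supplies a strength, the parsed one never overrides it.
    """
    text = str(text).strip()
    stem, form_token = text, None
    if "_" in text:
        stem, _, tail = text.partition("_")
        stem = stem.strip()
        tail = tail.strip()
        form_token = tail.split()[0] if tail else None
    matches = _STRENGTH_RE.findall(text)
    if matches:
        value_s, unit = matches[-1]
        return ParsedDescription(stem, form_token, float(value_s), unit.lower())
    return ParsedDescription(stem, form_token, None, None)


# --------------------------------------------------------------------------
# Exclusions
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ExclusionRule:
    """Case-insensitive substring (optionally word-anchored) over form + name.

    Plain substrings rather than regex, for auditability.
    """

    name: str
    pattern: str
    whole_word: bool = False

    def matches(self, form: str | None, product_name: str | None) -> bool:
        hay = f"{form or ''} {product_name or ''}".lower()
        pat = self.pattern.lower()
        if self.whole_word:
            return re.search(rf"(?<![a-z]){re.escape(pat)}(?![a-z])", hay) is not None
        return pat in hay


#: Default rules: device/appliance products and cosmetic-category forms whose
#: dispensed quantity has no defensible ingredient-mass interpretation.
DEFAULT_EXCLUSION_RULES = [
    ExclusionRule("medical device", "device"),
    ExclusionRule("appliance", "appliance"),
    ExclusionRule("bath additive", "bath additive"),
    ExclusionRule("wash", "wash"),
    ExclusionRule("foam", "foam", whole_word=True),
    ExclusionRule("shampoo", "shampoo"),
    ExclusionRule("spray", "spray"),
    ExclusionRule("multivitamin", "multivitamin"),
]


def apply_exclusions(
    catalog: BnfCatalog,
    rules: list[ExclusionRule] | None = None,
    descriptions: dict[str, str] | None = None,
) -> tuple[BnfCatalog, pd.DataFrame]:
    """Partition the catalog into (kept, excluded report).

    Every entry lands in exactly one side; the report names the first matching
    rule.  *descriptions* optionally maps bnf_code → product description so
    name-based rules (e.g. multivitamin) can fire even when the form is
    innocuous.
    """
    rules = DEFAULT_EXCLUSION_RULES if rules is None else rules
    descriptions = descriptions or {}
    df = catalog.components
    keep_mask = []
    excluded = []
    for _, row in df.iterrows():
        name = descriptions.get(row["bnf_code"], row.get("api_full"))
        hit = next((r for r in rules if r.matches(row.get("form"), name)), None)
        keep_mask.append(hit is None)
        if hit is not None:
            excluded.append(
                {"bnf_code": row["bnf_code"], "api": row["api"], "form": row.get("form"), "rule": hit.name}
            )
    kept = BnfCatalog(df[pd.Series(keep_mask, index=df.index)].reset_index(drop=True))
    return kept, pd.DataFrame(excluded, columns=["bnf_code", "api", "form", "rule"])
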