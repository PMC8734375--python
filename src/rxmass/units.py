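"""Unit-of-measure table: mass units with multiplication factors to kg.

Strengths in the product hierarchy come in mass units (mg, microgram, ng …)
and the dispensed quantity in formulation-dependent units.  Mass units carry
an exact multiplication factor to kilograms; volume and count units carry a
kind tag only — they can scale a concentration product's denominator but
never convert to mass on their own.

Factors are held as :class:`decimal.Decimal` so unit-normalised strength
comparisons (e.g. 500 mg vs 0.5 g) are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal


class UnknownUnitError(KeyError):
    def __init__(self, unit: str):
        super().__init__(unit)
        self.unit = unit

    def __str__(self) -> str:
        return f"unknown or non-mass unit: {self.unit!r}"


@dataclass
class UnitTable:
    """Mass factors to kg plus kind tags for non-mass quantity units."""

    mass_factors: dict[str, Decimal] = field(default_factory=dict)
    kinds: dict[str, str] = field(default_factory=dict)  # unit -> volume|count|percent

    def canon(self, unit: str) -> str:
        return resolve_alias(unit)

    def add_mass(self, unit: str, factor_to_kg: Decimal | str | float) -> None:
        f = Decimal(str(factor_to_kg))
        if f <= 0:
            raise ValueError(f"factor for {unit!r} must be positive, got {f}")
        self.mass_factors[self.canon(unit)] = f

    def add_kind(self, unit: str, kind: str) -> None:
        if kind not in ("volume", "count", "percent"):
            raise ValueError(f"unknown unit kind {kind!r}")
        self.kinds[self.canon(unit)] = kind

    def is_mass(self, unit: str) -> bool:
        return self.canon(unit) in self.mass_factors

    def kind_of(self, unit: str) -> str:
        u = self.canon(unit)
        if u in self.mass_factors:
            return "mass"
        return self.kinds.get(u, "unknown")

    def factor_to_kg(self, unit: str) -> Decimal:
        u = self.canon(unit)
        try:
            return self.mass_factors[u]
        except KeyError:
            raise UnknownUnitError(unit) from None


#: Synonyms folded onto one canonical symbol at lookup time.
_ALIASES = {
    "µg": "microgram",
    "ug": "microgram",
    "mcg": "microgram",
    "micrograms": "microgram",
    "nanogram": "ng",
    "milligram": "mg",
    "gram": "g",
    "litre": "l",
    "millilitre": "ml",
}


def default_unit_table() -> UnitTable:
    """The shipped factor table: SI mass ladder plus common quantity kinds."""
    t = UnitTable()
    for unit, factor in [
        ("kg", "1"),
        ("g", "1e-3"),
        ("mg", "1e-6"),
        ("microgram", "1e-9"),
        ("ng", "1e-12"),
    ]:
        t.add_mass(unit, factor)
    for unit, kind in [
        ("ml", "volume"),
        ("l", "volume"),
        ("unit", "count"),
        ("tablet", "count"),
        ("capsule", "count"),
        ("dose", "count"),
        ("%", "percent"),
    ]:
        t.add_kind(unit, kind)
    return t


def resolve_alias(unit: str) -> str:
    u = str(unit).strip().lower()
    return _ALIASES.get(u, u)
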