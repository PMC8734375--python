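"""Synthetic fixture bundles with a ground-truth ledger.

Generates every input dialect the pipeline reads — monthly prescribing files,
BNF↔SNOMED map, dm+d-style hierarchy tables, practice address file, postcode
lookup, region boundary polygons and the unit-factor table — from a seeded
configuration, together with a ledger of the exact per-contribution masses,
aggregate totals, expected reject counts and region membership the pipeline
must reproduce.

The bundle tests correctness, not realism: strengths are drawn from a set of
exactly representable milligram values and quantities are integers, so every
ledger comparison is exact.  Unmapped and excluded-category presentations are
planted deterministically (evenly spaced assignment, not sampling), so the
planted fractions are realised exactly at any size.  The same seed always
produces a byte-identical bundle.
"""

from __future__ import annotations

import csv
import json
import random
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path

import pandas as pd

#: Strength values (mg) that survive float round-trips exactly.
EXACT_STRENGTHS_MG = [1, 2, 5, 7.5, 10, 25, 125, 250, 500]

_EXCLUDED_FORMS = ["bath additive", "shampoo", "spray"]
_QUANTITY_CHOICES = [7, 14, 21, 28, 30, 56, 60, 84, 90, 100]


@dataclass(frozen=True)
class ApiSpec:
    """One product family: ingredient components and the forms/strengths sold.

    ``components`` holds (full ingredient name, strength in mg) pairs; a
    multi-ingredient product (e.g. a 500 mg/125 mg combination tablet) lists
    one pair per ingredient and produces one presentation.
    """

    name: str
    form: str
    strengths_mg: tuple = ()  # one presentation per strength (single-ingredient)
    components: tuple = ()  # ((full_name, mg), ...) fixed combination product

    def presentations(self) -> list[tuple]:
        """[(components tuple, label), ...] for this spec."""
        if self.components:
            return [(tuple(self.components), self.name)]
        return [
            (((self.name, s),), self.name)
            for s in self.strengths_mg
        ]


DEFAULT_API_SPECS = (
    ApiSpec("Amoxicillin (as amoxicillin trihydrate)", "capsule", strengths_mg=(250, 500)),
    ApiSpec("Clarithromycin", "tablet", strengths_mg=(250, 500)),
    ApiSpec("Diazepam", "tablet", strengths_mg=(2, 5, 10)),
    ApiSpec("Zopiclone", "tablet", strengths_mg=(7.5,)),
    ApiSpec("Promethazine hydrochloride", "tablet", strengths_mg=(25,)),
    ApiSpec("Aripiprazole", "tablet", strengths_mg=(5, 10)),
    ApiSpec("Sulfasalazine", "tablet", strengths_mg=(500,)),
    ApiSpec("Sertraline", "tablet", strengths_mg=(25,)),
    ApiSpec(
        "Co-amoxiclav",
        "tablet",
        components=(
            ("Amoxicillin (as amoxicillin trihydrate)", 500),
            ("Clavulanic acid (as potassium clavulanate)", 125),
        ),
    ),
    ApiSpec("Ibuprofen", "tablet", strengths_mg=(250,)),
)


@dataclass
class FixtureConfig:
    """Study conditions for one fixture bundle."""

    seed: int = 1
    n_practices: int = 20
    n_months: int = 12
    start_year: int = 2018
    rows_per_practice_month: int = 42
    api_specs: tuple = DEFAULT_API_SPECS
    #: (name, lon_min, lat_min, lon_max, lat_max)
    region_rects: tuple = (("SYNREGION", -2.6, 51.2, -2.2, 51.5),)
    unmapped_fraction: float = 0.1
    excluded_fraction: float = 0.1

    def validate(self) -> None:
        if not self.api_specs:
            raise ValueError("config needs at least one API spec")
        if not 1 <= self.n_months <= 48:
            raise ValueError("n_months must be in 1..48")
        for frac in (self.unmapped_fraction, self.excluded_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_practices < 1:
            raise ValueError("need at least one practice")
        if not self.region_rects:
            raise ValueError("need at least one region rectangle")


@dataclass
class FixtureBundle:
    """Paths of a generated bundle plus its ground-truth ledger."""

    root: Path
    config: FixtureConfig

    @property
    def pdpi_dir(self) -> Path:
        return self.root / "pdpi"

    @property
    def snomed_map(self) -> Path:
        return self.root / "snomed_map.csv"

    @property
    def dmd_dir(self) -> Path:
        return self.root / "dmd"

    @property
    def addr(self) -> Path:
        return self.root / "addr.csv"

    @property
    def nspl(self) -> Path:
        return self.root / "nspl.csv"

    @property
    def boundary(self) -> Path:
        return self.root / "boundary.geojson"

    @property
    def units(self) -> Path:
        return self.root / "units.csv"

    @property
    def ledger_dir(self) -> Path:
        return self.root / "ledger"

    def ledger(self) -> dict:
        with open(self.ledger_dir / "ledger.json", encoding="utf-8") as fh:
            return json.load(fh)

    def ledger_contributions(self) -> pd.DataFrame:
        return pd.read_csv(
            self.ledger_dir / "contributions.csv",
            dtype={"practice": str, "postcode": str, "period": str, "bnf_code": str},
            float_precision="round_trip",
        )

    def ledger_aggregate(self, name: str) -> pd.DataFrame:
        return pd.read_csv(
            self.ledger_dir / f"agg_{name}.csv",
            dtype={"period": str, "practice": str, "postcode": str},
            float_precision="round_trip",
        )


def _periods(start_year: int, n_months: int) -> list[str]:
    out = []
    y, m = start_year, 1
    for _ in range(n_months):
        out.append(f"{y}{m:02d}")
        m += 1
        if m > 12:
            m, y = 1, y + 1
    return out


def _evenly_spaced(n: int, k: int) -> list[int]:
    """k distinct indices spread evenly over range(n); deterministic planting."""
    if k <= 0:
        return []
    return sorted({(j * n) // k for j in range(k)})


def _planted_count(fraction: float, n: int) -> int:
    import math

    return min(n, int(math.floor(fraction * n + 0.5)))


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def _write_csv(path: Path, header: list[str], rows: list[list]) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)


def _mass_kg(quantity: int, strength_mg: float) -> float:
    # same round-once Decimal semantics as the quantification step
    return float(Decimal(str(quantity)) * Decimal(str(strength_mg)) * Decimal("1e-6"))


def _agg(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    d = df.sort_values(keys + ["mass_kg"], kind="stable")
    return d.groupby(keys, dropna=False, sort=True)["mass_kg"].sum().reset_index()


def generate_fixture(config: FixtureConfig, out_dir: str | Path) -> FixtureBundle:
    """Write a complete input bundle plus ground-truth ledger under *out_dir*."""
    config.validate()
    rng = random.Random(config.seed)
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    bundle = FixtureBundle(root=root, config=config)

    # ---- presentations -------------------------------------------------
    presentations = []  # dicts: bnf_code, components, form, label, excluded, unmapped
    idx = 0
    for spec in config.api_specs:
        for components, label in spec.presentations():
            presentations.append(
                {
                    "index": idx,
                    "bnf_code": f"{idx:07d}AAAAAAAA",
                    "components": components,
                    "form": spec.form,
                    "label": label,
                    "unmapped": False,
                    "excluded": False,
                }
            )
            idx += 1
    n_pres = len(presentations)
    n_unmapped = _planted_count(config.unmapped_fraction, n_pres)
    for i in _evenly_spaced(n_pres, n_unmapped):
        presentations[i]["unmapped"] = True
    mapped_idx = [p["index"] for p in presentations if not p["unmapped"]]
    n_excluded = _planted_count(config.excluded_fraction, n_pres)
    n_excluded = min(n_excluded, len(mapped_idx))
    for j, pos in enumerate(_evenly_spaced(len(mapped_idx), n_excluded)):
        p = presentations[mapped_idx[pos]]
        p["excluded"] = True
        p["form"] = _EXCLUDED_FORMS[j % len(_EXCLUDED_FORMS)]

    # ---- dm+d tables ---------------------------------------------------
    ingredient_ids: dict[str, str] = {}
    form_ids: dict[str, str] = {}
    vmp_rows, vpi_rows, amp_rows, vmpp_rows, ampp_rows = [], [], [], [], []
    snomed_rows = []
    for p in presentations:
        i = p["index"]
        for name, _mg in p["components"]:
            ingredient_ids.setdefault(name, str(100000 + len(ingredient_ids)))
        form_ids.setdefault(p["form"], str(900 + len(form_ids)))
        vmp_id = str(200000 + i)
        strength_txt = "/".join(_fmt(mg) for _, mg in p["components"])
        vmp_name = f"{p['label']} {strength_txt}mg {p['form']}"
        vmp_rows.append([vmp_id, vmp_name, form_ids[p["form"]]])
        for name, mg in p["components"]:
            vpi_rows.append([vmp_id, ingredient_ids[name], _fmt(mg), "mg", "", ""])
        amp_ids = [str(300000 + 2 * i), str(300000 + 2 * i + 1)]
        for j, amp_id in enumerate(amp_ids):
            amp_rows.append([amp_id, vmp_id, f"{vmp_name} (brand {j + 1})", ["Synthex", "Pharmaco"][j]])
        vmpp_ids = [str(400000 + 2 * i), str(400000 + 2 * i + 1)]
        for j, vmpp_id in enumerate(vmpp_ids):
            vmpp_rows.append([vmpp_id, vmp_id, str([28, 100][j]), p["form"]])
        ampp_ids = [str(500000 + 2 * i), str(500000 + 2 * i + 1)]
        for j, ampp_id in enumerate(ampp_ids):
            ampp_rows.append([ampp_id, amp_ids[j], vmpp_ids[0]])
        if not p["unmapped"]:
            level = i % 4  # rotate the hierarchy level the map points at
            ids = [amp_ids, [vmp_id], vmpp_ids, ampp_ids][level]
            form_token = {"tablet": "Tab", "capsule": "Cap"}.get(p["form"], p["form"].title())
            desc = f"{p['label']}_{form_token} {strength_txt} mg"
            for sid in ids:
                snomed_rows.append([p["bnf_code"], sid, desc])

    dmd = bundle.dmd_dir
    _write_csv(dmd / "ingredient.csv", ["ingredient_id", "name"],
               sorted([[v, k] for k, v in ingredient_ids.items()]))
    _write_csv(dmd / "form.csv", ["form_id", "name"], sorted([[v, k] for k, v in form_ids.items()]))
    _write_csv(dmd / "vmp.csv", ["vmp_id", "name", "form_id"], vmp_rows)
    _write_csv(
        dmd / "vpi.csv",
        ["vmp_id", "ingredient_id", "strength_value", "strength_unit", "denominator_value", "denominator_unit"],
        vpi_rows,
    )
    _write_csv(dmd / "amp.csv", ["amp_id", "vmp_id", "name", "supplier"], amp_rows)
    _write_csv(dmd / "vmpp.csv", ["vmpp_id", "vmp_id", "pack_size", "pack_unit"], vmpp_rows)
    _write_csv(dmd / "ampp.csv", ["ampp_id", "amp_id", "vmpp_id"], ampp_rows)
    _write_csv(bundle.snomed_map, ["bnf_code", "snomed_code", "description"], snomed_rows)

    # ---- practices, postcodes, geography -------------------------------
    name0, lon0, lat0, lon1, lat1 = config.region_rects[0]
    practices = []
    cols = max(1, int(config.n_practices ** 0.5))
    for i in range(config.n_practices):
        code = f"P{81000 + i}"
        postcode = f"BA{1 + i // 10} {i % 10}AA"
        fx = (i % cols + 0.5) / cols
        fy = (i // cols + 0.5) / max(1, (config.n_practices + cols - 1) // cols)
        lon = round(lon0 + (lon1 - lon0) * (0.1 + 0.8 * fx), 6)
        lat = round(lat0 + (lat1 - lat0) * (0.1 + 0.8 * fy), 6)
        practices.append({"code": code, "postcode": postcode, "lon": lon, "lat": lat})

    periods = _periods(config.start_year, config.n_months)
    _write_csv(
        bundle.addr,
        ["PERIOD", "PRACTICE", "NAME", "ADDRESS", "POSTCODE"],
        [[periods[0], p["code"], f"Synthetic Practice {i}", "1 High Street", p["postcode"]]
         for i, p in enumerate(practices)],
    )
    _write_csv(
        bundle.nspl,
        ["pcds", "long", "lat"],
        [[p["postcode"], repr(p["lon"]), repr(p["lat"])] for p in practices],
    )
    features = []
    for name, a, b, c, d in config.region_rects:
        ring = [[a, b], [c, b], [c, d], [a, d], [a, b]]
        features.append(
            {
                "type": "Feature",
                "properties": {"name": name},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    with open(bundle.boundary, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1, sort_keys=True)

    _write_csv(
        bundle.units,
        ["unit", "factor_to_kg", "kind"],
        [
            ["kg", "1", ""],
            ["g", "1e-3", ""],
            ["mg", "1e-6", ""],
            ["microgram", "1e-9", ""],
            ["ng", "1e-12", ""],
            ["ml", "", "volume"],
            ["l", "", "volume"],
            ["tablet", "", "count"],
            ["capsule", "", "count"],
            ["unit", "", "count"],
            ["%", "", "percent"],
        ],
    )

    # ---- prescribing rows + ground-truth contributions -----------------
    membership = {name0: sorted(p["code"] for p in practices)}
    contributions = []
    reject_rows = {"unmapped": 0, "excluded": 0}
    per_file_counts = {}
    form_token = {"tablet": "Tab", "capsule": "Cap"}
    pdpi_dir = bundle.pdpi_dir
    pdpi_dir.mkdir(parents=True, exist_ok=True)
    for period in periods:
        rows = []
        for p in practices:
            for _ in range(config.rows_per_practice_month):
                pres = presentations[rng.randrange(n_pres)]
                quantity = rng.choice(_QUANTITY_CHOICES)
                items = rng.randint(1, 5)
                strength_txt = "/".join(_fmt(mg) for _, mg in pres["components"])
                tok = form_token.get(pres["form"], pres["form"].title())
                bnf_name = f"{pres['label']}_{tok} {strength_txt} mg"
                nic = Decimal(quantity) * Decimal("0.05")
                rows.append(
                    [
                        "Q44", "RTV", p["code"], pres["bnf_code"], bnf_name,
                        str(items), str(nic), str(nic * Decimal("0.93")),
                        str(quantity), period,
                    ]
                )
                if pres["unmapped"]:
                    reject_rows["unmapped"] += 1
                elif pres["excluded"]:
                    reject_rows["excluded"] += 1
                else:
                    for ing_name, mg in pres["components"]:
                        from .mapping import api_grouping_key

                        contributions.append(
                            {
                                "practice": p["code"],
                                "postcode": p["postcode"],
                                "api": api_grouping_key(ing_name),
                                "api_full": ing_name,
                                "period": period,
                                "year": int(period[:4]),
                                "form": pres["form"],
                                "bnf_code": pres["bnf_code"],
                                "quantity": quantity,
                                "items": items,
                                "mass_kg": _mass_kg(quantity, mg),
                            }
                        )
        fname = f"PDPI_{period}.csv"
        _write_csv(
            pdpi_dir / fname,
            ["SHA", "PCT", "PRACTICE", "BNF CODE", "BNF NAME", "ITEMS", "NIC", "ACT COST", "QUANTITY", "PERIOD"],
            rows,
        )
        per_file_counts[fname] = len(rows)

    # ---- ledger --------------------------------------------------------
    ledger_dir = bundle.ledger_dir
    ledger_dir.mkdir(parents=True, exist_ok=True)
    contrib_df = pd.DataFrame(
        contributions,
        columns=[
            "practice", "postcode", "api", "api_full", "period", "year",
            "form", "bnf_code", "quantity", "items", "mass_kg",
        ],
    )
    contrib_df.to_csv(ledger_dir / "contributions.csv", index=False)
    for name, keys in [
        ("api", ["api"]),
        ("api_period", ["api", "period"]),
        ("api_practice", ["api", "practice"]),
        ("api_postcode", ["api", "postcode"]),
        ("api_form", ["api", "form"]),
        ("api_year", ["api", "year"]),
    ]:
        _agg(contrib_df, keys).to_csv(ledger_dir / f"agg_{name}.csv", index=False)

    ledger = {
        "seed": config.seed,
        "n_presentations": n_pres,
        "unmapped_bnf_codes": sorted(p["bnf_code"] for p in presentations if p["unmapped"]),
        "excluded_bnf_codes": sorted(p["bnf_code"] for p in presentations if p["excluded"]),
        "expected_reject_rows": reject_rows,
        "per_file_rows": per_file_counts,
        "total_input_rows": sum(per_file_counts.values()),
        "n_contributions": len(contrib_df),
        "membership": membership,
        "node_counts": {
            "ingredients": len(ingredient_ids),
            "vmps": len(vmp_rows),
            "vpi": len(vpi_rows),
            "amps": len(amp_rows),
            "vmpps": len(vmpp_rows),
            "ampps": len(ampp_rows),
            "forms": len(form_ids),
        },
        "total_mass_kg": float(contrib_df["mass_kg"].sum()) if len(contrib_df) else 0.0,
    }
    with open(ledger_dir / "ledger.json", "w", encoding="utf-8") as fh:
        json.dump(ledger, fh, indent=1, sort_keys=True)
    return bundle


_CONTRIB_SORT = ["practice", "period", "bnf_code", "api", "quantity", "mass_kg"]


def verify_ledger(
    bundle: FixtureBundle,
    contributions: pd.DataFrame,
    rejects: pd.DataFrame | None = None,
    membership: dict | None = None,
) -> list[str]:
    """Compare pipeline outputs against the bundle's ground truth.

    Returns an empty list iff every per-contribution mass, every aggregate at
    every level, the reject count and the region membership match exactly.
    Each mismatch is reported as one human-readable line.
    """
    from .quantify import aggregate

    report: list[str] = []
    truth = bundle.ledger_contributions()
    cols = ["practice", "postcode", "api", "period", "form", "bnf_code", "quantity", "mass_kg"]
    numeric = {"quantity", "mass_kg"}
    t = truth[cols].sort_values(_CONTRIB_SORT, kind="stable").reset_index(drop=True)
    got = contributions[cols].sort_values(_CONTRIB_SORT, kind="stable").reset_index(drop=True)
    if len(t) != len(got):
        report.append(f"contribution count: expected {len(t)}, got {len(got)}")
    else:
        for col in cols:
            a = t[col].astype(float) if col in numeric else t[col].astype(str)
            b = got[col].astype(float) if col in numeric else got[col].astype(str)
            neq = (a != b)
            if neq.any():
                i = int(neq.idxmax())
                report.append(
                    f"contributions differ in column {col!r} at sorted row {i}: "
                    f"expected {t[col].iloc[i]!r}, got {got[col].iloc[i]!r} "
                    f"({int(neq.sum())} rows total)"
                )
    for name, keys in [
        ("api", ["api"]),
        ("api_period", ["api", "period"]),
        ("api_practice", ["api", "practice"]),
        ("api_postcode", ["api", "postcode"]),
        ("api_form", ["api", "form"]),
    ]:
        want = bundle.ledger_aggregate(name)
        have = aggregate(contributions, keys)
        w = want.sort_values(keys, kind="stable").reset_index(drop=True)
        h = have.sort_values(keys, kind="stable").reset_index(drop=True)
        if len(w) != len(h):
            report.append(f"aggregate {name}: expected {len(w)} groups, got {len(h)}")
            continue
        for i in range(len(w)):
            if any(str(w[k].iloc[i]) != str(h[k].iloc[i]) for k in keys):
                report.append(f"aggregate {name}: group keys differ at row {i}")
                break
            if float(w["mass_kg"].iloc[i]) != float(h["mass_kg"].iloc[i]):
                report.append(
                    f"aggregate {name} {tuple(w[k].iloc[i] for k in keys)}: "
                    f"expected {w['mass_kg'].iloc[i]!r} kg, got {h['mass_kg'].iloc[i]!r} kg"
                )
    ledger = bundle.ledger()
    if rejects is not None:
        expected = sum(ledger["expected_reject_rows"].values())
        if len(rejects) != expected:
            report.append(f"reject rows: expected {expected}, got {len(rejects)}")
    if membership is not None:
        for region, want_list in ledger["membership"].items():
            got_list = sorted(membership.get(region, []))
            if got_list != want_list:
                missing = set(want_list) - set(got_list)
                extra = set(got_list) - set(want_list)
                report.append(
                    f"membership {region}: missing {sorted(missing)}, unexpected {sorted(extra)}"
                )
    return report
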