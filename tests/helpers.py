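"""Independent oracles and toy-graph builders used by the test suite.

The oracles deliberately share no code with the implementation: the catalog
oracle walks every hierarchy path by exhaustive scan over plain tuples, and
the containment oracle is a winding-number algorithm (the implementation uses
even-odd ray casting).
"""

from decimal import Decimal

import pandas as pd

from rxmass.core import ProductGraph


# --------------------------------------------------------------------------
# Toy graphs
# --------------------------------------------------------------------------

def make_single_api_graph():
    """One VMP 'Drug A 500 mg capsules', 3 AMPs, 2 VMPPs, 2 AMPPs, 1 BNF code."""
    graph = ProductGraph(
        ingredients=pd.DataFrame([{"ingredient_id": "10", "name": "Drug A"}]),
        forms=pd.DataFrame([{"form_id": "900", "name": "capsule"}]),
        vmps=pd.DataFrame([{"vmp_id": "20", "name": "Drug A 500mg capsules", "form_id": "900"}]),
        vpi=pd.DataFrame([
            {"vmp_id": "20", "ingredient_id": "10", "strength_value": 500.0,
             "strength_unit": "mg", "denominator_value": None, "denominator_unit": None},
        ]),
        amps=pd.DataFrame([
            {"amp_id": a, "vmp_id": "20", "name": f"Drug A brand {a}", "supplier": "S"}
            for a in ("30", "31", "32")
        ]),
        vmpps=pd.DataFrame([
            {"vmpp_id": v, "vmp_id": "20", "pack_size": "28", "pack_unit": "capsule"}
            for v in ("40", "41")
        ]),
        ampps=pd.DataFrame([
            {"ampp_id": "50", "amp_id": "30", "vmpp_id": "40"},
            {"ampp_id": "51", "amp_id": "31", "vmpp_id": "41"},
        ]),
    )
    map_rows = pd.DataFrame(
        [{"bnf_code": "0500000A0AAAAAA", "snomed_code": s, "description": "Drug A_Cap 500 mg"}
         for s in ("30", "31", "32", "40", "41")]
    )
    return graph, map_rows


def make_two_api_graph():
    """A 500 mg / 125 mg combination tablet: two ingredients on one VMP."""
    graph = ProductGraph(
        ingredients=pd.DataFrame([
            {"ingredient_id": "11", "name": "Amoxicillin (as amoxicillin trihydrate)"},
            {"ingredient_id": "12", "name": "Clavulanic acid (as potassium clavulanate)"},
        ]),
        forms=pd.DataFrame([{"form_id": "901", "name": "tablet"}]),
        vmps=pd.DataFrame([
            {"vmp_id": "21", "name": "Co-amoxiclav 500mg/125mg tablets", "form_id": "901"},
        ]),
        vpi=pd.DataFrame([
            {"vmp_id": "21", "ingredient_id": "11", "strength_value": 500.0,
             "strength_unit": "mg", "denominator_value": None, "denominator_unit": None},
            {"vmp_id": "21", "ingredient_id": "12", "strength_value": 125.0,
             "strength_unit": "mg", "denominator_value": None, "denominator_unit": None},
        ]),
        amps=pd.DataFrame([
            {"amp_id": "33", "vmp_id": "21", "name": "Combi brand", "supplier": "S"},
        ]),
        vmpps=pd.DataFrame([
            {"vmpp_id": "42", "vmp_id": "21", "pack_size": "21", "pack_unit": "tablet"},
        ]),
        ampps=pd.DataFrame([{"ampp_id": "52", "amp_id": "33", "vmpp_id": "42"}]),
    )
    map_rows = pd.DataFrame(
        [{"bnf_code": "0501013K0AAAAAA", "snomed_code": s, "description": "Co-Amoxiclav_Tab 500mg/125mg"}
         for s in ("33", "42", "52")]
    )
    return graph, map_rows


# --------------------------------------------------------------------------
# Exhaustive-path catalog oracle
# --------------------------------------------------------------------------

def brute_force_catalog(map_rows, graph, units):
    """Catalog by exhaustive scan: {bnf: (frozenset of component tuples, ambiguous)}.

    Components are (api_stem_lower, strength_kg_decimal, form) — strengths
    normalised to kg with Decimal, matching the exactness contract.
    """
    ingredients = {str(r["ingredient_id"]): str(r["name"]) for _, r in graph.ingredients.iterrows()}
    forms = {str(r["form_id"]): str(r["name"]) for _, r in graph.forms.iterrows()}
    vmps = {str(r["vmp_id"]): str(r.get("form_id")) for _, r in graph.vmps.iterrows()}
    amps = {str(r["amp_id"]): str(r["vmp_id"]) for _, r in graph.amps.iterrows()}
    vmpps = {str(r["vmpp_id"]): str(r["vmp_id"]) for _, r in graph.vmpps.iterrows()}
    ampps = {str(r["ampp_id"]): (str(r["amp_id"]), str(r["vmpp_id"])) for _, r in graph.ampps.iterrows()}
    vpi = [
        (str(r["vmp_id"]), str(r["ingredient_id"]), Decimal(str(r["strength_value"])),
         str(r["strength_unit"]))
        for _, r in graph.vpi.iterrows()
    ]

    import re

    def stem(name):
        return re.sub(r"\s*\([^)]*\)", "", name).strip().lower()

    def components_of(vmp_id):
        out = set()
        for v, ing, strength, unit in vpi:
            if v == vmp_id:
                kg = strength * units.factor_to_kg(unit)
                form = forms.get(vmps.get(vmp_id), None)
                out.add((stem(ingredients[ing]), kg, form))
        return frozenset(out)

    def vmp_for(code):
        # precedence: product levels before pack levels
        if code in amps:
            return amps[code]
        if code in vmps:
            return code
        if code in vmpps:
            return vmpps[code]
        if code in ampps:
            amp_id, vmpp_id = ampps[code]
            if amp_id in amps:
                return amps[amp_id]
            if vmpp_id in vmpps:
                return vmpps[vmpp_id]
        return None

    per_code = {}
    for _, row in map_rows.iterrows():
        bnf, sno = str(row["bnf_code"]), str(row["snomed_code"])
        vmp_id = vmp_for(sno)
        if vmp_id is None:
            continue
        comps = components_of(vmp_id)
        if not comps:
            continue
        per_code.setdefault(bnf, set()).add(comps)
    return {
        bnf: (frozenset().union(*variants), len(variants) > 1)
        for bnf, variants in per_code.items()
    }


def catalog_as_sets(catalog, units):
    """Project a built catalog onto the oracle's comparison space."""
    out = {}
    for bnf, grp in catalog.components.groupby("bnf_code"):
        comps = frozenset(
            (str(r["api"]).lower(),
             Decimal(str(r["strength_value"])) * units.factor_to_kg(r["strength_unit"]),
             r["form"] if pd.notna(r["form"]) else None)
            for _, r in grp.iterrows()
        )
        out[str(bnf)] = (comps, bool(grp["ambiguous"].any()))
    return out


# --------------------------------------------------------------------------
# Winding-number containment oracle
# --------------------------------------------------------------------------

def winding_number_contains(lon, lat, boundary):
    """Nonzero-winding containment with explicit on-edge check (inside)."""

    def on_segment(px, py, ax, ay, bx, by):
        cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
        if abs(cross) > 1e-12:
            return False
        return (min(ax, bx) - 1e-12 <= px <= max(ax, bx) + 1e-12
                and min(ay, by) - 1e-12 <= py <= max(ay, by) + 1e-12)

    for poly in boundary.polygons:
        wn = 0
        for ring in poly:
            for (ax, ay), (bx, by) in zip(ring[:-1], ring[1:]):
                if on_segment(lon, lat, ax, ay, bx, by):
                    return True
                if ay <= lat:
                    if by > lat and (bx - ax) * (lat - ay) - (by - ay) * (lon - ax) > 0:
                        wn += 1
                elif by <= lat and (bx - ax) * (lat - ay) - (by - ay) * (lon - ax) < 0:
                    wn -= 1
        if wn != 0:
            return True
    return False


# --------------------------------------------------------------------------
# Full pipeline driver
# --------------------------------------------------------------------------

def run_pipeline(bundle):
    """Run every stage over a fixture bundle; returns a dict of outputs."""
    from rxmass.geo import geolocate_practices, practices_in_region, read_boundaries
    from rxmass.ingest import (
        combine_monthly,
        read_dmd,
        read_postcode_lookup,
        read_practices,
        read_snomed_map,
        read_unit_table,
    )
    from rxmass.mapping import apply_exclusions, build_bnf_catalog
    from rxmass.quantify import quantify

    records, record_rejects = combine_monthly(bundle.pdpi_dir)
    map_rows, map_rejects, n_dupes = read_snomed_map(bundle.snomed_map)
    graph, graph_rejects = read_dmd(bundle.dmd_dir)
    units, _ = read_unit_table(bundle.units)
    catalog, unresolved = build_bnf_catalog(map_rows, graph, units)
    descriptions = dict(zip(map_rows["bnf_code"], map_rows["description"]))
    kept, excluded = apply_exclusions(catalog, descriptions=descriptions)
    directory, conflicts = read_practices(bundle.addr)
    geo, unmatched = geolocate_practices(directory, read_postcode_lookup(bundle.nspl))
    boundary = read_boundaries(bundle.boundary)[0]
    members = practices_in_region(geo, boundary)
    contributions, rejects = quantify(
        records, kept, units, practice_postcodes=geo[["practice", "postcode"]]
    )
    return {
        "records": records,
        "record_rejects": record_rejects,
        "graph": graph,
        "map_rows": map_rows,
        "units": units,
        "catalog": catalog,
        "kept": kept,
        "excluded": excluded,
        "unresolved": unresolved,
        "geo": geo,
        "boundary": boundary,
        "members": members,
        "contributions": contributions,
        "rejects": rejects,
    }
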