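"""Resolve product codes through a toy hierarchy into a BNF catalog.

Builds a two-ingredient combination product (500 mg amoxicillin +
125 mg clavulanic acid per tablet), maps three product codes to its one BNF
code at three different hierarchy levels, and prints the resulting catalog:
one component per ingredient, deduplicated across the codes.
"""

import pandas as pd

from rxmass import ProductGraph, build_bnf_catalog, default_unit_table

graph = ProductGraph(
    ingredients=pd.DataFrame([
        {"ingredient_id": "11", "name": "Amoxicillin (as amoxicillin trihydrate)"},
        {"ingredient_id": "12", "name": "Clavulanic acid (as potassium clavulanate)"},
    ]),
    forms=pd.DataFrame([{"form_id": "901", "name": "tablet"}]),
    vmps=pd.DataFrame([{"vmp_id": "21", "name": "Co-amoxiclav 500mg/125mg tablets", "form_id": "901"}]),
    vpi=pd.DataFrame([
        {"vmp_id": "21", "ingredient_id": "11", "strength_value": 500.0, "strength_unit": "mg",
         "denominator_value": None, "denominator_unit": None},
        {"vmp_id": "21", "ingredient_id": "12", "strength_value": 125.0, "strength_unit": "mg",
         "denominator_value": None, "denominator_unit": None},
    ]),
    amps=pd.DataFrame([{"amp_id": "33", "vmp_id": "21", "name": "Brand X", "supplier": "S"}]),
    vmpps=pd.DataFrame([{"vmpp_id": "42", "vmp_id": "21", "pack_size": "21", "pack_unit": "tablet"}]),
    ampps=pd.DataFrame([{"ampp_id": "52", "amp_id": "33", "vmpp_id": "42"}]),
)
map_rows = pd.DataFrame(
    [{"bnf_code": "0501013K0AAAAAA", "snomed_code": s, "description": "Co-Amoxiclav_Tab"}
     for s in ("33", "42", "52")]  # an actual product, a pack, an actual pack
)

catalog, unresolved = build_bnf_catalog(map_rows, graph, default_unit_table())
print(catalog.components[["bnf_code", "api", "strength_value", "strength_unit", "form", "provenance"]])
print(f"unresolved pairs: {len(unresolved)}")

# Two components under one BNF code: any prescription of this code later
# contributes mass to BOTH ingredients (500 mg and 125 mg per tablet).
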