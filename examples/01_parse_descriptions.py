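"""Parse product descriptions from prescribing records.

The BNF NAME column carries the product stem, an underscore-delimited form
token and usually a trailing strength.  Parsed strengths are validation and
display metadata — the product hierarchy remains the authority on strength.
"""

from rxmass import parse_product_description

for text in [
    "Phenergan_Tab 25 mg",
    "Zopiclone_Tab 7.5 mg",
    "Diazepam_Tab 2 mg",
    "Clarithromycin_I/V Inf 500 mg Vl",
    "Sod Chlor_Irrig Soln",
]:
    p = parse_product_description(text)
    strength = f"{p.strength_value} {p.strength_unit}" if p.strength_value else "(no strength)"
    print(f"{text:35s} -> stem={p.stem!r:15s} form={p.form_token!r:10s} strength={strength}")

# Each line shows what the mass pipeline could fall back on if a product had
# no hierarchy entry: e.g. the first row is a 25 mg tablet presentation.
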