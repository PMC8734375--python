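"""Report tables: targeted ingredient lists and postcode-resolved views.

Builds a tiny contributions table by hand, then prints the targeted report
(annual + zero-filled monthly kg) and the non-targeted per-postcode view with
form shares.  In real use the contributions table comes from quantify().
"""

import pandas as pd

from rxmass import nontargeted_report, summarize_series, targeted_report

rows = [
    ("Clarithromycin", "P1", "BA1 7NP", "201801", "tablet", 0.30),
    ("Clarithromycin", "P2", "BA2 2BB", "201801", "tablet", 0.10),
    ("Clarithromycin", "P1", "BA1 7NP", "201806", "oral suspension", 0.05),
    ("Amoxicillin", "P1", "BA1 7NP", "201803", "capsule", 0.20),
]
contributions = pd.DataFrame(
    [{"api": a, "practice": p, "postcode": pc, "period": m, "year": int(m[:4]),
      "form": f, "mass_kg": kg} for a, p, pc, m, f, kg in rows]
)

tables = targeted_report(contributions, ["Clarithromycin", "Amoxicillin", "Sertraline"], None, 2018)
print("annual kg by ingredient (listed-but-absent ingredients appear as 0):")
print(tables["annual"].to_string(index=False))
print("\nmonthly kg (all 12 months, zero-filled):")
print(tables["monthly"][tables["monthly"]["api"] == "Clarithromycin"].to_string(index=False))

stats = summarize_series(
    tables["monthly"][tables["monthly"]["api"] == "Clarithromycin"]["mass_kg"]
)
print(f"\nClarithromycin: mean {stats['mean_kg_per_month']:.4f} kg/month, "
      f"sd {stats['sd_kg_per_month']:.4f} kg/month over {stats['n_months']} months")

nt = nontargeted_report(contributions, "Clarithromycin", None, period="201801")
print("\nJanuary kg by postcode:")
print(nt["per_postcode"].to_string(index=False))
print("\nform shares (% of total kg, sums to 100):")
print(nt["form_shares"].to_string(index=False))
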