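# Methods

## The quantity-to-mass model

A prescribing record reports, per practice and month, a BNF presentation
code and the dispensed `QUANTITY` in formulation-dependent units: tablets or
capsules for discrete solid forms, millilitres for liquids, grams for some
topicals. The model computes, for each record and each active ingredient of
the presentation,

```
mass_kg = quantity × strength_value × factor_to_kg(strength_unit)              (discrete)
mass_kg = quantity × strength_value × factor_to_kg(strength_unit) / denom      (concentration)
```

where the strength comes from the product hierarchy's ingredient-strength
relation (e.g. 25 mg per tablet, or 5 mg per 1 ml with denominator 5 ml) and
`factor_to_kg` comes from the unit-of-measure table. For concentration
products the quantity is interpreted in the denominator's unit (ml of a
5 mg/5 ml solution), which matches how liquid quantities are reported in the
extracts.

Assumptions and their consequences:

- **Quantity, not items.** Mass uses the dispensed quantity only; the item
  count is carried for reporting. The extracts do not state whether quantity
  is per-item or total; it is treated as the total dispensed units, the
  interpretation consistent with how the column is defined.
- **Stated strength, no salt correction.** Strengths are attributed as
  stated by the hierarchy, e.g. "Amoxicillin (as amoxicillin trihydrate)
  500 mg" contributes 500 mg to the amoxicillin stem. No salt-to-base
  molecular-weight correction is applied; totals are therefore "prescribed
  strength mass", which may overstate the free-base mass for salt forms.
  The unparenthesised ingredient stem is the grouping key, so salts group
  with their parent compound.
- **Percent strengths are rejected.** % w/v or % w/w strengths have no
  defensible mass conversion without a density assumption, so such
  components go to the reject log (an override table can be supplied).
- **Dispensing ≠ consumption ≠ emission.** The output is prescribed mass;
  pharmacokinetics, compliance and excretion fractions are downstream
  science outside this package.

## Hierarchy resolution

Each SNOMED product code from the mapping file is matched against AMP
identifiers first, then VMP, then VMPP, then AMPP (product levels before
pack levels; pack hits are traversed up to their VMP). The VMP's
ingredient-strength rows yield one catalog component per API. Components
identical across a BNF code's many SNOMED codes — identity is
`(ingredient stem, unit-normalised strength, denominator, form)` compared
exactly in decimal arithmetic, no epsilon — are deduplicated. A BNF code
whose SNOMED codes disagree keeps all variants flagged **ambiguous**, and
quantification refuses flagged codes to the reject log: silently averaging
conflicting strengths would corrupt kilogram totals in a way no downstream
check could catch.

Unresolvable codes are values, not errors: they land in an unresolved report
so the match rate is always observable.

### Exclusions

The default exclusion rules drop device/appliance products and
cosmetic-category presentations — bath additives, washes, foams, shampoos,
sprays, multivitamin products — whose dispensed quantity has no meaningful
single-ingredient mass interpretation. Rules are ordered, case-insensitive
plain substrings (optionally word-anchored) over the form name and product
description: auditable by reading, no regex surprises. The partition is
total: every catalog entry is either kept or listed in the excluded report
with the rule that fired.

## Numerical policy

Per-contribution masses are computed in `decimal.Decimal` and rounded to
binary float once, so a contribution's value is independent of evaluation
order. Aggregation sorts rows by the grouping keys plus mass before summing,
making group sums bit-reproducible under input permutation. Mass
conservation across roll-up levels (yearly = Σ monthly = Σ per-practice =
Σ per-postcode, per API) holds to ≤ 1e-9 relative error; on the synthetic
fixtures — whose strengths are drawn from exactly representable milligram
values and whose quantities are integers — recovery of the ledger is exact,
bit for bit. CSV interchange uses round-trip float parsing throughout.
Output kilograms keep full float precision; any rounding is presentation
only.

## Geography

Practices are geocoded by joining their normalised postcode (upper case,
single internal space) to an NSPL-style lookup; unmatched practices are kept
without coordinates and logged. Region membership uses even-odd ray casting
on planar WGS84 lon/lat. Two deliberate choices: points on a boundary edge
count as inside (closed polygons — a deterministic tie-break for practices
sitting on a region border), and no geodesic correction is applied, which at
the ~100 km scale of English commissioning regions is far below the
positional noise of postcode centroids. Boundary files in other coordinate
systems must be converted before input.

## The synthetic fixture generator

The generator emulates every input dialect — monthly prescribing files, the
BNF↔SNOMED map, the six dm+d-style hierarchy tables, the practice address
file, the postcode lookup, region boundary polygons and the unit table —
from a seeded configuration, and writes a ledger of the exact
per-contribution masses, aggregates at five levels, expected reject counts
and region membership.

Default study conditions: 20 practices × 12 months × 10 APIs at 42 rows per
practice-month (~10⁴ rows), with 10 % of presentations planted unmapped and
10 % in excluded categories. The APIs mirror common prescribing (an
antibiotic pair, benzodiazepine, hypnotic, antihistamine, antipsychotic,
aminosalicylate, SSRI, NSAID, and a two-ingredient combination product) with
strengths from {1, 2, 5, 7.5, 10, 25, 125, 250, 500} mg so all ledger
arithmetic is exactly representable. Planting is deterministic (evenly
spaced assignment, not Bernoulli sampling), so planted fractions are exact
at any size; the same seed yields a byte-identical bundle.

What the fixtures do **not** emulate: realistic prescribing volume
distributions, seasonal shapes, dirty postcodes beyond case/spacing noise,
truncated BNF codes, or hierarchy churn across releases. Passing the
round-trip therefore demonstrates the pipeline's arithmetic, resolution
logic and accounting are correct — not that real extracts are clean. The
reject-log discipline (nothing silently dropped) is the designed defence for
real data.

## Scale of the shipped checks

Tests and the acceptance script run the full pipeline at the 20 × 12 × 10
study size (~10⁴ rows, a few seconds) and verify containment against an
independent winding-number oracle on 1000 random points, and catalog
construction against an exhaustive-path walk on ≤ 50-node hierarchies.
National extracts (10⁷ rows/month) are out of scope for the shipped checks;
the readers stream row-wise, so memory, not correctness, is the only
scale-sensitive part.

## Known limitations

- No VTM (therapeutic moiety) level; private prescriptions absent from the
  extracts by construction.
- Salt-mass vs base-mass as above; flagged, not corrected.
- Concentration handling assumes the quantity is reported in the
  denominator's unit; mismatched unit kinds are rejected rather than
  guessed.
- A practice's entire dispensing is attributed to its registered postcode;
  patients dispensing elsewhere blur the spatial signal (inherent to the
  source data).
- The practice directory keeps one postcode per practice (latest period
  wins, earlier values logged); mid-study moves are therefore attributed to
  the final location.
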