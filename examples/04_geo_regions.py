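"""Geolocate practices by postcode and assign them to a region polygon.

Joins a small practice directory to a postcode lookup, then uses even-odd
ray-casting containment against a rectangular region; one practice has a
postcode absent from the lookup and is retained without coordinates.
"""

import pandas as pd

from rxmass import RegionBoundary, geolocate_practices, practices_in_region

directory = pd.DataFrame(
    [
        ["P1", "Riverside Surgery", "1 High St", "ba1  1aa"],   # messy spacing
        ["P2", "Hilltop Practice", "2 Hill Rd", "BA2 2BB"],
        ["P3", "Old Mill Surgery", "3 Mill Ln", "ZZ9 9ZZ"],      # not in lookup
    ],
    columns=["practice", "name", "address", "postcode"],
)
lookup = pd.DataFrame(
    [["BA1 1AA", -2.36, 51.38], ["BA2 2BB", -2.35, 51.36]],
    columns=["postcode", "lon", "lat"],
)

geo, unmatched = geolocate_practices(directory, lookup)
print(geo[["practice", "postcode", "lon", "lat"]])
print(f"unmatched postcodes: {list(unmatched['practice'])}")

region = RegionBoundary(
    "Demo region",
    [[[(-2.40, 51.37), (-2.30, 51.37), (-2.30, 51.40), (-2.40, 51.40), (-2.40, 51.37)]]],
)
print(f"practices inside region: {practices_in_region(geo, region)}")
# P1 falls inside the rectangle; P2 lies south of it; P3 has no coordinates,
# so it can never be counted in a region.
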