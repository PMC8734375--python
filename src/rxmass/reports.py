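"""Report tables and exports: the data products behind the dashboard views.

Targeted view: the user supplies a CSV list of active ingredients of interest
and gets annual, monthly, per-practice, per-postcode and per-form kg tables
for one region and year.  Non-targeted view: one ingredient, one region and
period, broken down by postcode with monthly series and per-form percentage
shares.

Every cell is reproducible by filtering and summing the contributions table
directly; plots are static (bar charts with a colour-blind-safe palette) and
export to csv/png/eps/pdf.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from .quantify import aggregate

EXPORT_FORMATS = ("csv", "png", "eps", "pdf")

#: Okabe–Ito colour-blind-safe palette.
PALETTE = [
    "#E69F00", "#56B4E9", "#009E73", "#F0E442",
    "#0072B2", "#D55E00", "#CC79A7", "#000000",
]


def read_api_list(path: str | Path) -> list[str]:
    """Read a comma-separated list of ingredient names (one or many per line)."""
    names: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh):
            names.extend(cell.strip() for cell in row if cell.strip())
    # drop an obvious header cell
    if names and names[0].lower() in ("api", "apis", "ingredient", "name"):
        names = names[1:]
    if not names:
        raise ValueError(f"{path}: API list is empty; supply at least one ingredient name")
    seen, out = set(), []
    for n in names:
        if n.lower() not in seen:
            seen.add(n.lower())
            out.append(n)
    return out


def _months_of(year: int) -> list[str]:
    return [f"{year}{m:02d}" for m in range(1, 13)]


def _filter(contributions: pd.DataFrame, region: str | None, year: int | None) -> pd.DataFrame:
    df = contributions
    if region is not None and "region" in df.columns:
        df = df[df["region"] == region]
    if year is not None:
        df = df[df["period"].astype(str).str[:4].astype(int) == int(year)]
    return df


def targeted_report(
    contributions: pd.DataFrame,
    api_list: list[str],
    region: str | None,
    year: int,
) -> dict[str, pd.DataFrame]:
    """Five kg tables for the listed ingredients in one region and year.

    Returns ``annual`` (api), ``monthly`` (api × all 12 months, zero-filled so
    seasonal shapes are comparable), ``per_practice``, ``per_postcode`` and
    ``per_form``.  Listed ingredients absent from the data appear with 0 kg.
    """
    if not api_list:
        raise ValueError("API list is empty; supply at least one ingredient name")
    df = _filter(contributions, region, year)
    by_key = {a.lower(): a for a in api_list}
    df = df[df["api"].str.lower().isin(by_key)]

    annual = aggregate(df, ["api"]) if not df.empty else pd.DataFrame(columns=["api", "mass_kg"])
    present = set(annual["api"].str.lower()) if not annual.empty else set()
    fill = [{"api": by_key[a], "mass_kg": 0.0} for a in by_key if a not in present]
    if fill:
        frames = [f for f in (annual, pd.DataFrame(fill, columns=["api", "mass_kg"])) if not f.empty]
        annual = pd.concat(frames, ignore_index=True)
    annual = annual.sort_values("api", kind="stable").reset_index(drop=True)

    monthly = aggregate(df, ["api", "period"]) if not df.empty else pd.DataFrame(
        columns=["api", "period", "mass_kg"]
    )
    grid = pd.MultiIndex.from_product(
        [annual["api"], _months_of(year)], names=["api", "period"]
    ).to_frame(index=False)
    monthly = grid.merge(monthly, on=["api", "period"], how="left").fillna({"mass_kg": 0.0})

    def agg_or_empty(keys):
        if df.empty:
            return pd.DataFrame(columns=keys + ["mass_kg"])
        cols = [k for k in keys if k in df.columns]
        return aggregate(df, cols)

    return {
        "annual": annual,
        "monthly": monthly,
        "per_practice": agg_or_empty(["api", "practice"]),
        "per_postcode": agg_or_empty(["api", "postcode"]),
        "per_form": agg_or_empty(["api", "form"]),
    }


def nontargeted_report(
    contributions: pd.DataFrame,
    api: str,
    region: str | None,
    period: str | None = None,
    year: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Postcode-resolved view of one ingredient.

    ``per_postcode`` — kg by postcode for the requested period (or whole
    year); ``monthly_by_postcode`` — postcode × month series; ``form_shares``
    — percentage of total kg by medicinal form (sums to 100 when any mass is
    present).
    """
    df = _filter(contributions, region, year)
    df = df[df["api"].str.lower() == api.lower()]
    if period is not None:
        df_p = df[df["period"].astype(str) == str(period)]
    else:
        df_p = df
    per_postcode = (
        aggregate(df_p, ["postcode"]) if not df_p.empty else pd.DataFrame(columns=["postcode", "mass_kg"])
    )
    monthly = (
        aggregate(df, ["postcode", "period"])
        if not df.empty
        else pd.DataFrame(columns=["postcode", "period", "mass_kg"])
    )
    if df_p.empty:
        shares = pd.DataFrame(columns=["form", "mass_kg", "share_pct"])
    else:
        shares = aggregate(df_p, ["form"])
        total = shares["mass_kg"].sum()
        shares["share_pct"] = shares["mass_kg"] / total * 100.0 if total > 0 else 0.0
    return {
        "per_postcode": per_postcode,
        "monthly_by_postcode": monthly,
        "form_shares": shares,
    }


def export(
    table: pd.DataFrame,
    path: str | Path,
    fmt: str,
    title: str | None = None,
    x: str | None = None,
    y: str = "mass_kg",
) -> Path:
    """Write *table* as csv, or as a bar chart (png/eps/pdf) titled *title*.

    CSV round-trips numerically.  Unknown formats raise ValueError listing the
    supported ones.
    """
    fmt = fmt.lower().lstrip(".")
    if fmt not in EXPORT_FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; supported: {', '.join(EXPORT_FORMATS)}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        table.to_csv(path, index=False)
        return path

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if x is None:
        x = next(c for c in table.columns if c != y)
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(table) + 2), 4))
    labels = table[x].astype(str)
    colors = [PALETTE[i % len(PALETTE)] for i in range(len(table))]
    ax.bar(labels, table[y].astype(float), color=colors)
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    if title:
        ax.set_title(title)
    ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(path, format=fmt)
    plt.close(fig)
    return path
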