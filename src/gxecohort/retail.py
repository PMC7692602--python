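"""In-store retail food environment exposures from a weekly marketing panel.

The panel records, per store-week and stock-keeping unit (SKU), regular
price, package servings, and whether the SKU was promoted, on display, and
available, for two food categories: vegetables (healthful anchor) and soft
drinks (unhealthful anchor).  Four marketing indicators summarise each
(FSA, quarter, category) cell:

- ``variety``: mean over store-weeks of the number of distinct available SKUs,
- ``regular_price_per_serving``: mean of price/servings over non-promoted
  observations (undefined if every observation was promoted),
- ``discount_frequency``: share of observations promoted,
- ``display_share``: on-display share of available SKUs, averaged over
  store-weeks.

For each indicator the vegetable:soft-drink ratio is taken per quarter and
the quarterly series is collapsed to a single exposure per forward
sortation area (FSA) with exponential smoothing that up-weights recent
quarters.  A ratio above 1 is healthful for variety, discount and display;
for regular price a ratio above 1 means vegetables cost more relative to
soft drinks, which is unhealthful.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CATEGORIES = ("vegetables", "soft_drinks")
INDICATORS = ("variety", "regular_price_per_serving", "discount_frequency", "display_share")
# exposure column per indicator
RATIO_COLUMNS = {
    "variety": "variety_ratio",
    "regular_price_per_serving": "price_ratio",
    "discount_frequency": "discount_ratio",
    "display_share": "display_ratio",
}
# ratio > 1 healthful? price is inverted: dearer vegetables are unhealthful
HEALTHFUL_ABOVE_ONE = {
    "variety": True,
    "discount_frequency": True,
    "display_share": True,
    "regular_price_per_serving": False,
}

PANEL_COLUMNS = ["fsa", "quarter", "week", "store", "category", "sku",
                 "price", "servings", "promoted", "on_display", "available"]


def validate_panel(panel: pd.DataFrame) -> None:
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel missing columns: {missing}")
    if (panel["price"] < 0).any():
        raise ValueError("negative prices in panel")
    if (panel["servings"] < 1).any():
        raise ValueError("servings per package must be >= 1")


def compute_indicators(panel: pd.DataFrame, fsa: str, quarter: str) -> dict:
    """Four marketing indicators per category for one (FSA, quarter) cell.

    Returns ``{category: {indicator: value}}``; regular price is NaN when
    the cell has no non-promoted observation (to be imputed downstream, by
    design: a promoted price is not a regular price).
    """
    cell = panel[(panel["fsa"] == fsa) & (panel["quarter"] == quarter)]
    if cell.empty:
        raise KeyError(f"panel has no rows for fsa={fsa!r}, quarter={quarter!r}")
    out = {}
    for cat, grp in cell.groupby("category"):
        avail = grp[grp["available"]]
        variety = (
            avail.groupby(["store", "week"])["sku"].nunique().mean()
            if not avail.empty else 0.0
        )
        non_promo = grp[~grp["promoted"].astype(bool)]
        price = (
            float((non_promo["price"] / non_promo["servings"]).mean())
            if not non_promo.empty else float("nan")
        )
        discount = float(grp["promoted"].astype(bool).mean())
        if avail.empty:
            display = float("nan")
        else:
            display = float(
                avail.groupby(["store", "week"])["on_display"].mean().mean()
            )
        out[cat] = {
            "variety": float(variety),
            "regular_price_per_serving": price,
            "discount_frequency": discount,
            "display_share": display,
        }
    return out


def healthfulness_ratio(veg_value: float, soda_value: float,
                        indicator: str = "variety") -> tuple:
    """Vegetable:soft-drink ratio plus its healthful/unhealthful reading."""
    if indicator not in HEALTHFUL_ABOVE_ONE:
        raise KeyError(f"unknown indicator: {indicator!r}")
    if not np.isfinite(veg_value) or not np.isfinite(soda_value):
        return float("nan"), "undefined"
    if soda_value <= 0:
        return float("nan"), "undefined (zero denominator)"
    ratio = veg_value / soda_value
    above = ratio > 1
    healthful = above if HEALTHFUL_ABOVE_ONE[indicator] else not above
    return ratio, "healthful" if healthful else "unhealthful"


def exponential_smooth(series_by_quarter: pd.Series, decay: float) -> float:
    """Recency-weighted mean over quarters.

    Non-missing quarters ``q`` (positions in the sorted index) receive
    weights proportional to ``(1-decay)**(latest-q)``, normalised to sum to
    one; the most recent quarter is always the heaviest.  Returns NaN when
    every quarter is missing.
    """
    if not 0 < decay < 1:
        raise ValueError("decay must lie in (0, 1)")
    s = pd.Series(series_by_quarter).sort_index()
    vals = s.to_numpy(dtype=float)
    pos = np.arange(len(s))
    ok = np.isfinite(vals)
    if not ok.any():
        return float("nan")
    w = (1.0 - decay) ** (pos[ok].max() - pos[ok])
    w = w / w.sum()
    return float((w * vals[ok]).sum())


def build_exposures(panel: pd.DataFrame, decay: float = 0.3,
                    include_components: bool = False) -> pd.DataFrame:
    """One smoothed exposure row per FSA.

    Per FSA and indicator: compute quarterly vegetable and soft-drink
    indicator values, take the vegetable:soft-drink ratio within each
    quarter, then smooth the quarterly ratio series (ratio-then-smooth
    order, so each quarter's healthfulness stays interpretable before time
    averaging).  Columns: the four ``*_ratio`` exposures plus provenance
    (``n_quarters`` used per FSA).  With ``include_components`` the
    smoothed per-category indicator values are appended (``veg_*`` /
    ``soda_*``), which downstream imputation uses as auxiliary variables.
    """
    validate_panel(panel)
    prefix = {"vegetables": "veg", "soft_drinks": "soda"}
    rows = []
    for fsa in sorted(panel["fsa"].unique()):
        quarters = sorted(panel.loc[panel["fsa"] == fsa, "quarter"].unique())
        series = {ind: pd.Series(np.nan, index=quarters, dtype=float) for ind in INDICATORS}
        comp_series = {
            (cat, ind): pd.Series(np.nan, index=quarters, dtype=float)
            for cat in CATEGORIES for ind in INDICATORS
        }
        for q in quarters:
            cell = compute_indicators(panel, fsa, q)
            for cat in CATEGORIES:
                if cat in cell:
                    for ind in INDICATORS:
                        comp_series[(cat, ind)].loc[q] = cell[cat][ind]
            if not all(c in cell for c in CATEGORIES):
                continue
            for ind in INDICATORS:
                ratio, _ = healthfulness_ratio(
                    cell["vegetables"][ind], cell["soft_drinks"][ind], ind
                )
                series[ind].loc[q] = ratio
        row = {"fsa": fsa, "n_quarters": len(quarters)}
        for ind in INDICATORS:
            row[RATIO_COLUMNS[ind]] = exponential_smooth(series[ind], decay)
        if include_components:
            for cat in CATEGORIES:
                for ind in INDICATORS:
                    row[f"{prefix[cat]}_{RATIO_COLUMNS[ind].split('_')[0]}"] = (
                        exponential_smooth(comp_series[(cat, ind)], decay)
                    )
        rows.append(row)
    return pd.DataFrame(rows).set_index("fsa")
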