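"""Matching established alien species to trade and trade-breadth comparison.

Establishment is used at two levels: species-level (a species has at least
one self-sustaining alien population anywhere) for the breadth comparison
between established and unestablished traded aliens, and country-level
(which species established where) for establishment richness.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["match_established", "trade_breadth", "breadth_summary"]


def match_established(established: set, traded_alien: set) -> dict:
    """Intersect the established-species list with species traded as aliens.

    Returns the intersection, its size, and its share of all established
    species (percentage, one decimal; ``None`` for an empty list).
    """
    from .classify import round_half_up

    inter = set(established) & set(traded_alien)
    share = (round_half_up(100.0 * len(inter) / len(established), 1)
             if established else None)
    return {
        "established_by_trade": inter,
        "n_established_by_trade": len(inter),
        "n_established": len(set(established)),
        "traded_share_of_established_pct": share,
    }


def trade_breadth(classified: pd.DataFrame, countries: pd.DataFrame,
                  established: set) -> pd.DataFrame:
    """Per-species trade breadth: distinct trading countries and summed area.

    All trade records (alien and native labels) count toward breadth;
    ``trade_area_km2`` sums the land areas of the distinct trading
    countries, treating a missing area as zero.
    """
    area = countries.set_index("country")["area_km2"]
    pairs = classified.drop_duplicates(["accepted_name", "country"])
    g = pairs.groupby("accepted_name")
    n_countries = g["country"].nunique()
    areas = g["country"].apply(lambda s: float(area.reindex(s).fillna(0.0).sum()))
    cls = classified.drop_duplicates("accepted_name").set_index("accepted_name")["class"]
    out = pd.DataFrame({
        "accepted_name": n_countries.index,
        "class": cls.reindex(n_countries.index).to_numpy(),
        "established": n_countries.index.isin(established).astype(int),
        "n_trade_countries": n_countries.to_numpy(),
        "trade_area_km2": areas.to_numpy(),
    }).reset_index(drop=True)
    return out


def breadth_summary(breadth: pd.DataFrame,
                    metric: str = "n_trade_countries") -> pd.DataFrame:
    """Per-class group means +/- sd and established/unestablished mean ratio.

    Sample sd (n-1); single-member groups report sd ``NaN``; an empty group
    leaves the ratio undefined (``NaN``).  Ratios are rounded to two
    decimals, matching the reporting convention.
    """
    from .classify import round_half_up

    rows = []
    for cls, sub in breadth.groupby("class"):
        est = sub.loc[sub["established"] == 1, metric].astype(float)
        une = sub.loc[sub["established"] == 0, metric].astype(float)
        m1 = est.mean() if len(est) else np.nan
        m0 = une.mean() if len(une) else np.nan
        ratio = round_half_up(m1 / m0, 2) if len(est) and len(une) and m0 else np.nan
        rows.append({
            "class": cls,
            "n_established": int(len(est)),
            "n_unestablished": int(len(une)),
            "mean_established": m1,
            "sd_established": est.std(ddof=1) if len(est) > 1 else np.nan,
            "mean_unestablished": m0,
            "sd_unestablished": une.std(ddof=1) if len(une) > 1 else np.nan,
            "ratio_of_means": ratio,
        })
    return pd.DataFrame(rows)
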