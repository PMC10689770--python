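"""Alien/native classification of traded species-country combinations.

A species traded in a country outside its native range is an *alien in
trade* there; the number of distinct alien species traded in a country is
its *colonization pressure*.  The native range of a species is the set of
countries with native extant, native possibly extant, extinct, or possibly
extinct presence; countries where the species has only an introduced
presence never count as native.  Species with no range data at all are
labeled ``unknown-range`` and excluded from richness accounting while
remaining in trade totals.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "CLASSES",
    "native_range",
    "classify_record",
    "classify_records",
    "species_alien_status",
    "country_richness",
    "venn_counts",
    "share_metrics",
    "round_half_up",
]

CLASSES = ("mammal", "bird", "reptile", "amphibian")

_NATIVE_PRESENCE = ("native_extant", "native_possibly_extant",
                    "extinct", "possibly_extinct")


def native_range(species_row) -> frozenset:
    """Native country set of one species-master row.

    The row holds presence fields as iterables (or delimited strings) named
    after the presence categories; the native range is their union, with
    ``introduced`` countries excluded.
    """
    out: set = set()
    for fieldname in _NATIVE_PRESENCE:
        out |= _as_set(species_row.get(fieldname))
    return frozenset(out - _as_set(species_row.get("introduced")))


def _as_set(value) -> set:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return set()
    if isinstance(value, str):
        return {v for v in value.split(";") if v}
    return set(value)


def native_ranges(species: pd.DataFrame) -> dict[str, frozenset]:
    """Native-range country sets for every row of a species master table."""
    n = len(species)
    cols = [species[c] if c in species.columns else pd.Series([""] * n)
            for c in _NATIVE_PRESENCE]
    intro = (species["introduced"] if "introduced" in species.columns
             else pd.Series([""] * n))
    out: dict[str, frozenset] = {}
    for name, *pres, inr in zip(species["accepted_name"], *cols, intro):
        s: set = set()
        for p in pres:
            s |= _as_set(p)
        out[name] = frozenset(s - _as_set(inr))
    return out


def classify_record(accepted_name: str, country: str,
                    ranges: dict[str, frozenset]) -> str:
    """Label one (species, country) combination alien / native / unknown-range."""
    if accepted_name not in ranges:
        raise KeyError(f"species not in master table: {accepted_name!r}")
    rng = ranges[accepted_name]
    if not rng:
        return "unknown-range"
    return "native" if country in rng else "alien"


def classify_records(clean: pd.DataFrame, species: pd.DataFrame) -> pd.DataFrame:
    """Classify every cleaned trade record against the species master.

    ``species`` must carry ``accepted_name``, ``class`` and the presence
    fields read by :func:`native_range`.  Returns the input plus ``label``
    and ``class`` columns.
    """
    ranges = native_ranges(species)
    unknown = clean.loc[~clean["accepted_name"].isin(ranges), "accepted_name"]
    if len(unknown):
        raise KeyError(f"species not in master table: {sorted(set(unknown))[:5]}")
    out = clean.copy()
    cls = species.set_index("accepted_name")["class"]
    out["class"] = out["accepted_name"].map(cls).to_numpy()
    empties = {name for name, rng in ranges.items() if not rng}
    is_unknown = out["accepted_name"].isin(empties)
    # Vectorized membership: explode ranges once into a (species, country) frame.
    pairs = pd.DataFrame(
        [(name, c) for name, rng in ranges.items() for c in rng],
        columns=["accepted_name", "country"],
    )
    pairs["__native"] = True
    merged = out.merge(pairs, on=["accepted_name", "country"], how="left")
    label = np.where(merged["__native"].notna().to_numpy(), "native", "alien")
    label = np.where(is_unknown.to_numpy(), "unknown-range", label)
    out["label"] = label
    return out


def species_alien_status(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-species flags: alien anywhere, native-only, both alien and native."""
    g = classified.groupby("accepted_name")["label"]
    any_alien = g.apply(lambda s: bool((s == "alien").any()))
    any_native = g.apply(lambda s: bool((s == "native").any()))
    return pd.DataFrame({
        "alien_anywhere": any_alien,
        "native_only": ~any_alien & any_native,
        "both_alien_and_native": any_alien & any_native,
    }).reset_index()


def country_richness(classified: pd.DataFrame,
                     establishment: pd.DataFrame | None = None) -> pd.DataFrame:
    """Distinct-species richness per country, class and label.

    Returns one row per country with columns ``alien_<class>``,
    ``native_<class>``, ``established_<class>`` plus ``alien_total`` (the
    colonization pressure), ``native_total`` and ``established_total``.
    Unknown-range records are excluded from every count.
    """
    known = classified[classified["label"].isin(["alien", "native"])]
    counts = (known.drop_duplicates(["accepted_name", "country", "label"])
              .groupby(["country", "class", "label"])["accepted_name"]
              .nunique().unstack(["label", "class"], fill_value=0))
    countries = sorted(classified["country"].unique())
    out = pd.DataFrame({"country": countries}).set_index("country")
    for label in ("alien", "native"):
        total = np.zeros(len(out), dtype=int)
        for cls in CLASSES:
            col = counts[(label, cls)] if (label, cls) in counts.columns else None
            vals = (col.reindex(out.index).fillna(0).astype(int)
                    if col is not None else pd.Series(0, index=out.index))
            out[f"{label}_{cls}"] = vals
            total += vals.to_numpy()
        out[f"{label}_total"] = total

    if establishment is None:
        establishment = pd.DataFrame(columns=["accepted_name", "country"])
    # Established-alien richness: established (species, country) pairs where
    # the species is an alien in trade in that country.
    alien_pairs = known.loc[known["label"] == "alien",
                            ["accepted_name", "country", "class"]].drop_duplicates()
    est = establishment.merge(alien_pairs, on=["accepted_name", "country"])
    ecounts = (est.drop_duplicates(["accepted_name", "country"])
               .groupby(["country", "class"])["accepted_name"].nunique()
               .unstack("class", fill_value=0))
    total = np.zeros(len(out), dtype=int)
    for cls in CLASSES:
        vals = (ecounts[cls].reindex(out.index).fillna(0).astype(int)
                if cls in ecounts.columns else pd.Series(0, index=out.index))
        out[f"established_{cls}"] = vals
        total += vals.to_numpy()
    out["established_total"] = total
    return out.reset_index()


def venn_counts(source_sets: dict[str, set]) -> dict:
    """Counts of the 15 non-empty intersection regions of 4 source sets.

    Returns a dict with one entry per region keyed by a ``+``-joined sorted
    source combination (exclusive region counts), plus ``union``,
    ``unique_total`` (species in exactly one source) and ``unique_share``
    (percentage, one decimal).
    """
    if len(source_sets) != 4:
        raise ValueError(f"need exactly 4 source sets, got {len(source_sets)}")
    names = sorted(source_sets)
    union = set().union(*source_sets.values())
    regions: dict[str, int] = {}
    unique_total = 0
    for r in range(1, 5):
        for combo in combinations(names, r):
            inside = set.intersection(*(set(source_sets[n]) for n in combo))
            outside = set().union(*(set(source_sets[n]) for n in names
                                    if n not in combo)) if r < 4 else set()
            exclusive = inside - outside
            regions["+".join(combo)] = len(exclusive)
            if r == 1:
                unique_total += len(exclusive)
    return {
        "regions": regions,
        "union": len(union),
        "unique_total": unique_total,
        "unique_share": round_half_up(100.0 * unique_total / len(union), 1)
        if union else None,
    }


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (the reporting convention for percentages)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def share_metrics(totals: dict) -> dict:
    """Headline share percentages and ratios from count totals.

    ``totals`` carries ``extant``, ``traded``, ``alien_traded``,
    ``established_traded_alien``, ``established_all``, ``native_only``,
    ``both_alien_and_native``.  Percentages are rounded half-up to one
    decimal, ratios to two; zero denominators yield ``None``.
    """

    def pct(num, den):
        return round_half_up(100.0 * num / den, 1) if den else None

    return {
        "traded_of_extant_pct": pct(totals["traded"], totals.get("extant", 0)),
        "alien_of_traded_pct": pct(totals["alien_traded"], totals["traded"]),
        "native_only_of_traded_pct": pct(totals["native_only"], totals["traded"]),
        "both_of_alien_pct": pct(totals["both_alien_and_native"],
                                 totals["alien_traded"]),
        "established_of_alien_pct": pct(totals["established_traded_alien"],
                                        totals["alien_traded"]),
        "traded_of_established_pct": pct(totals["established_traded_alien"],
                                         totals.get("established_all", 0)),
    }
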