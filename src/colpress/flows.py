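"""Donor-to-recipient species-flow matrices among the 8 economic regions.

A species contributes one flow unit for every distinct (species, donor
region, recipient region) triple in which it is native in at least one
country of the donor region and traded as an alien in at least one country
of the recipient region — so a species native in 2 regions and alien-traded
in 3 contributes 6 units, and intraregional flow (diagonal) arises when the
native and alien countries fall in the same region.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["DEFAULT_REGIONS", "assign_regions", "flow_matrix",
           "region_totals", "export_chord", "matrix_from_chord"]

DEFAULT_REGIONS = (
    "South and East Asia", "Mideast and Central Asia", "Africa", "Europe",
    "North America", "Central America", "South America", "Oceania",
)


def assign_regions(countries, region_map: pd.DataFrame,
                   regions=DEFAULT_REGIONS) -> tuple[dict, list]:
    """Validate a country -> region mapping against the configured regions.

    Returns (mapping, unmapped-country list); an out-of-schema region name
    is an error, an unmapped country is excluded with a warning entry.
    """
    bad = set(region_map["region"].unique()) - set(regions)
    if bad:
        raise ValueError(f"regions outside the configured set: {sorted(bad)}")
    mapping = dict(zip(region_map["country"], region_map["region"]))
    unmapped = [c for c in countries if c not in mapping]
    return {c: mapping[c] for c in countries if c in mapping}, unmapped


def flow_matrix(classified: pd.DataFrame, species: pd.DataFrame,
                region_map: pd.DataFrame, which: str = "all",
                established: set | None = None,
                regions=DEFAULT_REGIONS) -> pd.DataFrame:
    """Region-by-region distinct-species flow counts.

    Parameters
    ----------
    classified : classified trade records (needs ``accepted_name``,
        ``country``, ``label``).
    species : species master with the presence fields defining native range.
    which : ``"all"`` for every traded alien, ``"established"`` to restrict
        to the established-by-trade species (requires ``established``).
    """
    from .classify import native_ranges

    if which not in {"all", "established"}:
        raise ValueError(f"unknown filter label: {which!r}")
    mapping, _ = assign_regions(
        set(classified["country"]).union(region_map["country"]),
        region_map, regions)

    alien = classified.loc[classified["label"] == "alien",
                           ["accepted_name", "country"]].drop_duplicates()
    if which == "established":
        if established is None:
            raise ValueError("established species set required for this filter")
        alien = alien[alien["accepted_name"].isin(established)]

    alien = alien.assign(recipient=alien["country"].map(mapping)).dropna(
        subset=["recipient"])
    recip = alien[["accepted_name", "recipient"]].drop_duplicates()

    wanted = set(recip["accepted_name"])
    ranges = {name: rng for name, rng in
              native_ranges(species).items() if name in wanted}
    donor_rows = [(name, mapping[c]) for name, rng in ranges.items()
                  for c in rng if c in mapping]
    donors = pd.DataFrame(donor_rows, columns=["accepted_name", "donor"]
                          ).drop_duplicates()

    triples = donors.merge(recip, on="accepted_name").drop_duplicates()
    mat = pd.DataFrame(0, index=list(regions), columns=list(regions), dtype=int)
    if len(triples):
        counts = triples.groupby(["donor", "recipient"]).size()
        for (d, r), v in counts.items():
            mat.loc[d, r] = int(v)
    return mat


def region_totals(matrix: pd.DataFrame) -> dict:
    """Donor (row), recipient (column) and grand totals of a flow matrix."""
    return {
        "donor": matrix.sum(axis=1).to_dict(),
        "recipient": matrix.sum(axis=0).to_dict(),
        "grand_total": int(matrix.to_numpy().sum()),
    }


def export_chord(matrix: pd.DataFrame) -> pd.DataFrame:
    """Long-format edge table (donor, recipient, count) of non-zero entries."""
    long = matrix.stack().rename("count").reset_index()
    long.columns = ["donor", "recipient", "count"]
    return long[long["count"] > 0].reset_index(drop=True)


def matrix_from_chord(edges: pd.DataFrame, regions=DEFAULT_REGIONS) -> pd.DataFrame:
    """Inverse of :func:`export_chord` (exact round-trip)."""
    mat = pd.DataFrame(0, index=list(regions), columns=list(regions), dtype=int)
    for _, row in edges.iterrows():
        mat.loc[row["donor"], row["recipient"]] = int(row["count"])
    return mat
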