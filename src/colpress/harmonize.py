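"""Cleaning and taxonomic harmonization of raw trade records.

Raw trade tables arrive from four source dialects (CITES-like and LEMIS-like
transaction logs, zoo-inventory rows, and free-text online listings).  This
module resolves every name to an accepted scientific name through a key
table (synonyms, common names, trade names), extracts name keys from free
text with spreadsheet LOOKUP-over-sorted-array semantics (the key returned
is the one occurring in the text that sorts last in a length-ascending,
lexicographically tie-broken index, i.e. the longest match), and applies the
quality-control exclusion rules: live-term filtering, duplicated lines,
identical importer and exporter, missing names, genus-only and hybrid
markers, and the zoo-source exclusion of threatened species.
"""

from __future__ import annotations

import re
from collections import deque
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "NameKey",
    "KeyIndex",
    "AmbiguousKeyError",
    "build_key_index",
    "extract_name",
    "resolve_accepted",
    "clean_trade_records",
    "exclude_isis_threatened",
    "SOURCES",
    "THREATENED_CATEGORIES",
]

SOURCES = ("CITES", "LEMIS", "ISIS", "OTAPS")
#: IUCN categories treated as threatened for the zoo-inventory exclusion.
THREATENED_CATEGORIES = frozenset({"VU", "EN", "CR"})

_GENUS_ONLY = re.compile(r"\b(sp|spp)\.?$", re.IGNORECASE)
_HYBRID = re.compile(r"(×|\bx\b|hybrid)", re.IGNORECASE)


class AmbiguousKeyError(ValueError):
    """A key string maps to more than one accepted name."""

    def __init__(self, collisions: dict[str, set[str]]):
        self.collisions = collisions
        lines = "; ".join(f"{k!r} -> {sorted(v)}" for k, v in sorted(collisions.items()))
        super().__init__(f"ambiguous keys: {lines}")


@dataclass(frozen=True)
class NameKey:
    """One lookup key pointing at an accepted scientific name."""

    key_string: str
    accepted_name: str
    key_type: str = "scientific"  # scientific|synonym|common|trade-name|specific
    language: str = "en"

    def __post_init__(self):
        if not self.key_string:
            raise ValueError("key_string must be non-empty")


class _Aho:
    """Minimal Aho-Corasick automaton over lowercase patterns.

    Finds every pattern occurring as a substring of a query in a single
    pass; no installed library provides multi-pattern matching, and a
    per-key scan is quadratic in corpus size.
    """

    def __init__(self, patterns: list[str]):
        self.goto: list[dict[str, int]] = [{}]
        self.out: list[list[int]] = [[]]
        self.fail: list[int] = [0]
        for pid, pat in enumerate(patterns):
            node = 0
            for ch in pat:
                nxt = self.goto[node].get(ch)
                if nxt is None:
                    nxt = len(self.goto)
                    self.goto[node][ch] = nxt
                    self.goto.append({})
                    self.out.append([])
                    self.fail.append(0)
                node = nxt
            self.out[node].append(pid)
        q: deque[int] = deque()
        for child in self.goto[0].values():
            q.append(child)
        while q:
            node = q.popleft()
            for ch, child in self.goto[node].items():
                q.append(child)
                f = self.fail[node]
                while f and ch not in self.goto[f]:
                    f = self.fail[f]
                self.fail[child] = self.goto[f].get(ch, 0) if self.goto[f].get(ch, 0) != child else 0
                self.out[child] = self.out[child] + self.out[self.fail[child]]

    def search(self, text: str):
        """Yield pattern ids occurring in ``text`` (with multiplicity collapsed)."""
        found: set[int] = set()
        node = 0
        for ch in text:
            while node and ch not in self.goto[node]:
                node = self.fail[node]
            node = self.goto[node].get(ch, 0)
            if self.out[node]:
                found.update(self.out[node])
        return found


@dataclass
class KeyIndex:
    """Length-ascending key index implementing the sorted-array lookup.

    Keys are lowercased; ordering is by character count, equal lengths
    broken lexicographically, so the last matching element of the array is
    the longest (then lexicographically greatest) key occurring in a text.
    """

    keys: list[str]
    accepted: dict[str, str]
    _automaton: _Aho | None = field(default=None, repr=False, compare=False)

    def automaton(self) -> _Aho:
        if self._automaton is None:
            self._automaton = _Aho(self.keys)
        return self._automaton


def build_key_index(keys) -> KeyIndex:
    """Build the lookup index from an iterable of :class:`NameKey`.

    Raises :class:`AmbiguousKeyError` if one lowercased key string maps to
    several accepted names.
    """
    mapping: dict[str, set[str]] = {}
    for k in keys:
        mapping.setdefault(k.key_string.lower(), set()).add(k.accepted_name)
    if not mapping:
        raise ValueError("no keys supplied")
    collisions = {k: v for k, v in mapping.items() if len(v) > 1}
    if collisions:
        raise AmbiguousKeyError(collisions)
    ordered = sorted(mapping, key=lambda s: (len(s), s))
    return KeyIndex(keys=ordered, accepted={k: next(iter(v)) for k, v in mapping.items()})


def extract_name(text: str, index: KeyIndex) -> str | None:
    """Extract the name key from free text; ``None`` when no key occurs.

    Case-insensitive substring search without word-boundary enforcement;
    among all keys present, returns the one last in the index ordering.
    """
    hits = index.automaton().search(text.lower())
    if not hits:
        return None
    return max((index.keys[i] for i in hits), key=lambda s: (len(s), s))


def resolve_accepted(key_string: str, index: KeyIndex) -> str | None:
    """Exact lookup of a key to its accepted name; ``None`` if unresolved."""
    return index.accepted.get(key_string.lower())


def _is_genus_only(name: str) -> bool:
    return bool(_GENUS_ONLY.search(name.strip()))


def _is_hybrid(name: str) -> bool:
    return bool(_HYBRID.search(name))


def clean_trade_records(raw: pd.DataFrame, index: KeyIndex,
                        countries: set[str] | None = None):
    """Apply QC rules and name resolution to a raw multi-source trade table.

    Parameters
    ----------
    raw : DataFrame with columns ``source``, ``name`` (scientific name or
        free listing text for OTAPS rows), ``country``, optional
        ``exporter``, ``term``, ``year``.
    index : the key index used for free-text extraction and resolution.
    countries : optional set of known country ids; records whose country is
        not in the set are excluded and counted.

    Returns
    -------
    (clean, report) : cleaned DataFrame with columns
        ``source, accepted_name, country, year`` and a dict counting removals
        by rule.  The rule order is: unknown source check, non-live term,
        exact duplicate lines, importer==exporter, missing name, genus-only
        marker, hybrid marker, unresolved name, unknown country.
    """
    required = {"source", "name", "country"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"raw table missing columns: {sorted(missing)}")
    bad_sources = set(raw["source"].unique()) - set(SOURCES)
    if bad_sources:
        raise ValueError(f"unknown source labels: {sorted(bad_sources)}")

    report = {
        "input_rows": int(len(raw)),
        "non_live_term": 0,
        "duplicate_lines": 0,
        "same_importer_exporter": 0,
        "missing_name": 0,
        "genus_only": 0,
        "hybrid": 0,
        "unresolved_name": 0,
        "unknown_country": 0,
    }
    df = raw.copy()

    if "term" in df.columns:
        trans = df["source"].isin(["CITES", "LEMIS"])
        keep = ~trans | (df["term"].astype(str).str.lower().isin(["live", "liv"]))
        report["non_live_term"] = int((~keep).sum())
        df = df[keep]

    before = len(df)
    df = df.drop_duplicates()
    report["duplicate_lines"] = before - len(df)

    if "exporter" in df.columns:
        same = df["exporter"].notna() & (df["exporter"] == df["country"])
        report["same_importer_exporter"] = int(same.sum())
        df = df[~same]

    name = df["name"].astype("string")
    blank = name.isna() | (name.str.strip() == "")
    report["missing_name"] = int(blank.sum())
    df, name = df[~blank], name[~blank]

    # Free-text listings go through key extraction first.
    is_text = df["source"] == "OTAPS"
    extracted = name.str.lower().copy()
    if is_text.any():
        auto = index.automaton()
        keys = index.keys

        def _ext(t: str) -> str | None:
            hits = auto.search(t.lower())
            if not hits:
                return None
            return max((keys[i] for i in hits), key=lambda s: (len(s), s))

        extracted.loc[is_text] = name[is_text].map(_ext)
    no_key = extracted.isna()
    report["unresolved_name"] += int(no_key.sum())
    df, extracted = df[~no_key], extracted[~no_key]

    genus = extracted.map(_is_genus_only)
    report["genus_only"] = int(genus.sum())
    df, extracted = df[~genus], extracted[~genus]
    hybrid = extracted.map(_is_hybrid)
    report["hybrid"] = int(hybrid.sum())
    df, extracted = df[~hybrid], extracted[~hybrid]

    accepted = extracted.map(index.accepted)
    unresolved = accepted.isna()
    report["unresolved_name"] += int(unresolved.sum())
    df, accepted = df[~unresolved], accepted[~unresolved]

    if countries is not None:
        bad = ~df["country"].isin(countries)
        report["unknown_country"] = int(bad.sum())
        df, accepted = df[~bad], accepted[~bad]

    clean = pd.DataFrame({
        "source": df["source"].to_numpy(),
        "accepted_name": accepted.to_numpy(),
        "country": df["country"].to_numpy(),
        "year": df["year"].to_numpy() if "year" in df.columns else pd.NA,
    })
    # Synonym resolution can fold distinct raw lines onto one record:
    # deduplicate resolved (source, species, country, year) once more.
    before = len(clean)
    clean = clean.drop_duplicates().reset_index(drop=True)
    report["duplicate_after_resolution"] = before - len(clean)
    report["output_rows"] = int(len(clean))
    report["removed_total"] = report["input_rows"] - report["output_rows"]
    return clean, report


def exclude_isis_threatened(records: pd.DataFrame, species: pd.DataFrame) -> pd.DataFrame:
    """Drop zoo-inventory (ISIS) rows for threatened species (VU/EN/CR).

    Zoo holdings of threatened species are assumed to serve conservation
    rather than commerce; rows for the same species from other sources are
    untouched.
    """
    cat = species.set_index("accepted_name")["iucn_category"]
    threatened = records["accepted_name"].map(cat).isin(THREATENED_CATEGORIES)
    drop = (records["source"] == "ISIS") & threatened
    return records[~drop].reset_index(drop=True)
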