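"""Seeded synthetic worlds with a recoverable ground truth.

The generator emulates the structure of a global live-vertebrate-trade
compilation: a country table with socio-economic and climatic covariates,
an IUCN-like species master with native ranges clustered inside a home
biogeographic realm, four overlapping trade sources with fixed per-source
species marginals (two transaction logs, a zoo inventory, and free-text
online listings), configurable name noise (synonym use, typos, junk
listings) and planted quality-control violations, and establishment drawn
from (a) a species-level logistic model on trade breadth and (b) a
country-level log-linear model on the nine country predictors with realm
random intercepts.  Everything planted is written to a truth ledger so
that downstream stages can be checked for exact conservation and
parameter recovery.

All randomness flows from a single integer seed through independent named
substreams (see :func:`colpress.config.substream`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import SimConfig, substream
from .flows import DEFAULT_REGIONS
from .harmonize import THREATENED_CATEGORIES
from .inference import PREDICTORS

__all__ = [
    "generate_world", "generate_species", "generate_trade",
    "generate_establishment", "simulate_country_response", "generate_all",
]

_SYLLABLES = np.array([
    "ba", "ce", "di", "fo", "gu", "la", "me", "ni", "po", "ru", "sa", "te",
    "vi", "zo", "cha", "dre", "phi", "klo", "stu", "bra", "gle", "tri",
    "mor", "ven", "dul", "pex", "qui", "rho", "syl", "tur", "ulm", "vor",
    "wex", "yal", "zem", "cro", "fli", "gno", "hyp", "jor", "kel", "lum",
])
_FILLER = np.array([
    "for", "sale", "adult", "pair", "ship", "vet", "checked", "tame",
    "cage", "included", "juvenile", "captive", "bred", "nationwide",
    "pickup", "only", "healthy", "feeding", "well",
])
_IUCN = np.array(["LC", "NT", "VU", "EN", "CR", "DD"])
_IUCN_P = np.array([0.55, 0.09, 0.12, 0.10, 0.06, 0.08])

# Primary realm -> economic region assignment (with alternatives), used
# when the configured regions are the default 8.
_REALM_REGION = {
    "Afrotropics": (("Africa", "Mideast and Central Asia"), (0.85, 0.15)),
    "Australasia": (("Oceania", "South and East Asia"), (0.80, 0.20)),
    "Indo-Malay": (("South and East Asia", "Mideast and Central Asia"), (0.85, 0.15)),
    "Nearctic": (("North America", "Central America"), (0.90, 0.10)),
    "Neotropics": (("South America", "Central America"), (0.55, 0.45)),
    "Palaearctic": (("Europe", "Mideast and Central Asia"), (0.60, 0.40)),
    "Oceania": (("Oceania", "South and East Asia"), (0.90, 0.10)),
}

_TROPICAL = {"Afrotropics", "Indo-Malay", "Neotropics", "Oceania", "Australasia"}


def generate_world(config: SimConfig) -> pd.DataFrame:
    """Country table: realm, region, insularity, income class and covariates."""
    rng = substream(config.seed, "world")
    n = config.n_countries
    ids = np.array([f"C{i:03d}" for i in range(1, n + 1)])
    realms = rng.choice(np.array(config.realm_names), size=n)

    if set(config.region_names) == set(DEFAULT_REGIONS):
        regions = np.empty(n, dtype=object)
        for i, realm in enumerate(realms):
            if realm in _REALM_REGION:
                opts, probs = _REALM_REGION[realm]
                regions[i] = rng.choice(np.array(opts), p=np.array(probs))
            else:
                regions[i] = rng.choice(np.array(config.region_names))
    else:
        regions = rng.choice(np.array(config.region_names), size=n)

    insular = (rng.random(n) < np.where(realms == "Oceania", 0.7, 0.2)).astype(int)
    log_area = rng.normal(11.5, 1.8, n)
    area = np.exp(log_area)
    population = np.exp(7.5 + 0.75 * log_area + rng.normal(0.0, 1.0, n))
    gdp_pc = np.exp(rng.normal(9.2, 1.1, n))
    gdp = population * gdp_pc
    trade_value = np.exp(0.9 * np.log(gdp) + rng.normal(0.5, 0.8, n))
    temp = np.where(np.isin(realms, list(_TROPICAL)),
                    rng.normal(24.0, 3.0, n), rng.normal(8.0, 6.0, n))
    precip = np.exp(rng.normal(np.log(800.0), 0.6, n))
    effort = rng.uniform(0.02, 0.45, n)

    world = pd.DataFrame({
        "country": ids,
        "name": [f"Country {i:03d}" for i in range(1, n + 1)],
        "realm": realms,
        "region": regions,
        "insularity": insular,
        "income_class": pd.qcut(gdp_pc, 4, labels=["low", "lower-middle",
                                                   "upper-middle", "high"]).astype(str),
        "area_km2": area,
        "population": population,
        "gdp": gdp,
        "trade_value": trade_value,
        "mean_temperature_c": temp,
        "mean_precipitation_mm": precip,
        "sampling_effort": effort,
    })
    for cls in config.n_species_per_class:
        world[f"congeneric_{cls}"] = np.rint(
            np.exp(rng.normal(3.3, 0.8, n))).astype(int)
    return world


def _unique_words(rng, count, n_syll_low, n_syll_high, taken: set) -> list[str]:
    out: list[str] = []
    attempts = 0
    while len(out) < count:
        k = int(rng.integers(n_syll_low, n_syll_high + 1))
        w = "".join(rng.choice(_SYLLABLES, size=k))
        attempts += 1
        if attempts > 50 * max(count, 100):  # namespace nearly exhausted
            w += "".join(rng.choice(_SYLLABLES, size=2))
        if w not in taken:
            taken.add(w)
            out.append(w)
    return out


def generate_species(config: SimConfig, world: pd.DataFrame):
    """Species master plus name-key table.

    Each species gets accepted taxonomy (class/order/family/genus), an IUCN
    category, a native country set clustered within a home realm (with
    small spillover), and a disjoint introduced set.  The key table maps
    every accepted name, synonym and common name to the accepted name; key
    strings are globally unique, so resolution is unambiguous.
    """
    rng = substream(config.seed, "species")
    if not config.n_species_per_class:
        raise ValueError("n_species_per_class is empty")
    realm_countries = {r: world.loc[world["realm"] == r, "country"].to_numpy()
                       for r in config.realm_names}
    all_countries = world["country"].to_numpy()
    if all_countries.size == 0:
        raise ValueError("world has no countries; every native range would be empty")

    taken_words: set[str] = set()
    taken_names: set[str] = set()
    rows = []
    key_rows = []
    syn_rate = config.noise["synonym_rate"]
    for cls, count in config.n_species_per_class.items():
        n_fam = max(3, count // 60)
        n_ord = max(2, n_fam // 6)
        fam_names = [f"{w.capitalize()}idae" for w in
                     _unique_words(rng, n_fam, 2, 3, taken_words)]
        fam_order = rng.integers(0, n_ord, n_fam)
        # per-family genus pools
        genera_per_fam = [max(1, int(rng.poisson(4)) + 1) for _ in range(n_fam)]
        fam_genera = [[w.capitalize() for w in
                       _unique_words(rng, g, 2, 3, taken_words)]
                      for g in genera_per_fam]
        fams = rng.integers(0, n_fam, count)
        epithets = _unique_words(rng, count, 2, 4, taken_words)
        for i in range(count):
            fam = fams[i]
            genus = fam_genera[fam][int(rng.integers(0, len(fam_genera[fam])))]
            name = f"{genus} {epithets[i]}"
            if name in taken_names:  # genus reuse cannot collide (epithets unique)
                continue
            taken_names.add(name)
            home = config.realm_names[int(rng.integers(0, len(config.realm_names)))]
            pool = realm_countries[home]
            if pool.size == 0:
                pool = all_countries
            k = min(1 + int(rng.poisson(3)), pool.size)
            native = set(rng.choice(pool, size=k, replace=False))
            if rng.random() < 0.15 and all_countries.size > len(native):
                extra = rng.choice(all_countries, size=1)[0]
                native.add(extra)
            extinct: set = set()
            if len(native) > 1 and rng.random() < 0.05:
                extinct = {sorted(native)[0]}
                native -= extinct
            outside = np.array(sorted(set(all_countries) - native - extinct))
            introduced: set = set()
            if outside.size and rng.random() < 0.08:
                introduced = set(rng.choice(
                    outside, size=min(2, outside.size), replace=False))
            rows.append({
                "accepted_name": name,
                "class": cls,
                "order": f"{cls}-order-{fam_order[fam]}",
                "family": fam_names[fam],
                "genus": genus,
                "iucn_category": rng.choice(_IUCN, p=_IUCN_P),
                "native_extant": ";".join(sorted(native)),
                "native_possibly_extant": "",
                "extinct": ";".join(sorted(extinct)),
                "possibly_extinct": "",
                "introduced": ";".join(sorted(introduced)),
            })
            key_rows.append({"key_string": name, "key_type": "scientific",
                             "language": "la", "accepted_name": name})
            # synonyms: alternative genus placements of the same epithet
            for _ in range(int(rng.poisson(0.8))):
                alt_fam = int(rng.integers(0, n_fam))
                alt_genus = fam_genera[alt_fam][
                    int(rng.integers(0, len(fam_genera[alt_fam])))]
                syn = f"{alt_genus} {epithets[i]}"
                if syn != name and syn not in taken_names:
                    taken_names.add(syn)
                    key_rows.append({"key_string": syn, "key_type": "synonym",
                                     "language": "la", "accepted_name": name})
            if rng.random() < 0.5:
                common = " ".join(w.capitalize() for w in
                                  _unique_words(rng, 2, 2, 4, taken_words))
                key_rows.append({"key_string": common, "key_type": "common",
                                 "language": "en", "accepted_name": name})
    species = pd.DataFrame(rows)
    keys = pd.DataFrame(key_rows)
    _ = syn_rate  # synonym *use* happens at trade generation
    return species, keys


def _typo(name: str, known: set, rng) -> str:
    """Perturb a name so it resolves to nothing."""
    chars = list(name)
    i = int(rng.integers(0, len(chars) - 1))
    chars[i], chars[i + 1] = chars[i + 1], chars[i]
    cand = "".join(chars)
    if cand.lower() in known or cand == name:
        cand = name + "9"  # digit guarantees no key matches
    return cand


def _junk_text(rng, tag: int) -> str:
    """Listing text guaranteed to contain no name key (digits break letter runs)."""
    toks = [f"{w[:3]}{int(rng.integers(0, 10))}{w[:2]}"
            for w in rng.choice(_FILLER, size=int(rng.integers(3, 7)))]
    return " ".join(toks) + f" lot{tag}"


def generate_trade(config: SimConfig, world: pd.DataFrame,
                   species: pd.DataFrame, keys: pd.DataFrame):
    """Raw per-source trade tables plus the generator ledger.

    Source membership is drawn without replacement with shared popularity
    weights ``exp(overlap_control * g)``, ``g ~ N(0,1)``, so the
    concentration parameter controls how much the four sources agree; the
    zoo source samples only non-threatened species.  Every member species
    carries its full trading plan (1 + Poisson distinct countries, each
    alien with probability ``p_alien_trade``) into each source that lists
    it.  Planted noise and QC violations are appended as extra rows and
    ledgered.
    """
    rng = substream(config.seed, "trade")
    pool = species["accepted_name"].to_numpy()
    n_pool = pool.size
    threatened = species["iucn_category"].isin(THREATENED_CATEGORIES).to_numpy()
    tradeable = np.arange(n_pool)
    if config.n_tradeable is not None and config.n_tradeable < n_pool:
        tradeable = np.sort(rng.choice(n_pool, size=config.n_tradeable,
                                       replace=False))
    g = rng.normal(0.0, 1.0, n_pool)
    w = np.exp(config.overlap_control * g)

    members: dict[str, np.ndarray] = {}
    for src, m in config.source_marginals.items():
        if src == "ISIS":
            cand = tradeable[~threatened[tradeable]]
        else:
            cand = tradeable
        if m > cand.size:
            raise ValueError(f"source marginal {src}={m} exceeds eligible pool "
                             f"{cand.size}")
        p = w[cand] / w[cand].sum()
        members[src] = cand[rng.choice(cand.size, size=m, replace=False, p=p)]

    from .classify import native_ranges

    traded_idx = sorted(set(np.concatenate(list(members.values()))))
    native_sets = {n: set(r) for n, r in
                   native_ranges(species.iloc[traded_idx]).items()}

    countries = world["country"].to_numpy()
    cindex = {c: i for i, c in enumerate(countries)}
    import_w = world["trade_value"].to_numpy() ** config.import_weight_exponent

    plan_rows = []
    plans: dict[str, list[tuple[str, bool]]] = {}
    for idx in traded_idx:
        name = pool[idx]
        nat = native_sets[name]
        nat_arr = np.array(sorted(nat & set(countries)))
        non_native = np.array([c for c in countries if c not in nat])
        k = 1 + int(rng.poisson(config.trade_countries_mean_extra))
        n_alien = int(rng.binomial(k, config.p_alien_trade))
        n_native = k - n_alien
        n_alien = min(n_alien, non_native.size)
        n_native = min(n_native, nat_arr.size)
        if n_alien + n_native == 0:
            n_alien = min(1, non_native.size)
        picks: list[tuple[str, bool]] = []
        if n_alien:
            pw = import_w[[cindex[c] for c in non_native]]
            chosen = rng.choice(non_native, size=n_alien, replace=False,
                                p=pw / pw.sum())
            picks += [(c, True) for c in chosen]
        if n_native:
            chosen = rng.choice(nat_arr, size=n_native, replace=False)
            picks += [(c, False) for c in chosen]
        plans[name] = picks
        for c, alien in picks:
            plan_rows.append({"accepted_name": name, "country": c,
                              "is_alien": alien})

    syn_by_species: dict[str, list[str]] = {}
    for ks, kt, acc in zip(keys["key_string"], keys["key_type"],
                           keys["accepted_name"]):
        if kt != "scientific":
            syn_by_species.setdefault(acc, []).append(ks)

    syn_rate = config.noise["synonym_rate"]
    tables: dict[str, list[dict]] = {s: [] for s in config.source_marginals}
    for src, midx in members.items():
        for idx in midx:
            name = pool[idx]
            nat_arr = np.array(sorted(native_sets[name] & set(countries)))
            for c, alien in plans[name]:
                syns = syn_by_species.get(name, [])
                use_syn = syns and rng.random() < syn_rate
                label = syns[int(rng.integers(0, len(syns)))] if use_syn else name
                year = int(rng.integers(2000, 2022))
                if src in ("CITES", "LEMIS"):
                    if alien and nat_arr.size:
                        exporter = str(rng.choice(nat_arr))
                    else:
                        exporter = str(rng.choice(countries))
                    if exporter == c:
                        exporter = str(countries[(cindex[c] + 1) % len(countries)])
                    tables[src].append({"source": src, "name": label,
                                        "country": c, "exporter": exporter,
                                        "term": "live", "year": year})
                elif src == "ISIS":
                    tables[src].append({"source": src, "name": label,
                                        "country": c, "exporter": None,
                                        "term": None, "year": year})
                else:  # OTAPS free-text listing
                    pre = " ".join(rng.choice(_FILLER,
                                              size=int(rng.integers(1, 4))))
                    post = " ".join(rng.choice(_FILLER,
                                               size=int(rng.integers(1, 4))))
                    tables[src].append({"source": src,
                                        "name": f"{pre} {label} {post}",
                                        "country": c, "exporter": None,
                                        "term": None, "year": year})

    ledger = {
        "members": {s: sorted(pool[i] for i in m) for s, m in members.items()},
        "plan": pd.DataFrame(plan_rows),
        "noise_counts": {},
    }

    # --- planted noise and QC violations (all extra rows) ------------------
    # Snapshots of the pristine base rows: planted rows must never be built
    # on top of other planted rows, or the per-rule removal counts would
    # stop reconciling with the cleaning report.
    known_keys = set(keys["key_string"].str.lower())
    trans_rows = tables["CITES"] + tables["LEMIS"]
    base_all = [r for s in config.source_marginals for r in tables[s]]
    n_typo = int(round(config.noise["typo_rate"] * len(trans_rows)))
    typo_pick = rng.choice(len(trans_rows), size=min(n_typo, len(trans_rows)),
                           replace=False)
    for j in typo_pick:
        r = dict(trans_rows[j])
        r["name"] = _typo(r["name"], known_keys, rng)
        tables[r["source"]].append(r)
    ledger["noise_counts"]["typo"] = len(typo_pick)

    n_junk = int(round(config.noise["junk_listing_rate"] * len(tables["OTAPS"])))
    base_otaps = list(tables["OTAPS"])
    for j in range(n_junk):
        proto = base_otaps[int(rng.integers(0, len(base_otaps)))] if base_otaps \
            else {"country": str(rng.choice(countries)), "year": 2015}
        tables["OTAPS"].append({"source": "OTAPS", "name": _junk_text(rng, j),
                                "country": proto["country"], "exporter": None,
                                "term": None, "year": proto["year"]})
    ledger["noise_counts"]["junk_listing"] = n_junk

    qc = config.qc_planted

    def _sample_trans(count):
        count = min(count, len(trans_rows))
        return [dict(trans_rows[j]) for j in
                rng.choice(len(trans_rows), size=count, replace=False)]

    for r in _sample_trans(qc.get("non_live_term", 0)):
        r["term"] = "bodies"
        tables[r["source"]].append(r)
    ledger["noise_counts"]["non_live_term"] = min(qc.get("non_live_term", 0),
                                                  len(trans_rows))

    n_dup = min(qc.get("duplicate_lines", 0), len(base_all))
    for j in rng.choice(len(base_all), size=n_dup, replace=False):
        tables[base_all[j]["source"]].append(dict(base_all[j]))
    ledger["noise_counts"]["duplicate_lines"] = n_dup

    for r in _sample_trans(qc.get("same_importer_exporter", 0)):
        r["exporter"] = r["country"]
        tables[r["source"]].append(r)
    ledger["noise_counts"]["same_importer_exporter"] = min(
        qc.get("same_importer_exporter", 0), len(trans_rows))

    for r in _sample_trans(qc.get("missing_name", 0)):
        r["name"] = ""
        tables[r["source"]].append(r)
    ledger["noise_counts"]["missing_name"] = min(qc.get("missing_name", 0),
                                                 len(trans_rows))

    genera = species["genus"].to_numpy()
    for r in _sample_trans(qc.get("genus_only", 0)):
        r["name"] = f"{rng.choice(genera)} sp."
        tables[r["source"]].append(r)
    ledger["noise_counts"]["genus_only"] = min(qc.get("genus_only", 0),
                                               len(trans_rows))

    for r in _sample_trans(qc.get("hybrid", 0)):
        r["name"] = f"{rng.choice(genera)} hybrid"
        tables[r["source"]].append(r)
    ledger["noise_counts"]["hybrid"] = min(qc.get("hybrid", 0), len(trans_rows))

    n_thr = qc.get("isis_threatened_rows", 0)
    thr_idx = np.where(threatened)[0]
    planted_thr = 0
    if n_thr and thr_idx.size:
        seen = set()
        while planted_thr < n_thr:
            sp = pool[int(rng.choice(thr_idx))]
            c = str(rng.choice(countries))
            if (sp, c) in seen:
                continue
            seen.add((sp, c))
            tables["ISIS"].append({"source": "ISIS", "name": sp, "country": c,
                                   "exporter": None, "term": None,
                                   "year": int(rng.integers(2000, 2022))})
            planted_thr += 1
    ledger["noise_counts"]["isis_threatened_rows"] = planted_thr

    raw = {s: pd.DataFrame(tables[s]) for s in config.source_marginals}
    return raw, ledger


def generate_establishment(config: SimConfig, world: pd.DataFrame,
                           species: pd.DataFrame, classified: pd.DataFrame):
    """Establishment records plus the truth ledger.

    Species-level: every species with at least one alien trade record is
    flagged established with probability ``logit^-1(a + b * n_countries)``;
    a small rate of never-traded species is flagged too (non-trade
    pathways).  Country-level: per class, target establishment richness is
    drawn from the log-linear country model with realm random intercepts
    and realized by sampling flagged species among that country's traded
    aliens (breadth-weighted); every flagged traded species keeps at least
    one establishment country.
    """
    from .classify import country_richness
    from .inference import transform_predictors

    rng = substream(config.seed, "establishment")
    a = config.establishment_logit["intercept"]
    b = config.establishment_logit["slope"]

    pairs = classified.drop_duplicates(["accepted_name", "country"])
    breadth = pairs.groupby("accepted_name")["country"].nunique()
    alien_pairs = classified.loc[classified["label"] == "alien",
                                 ["accepted_name", "country", "class"]
                                 ].drop_duplicates()
    alien_species = alien_pairs["accepted_name"].unique()
    p_est = expit(a + b * breadth.reindex(alien_species).to_numpy())
    flags = rng.random(alien_species.size) < p_est
    flagged = set(alien_species[flags])

    traded = set(classified["accepted_name"])
    untraded = species.loc[~species["accepted_name"].isin(traded)]
    unt_flags = rng.random(len(untraded)) < config.p_establish_untraded
    unt_established = untraded.loc[unt_flags]

    # Country-level targets from the log-linear model (all income classes,
    # standardization over the full country set).
    summary = country_richness(classified).merge(world, on="country")
    beta = np.array([config.country_model["beta"][p] for p in PREDICTORS])
    realm_sd = config.country_model["realm_sd"]
    resid_sd = config.country_model["residual_sd"]
    intercept = config.country_model["intercept"]
    classes = sorted(set(classified["class"].dropna()))
    realms = sorted(set(world["realm"]))

    rec_rows: list[dict] = []
    realm_effects: dict[str, dict[str, float]] = {}
    for cls in classes:
        design = transform_predictors(
            summary, cls,
            income_filter=tuple(sorted(set(world["income_class"]))))
        X = design[list(PREDICTORS)].to_numpy(dtype=float)
        u = {r: rng.normal(0.0, realm_sd) for r in realms}
        realm_effects[cls] = u
        eps = rng.normal(0.0, resid_sd, len(design))
        mu = intercept + X @ beta + np.array(
            [u[r] for r in design["realm"]]) + eps
        targets = np.maximum(0, np.rint(np.expm1(mu))).astype(int)

        sub = alien_pairs[alien_pairs["class"] == cls]
        sub = sub[sub["accepted_name"].isin(flagged)]
        by_country = {c: g["accepted_name"].to_numpy()
                      for c, g in sub.groupby("country")}
        assigned: set[tuple[str, str]] = set()
        for c, t in zip(design["country"], targets):
            cands = by_country.get(c)
            if cands is None or t == 0:
                continue
            bw = breadth.reindex(cands).to_numpy(dtype=float)
            take = min(int(t), cands.size)
            chosen = rng.choice(cands, size=take, replace=False,
                                p=bw / bw.sum())
            for spn in chosen:
                assigned.add((spn, c))
        # guarantee every flagged species of this class establishes somewhere
        covered = {spn for spn, _ in assigned}
        for spn in sub["accepted_name"].unique():
            if spn not in covered:
                opts = sub.loc[sub["accepted_name"] == spn, "country"].to_numpy()
                assigned.add((spn, str(rng.choice(opts))))
        rec_rows += [{"accepted_name": spn, "country": c} for spn, c in assigned]

    # never-traded established species: 1-2 countries outside the native range
    all_countries = world["country"].to_numpy()
    for _, row in unt_established.iterrows():
        nat = set(filter(None, row["native_extant"].split(";")))
        outside = np.array([c for c in all_countries if c not in nat])
        if not outside.size:
            continue
        for c in rng.choice(outside, size=min(int(rng.integers(1, 3)),
                                              outside.size), replace=False):
            rec_rows.append({"accepted_name": row["accepted_name"],
                             "country": str(c)})

    records = pd.DataFrame(rec_rows).drop_duplicates().reset_index(drop=True)
    truth = {
        "establishment_logit": {"intercept": a, "slope": b},
        "country_model": {
            "intercept": intercept,
            "beta": dict(config.country_model["beta"]),
            "realm_sd": realm_sd,
            "residual_sd": resid_sd,
        },
        "p_establish_untraded": config.p_establish_untraded,
        "n_alien_species": int(alien_species.size),
        "n_flagged_traded": int(len(flagged)),
        "n_flagged_untraded": int(len(unt_established)),
        "realized_prevalence": float(len(flagged) / alien_species.size)
        if alien_species.size else None,
        "flagged_traded": sorted(flagged),
        "flagged_untraded": sorted(unt_established["accepted_name"]),
    }
    return records, truth


def simulate_country_response(n: int, beta: dict, intercept: float,
                              realm_sd: float, residual_sd: float,
                              rng: np.random.Generator,
                              n_realms: int = 7):
    """Direct draw from the country-level linear mixed model.

    Continuous predictors are standard normal, insularity is Bernoulli(0.3);
    returns a design frame (with ``realm`` labels) and the response vector.
    Used for parameter-recovery and variance-partition checks without
    running the full trade pipeline.
    """
    names = list(beta)
    X = rng.normal(0.0, 1.0, (n, len(names)))
    if "insularity" in names:
        j = names.index("insularity")
        X[:, j] = (rng.random(n) < 0.3).astype(float)
    realms = rng.integers(0, n_realms, n)
    u = rng.normal(0.0, realm_sd, n_realms)
    y = (intercept + X @ np.array([beta[p] for p in names])
         + u[realms] + rng.normal(0.0, residual_sd, n))
    design = pd.DataFrame(X, columns=names)
    design["realm"] = [f"realm{r}" for r in realms]
    return design, y


def generate_all(config: SimConfig):
    """Convenience wrapper: world, species, keys, raw trade, ledger."""
    world = generate_world(config)
    species, keys = generate_species(config, world)
    raw, ledger = generate_trade(config, world, species, keys)
    return world, species, keys, raw, ledger
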