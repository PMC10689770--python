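"""Shared fixtures: a small synthetic world and its harmonized artifacts."""

from __future__ import annotations

import pandas as pd
import pytest

from colpress.classify import classify_records
from colpress.config import SimConfig
from colpress.harmonize import (NameKey, build_key_index, clean_trade_records,
                                exclude_isis_threatened)
from colpress.synthetic import generate_all


def small_config(seed: int = 11, **over) -> SimConfig:
    base = dict(
        seed=seed,
        n_countries=40,
        n_species_per_class={"mammal": 120, "bird": 200, "reptile": 150,
                             "amphibian": 80},
        n_tradeable=None,
        source_marginals={"CITES": 80, "LEMIS": 120, "ISIS": 100, "OTAPS": 160},
        qc_planted={"non_live_term": 10, "duplicate_lines": 12,
                    "same_importer_exporter": 8, "missing_name": 6,
                    "genus_only": 5, "hybrid": 4, "isis_threatened_rows": 7},
    )
    base.update(over)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_world():
    cfg = small_config()
    world, species, keys, raw, ledger = generate_all(cfg)
    return {"config": cfg, "world": world, "species": species, "keys": keys,
            "raw": raw, "ledger": ledger}


@pytest.fixture(scope="session")
def small_index(small_world):
    k = small_world["keys"]
    return build_key_index(
        NameKey(key_string=s, accepted_name=a, key_type=t)
        for s, t, a in zip(k["key_string"], k["key_type"], k["accepted_name"]))


@pytest.fixture(scope="session")
def small_clean(small_world, small_index):
    raw_all = pd.concat(small_world["raw"].values(), ignore_index=True)
    clean, report = clean_trade_records(
        raw_all, small_index, countries=set(small_world["world"]["country"]))
    clean = exclude_isis_threatened(clean, small_world["species"])
    return clean, report


@pytest.fixture(scope="session")
def small_classified(small_world, small_clean):
    clean, _ = small_clean
    return classify_records(clean, small_world["species"])
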