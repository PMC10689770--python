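"""The synthetic-data generators: determinism, planted-truth conservation,
and the generative models for establishment."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from colpress.config import DEFAULT_REALMS, SimConfig
from colpress.flows import DEFAULT_REGIONS
from colpress.synthetic import (generate_establishment, generate_species,
                                generate_trade, generate_world)
from conftest import small_config


class TestWorld:
    def test_same_seed_twice_is_byte_identical(self):
        cfg = small_config(seed=5)
        a = generate_world(cfg).to_csv(index=False)
        b = generate_world(small_config(seed=5)).to_csv(index=False)
        assert a == b

    def test_row_count_honors_config(self):
        cfg = small_config(n_countries=100)
        assert len(generate_world(cfg)) == 100

    def test_default_realms_and_regions_all_present(self):
        world = generate_world(SimConfig(seed=0))
        assert set(world["realm"]) == set(DEFAULT_REALMS)
        assert set(world["region"]) == set(DEFAULT_REGIONS)

    def test_income_classes_are_gdp_per_capita_quartiles(self):
        world = generate_world(small_config())
        gdp_pc = world["gdp"] / world["population"]
        order = ["low", "lower-middle", "upper-middle", "high"]
        med = {c: gdp_pc[world["income_class"] == c].median() for c in order}
        assert med["low"] < med["lower-middle"] < med["upper-middle"] < med["high"]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            small_config(n_countries=-1)
        with pytest.raises(ValueError):
            small_config(realm_names=("A", "A"))


class TestSpecies:
    def test_counts_honor_config(self, small_world):
        species = small_world["species"]
        for cls, n in small_world["config"].n_species_per_class.items():
            assert (species["class"] == cls).sum() == n

    def test_native_and_introduced_disjoint(self, small_world):
        for _, row in small_world["species"].iterrows():
            nat = set(filter(None, row["native_extant"].split(";")))
            nat |= set(filter(None, row["extinct"].split(";")))
            intro = set(filter(None, row["introduced"].split(";")))
            assert not nat & intro

    def test_every_key_maps_to_exactly_one_accepted_name(self, small_world):
        keys = small_world["keys"]
        assert not keys["key_string"].str.lower().duplicated().any()

    def test_no_species_has_empty_native_range(self, small_world):
        assert (small_world["species"]["native_extant"].str.len() > 0).all()

    def test_empty_world_rejected(self):
        cfg = small_config()
        world = generate_world(cfg).iloc[:0]
        with pytest.raises(ValueError, match="empty"):
            generate_species(cfg, world)


class TestTrade:
    def test_marginals_realized_exactly(self, small_world, small_clean):
        clean, _ = small_clean
        for src, target in small_world["config"].source_marginals.items():
            assert clean.loc[clean["source"] == src,
                             "accepted_name"].nunique() == target

    def test_determinism(self):
        cfg = small_config(seed=6)
        w = generate_world(cfg)
        s, k = generate_species(cfg, w)
        raw1, _ = generate_trade(cfg, w, s, k)
        raw2, _ = generate_trade(cfg, w, s, k)
        for src in raw1:
            assert raw1[src].to_csv(index=False) == raw2[src].to_csv(index=False)

    def test_oversized_marginal_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            small_config(source_marginals={"CITES": 10**6, "LEMIS": 1,
                                           "ISIS": 1, "OTAPS": 1})

    def test_noise_off_every_listing_contains_its_planted_key(
            self, small_index):
        """With junk rate zero, extraction recovers a key from every
        online-listing text and it resolves to the planned species."""
        from colpress.harmonize import extract_name, resolve_accepted

        cfg = small_config(
            seed=12,
            noise={"synonym_rate": 0.2, "typo_rate": 0.0,
                   "junk_listing_rate": 0.0},
            qc_planted={})
        w = generate_world(cfg)
        s, k = generate_species(cfg, w)
        raw, ledger = generate_trade(cfg, w, s, k)
        from colpress.harmonize import NameKey, build_key_index
        idx = build_key_index(
            NameKey(key_string=ks, accepted_name=a, key_type=t)
            for ks, t, a in zip(k["key_string"], k["key_type"],
                                k["accepted_name"]))
        plan_pairs = set(zip(ledger["plan"]["accepted_name"],
                             ledger["plan"]["country"]))
        for _, row in raw["OTAPS"].iterrows():
            key = extract_name(row["name"], idx)
            assert key is not None, row["name"]
            acc = resolve_accepted(key, idx)
            assert (acc, row["country"]) in plan_pairs

    def test_planted_qc_violations_recoverable(self, small_world, small_clean):
        _, report = small_clean
        nc = small_world["ledger"]["noise_counts"]
        assert report["non_live_term"] == nc["non_live_term"]
        assert report["duplicate_lines"] == nc["duplicate_lines"]
        assert report["same_importer_exporter"] == nc["same_importer_exporter"]
        assert report["missing_name"] == nc["missing_name"]
        assert report["genus_only"] == nc["genus_only"]
        assert report["hybrid"] == nc["hybrid"]
        assert report["unresolved_name"] == nc["typo"] + nc["junk_listing"]

    def test_isis_threatened_rows_recoverable(self, small_world, small_index):
        from colpress.harmonize import (clean_trade_records,
                                        exclude_isis_threatened)

        raw_all = pd.concat(small_world["raw"].values(), ignore_index=True)
        clean, _ = clean_trade_records(
            raw_all, small_index,
            countries=set(small_world["world"]["country"]))
        after = exclude_isis_threatened(clean, small_world["species"])
        removed = len(clean) - len(after)
        assert removed == small_world["ledger"]["noise_counts"][
            "isis_threatened_rows"]


class TestEstablishment:
    def test_zero_slope_prevalence_matches_intercept(self, small_world,
                                                     small_classified):
        """b = 0: realized establishment rate within 3 binomial standard
        errors of logit^-1(a)."""
        cfg = small_config(
            establishment_logit={"intercept": -1.0, "slope": 0.0},
            p_establish_untraded=0.0)
        _, truth = generate_establishment(cfg, small_world["world"],
                                          small_world["species"],
                                          small_classified)
        p = expit(-1.0)
        n = truth["n_alien_species"]
        se = np.sqrt(p * (1 - p) / n)
        assert abs(truth["realized_prevalence"] - p) <= 3 * se

    def test_truth_ledger_round_trips_config(self, small_world,
                                             small_classified):
        cfg = small_world["config"]
        _, truth = generate_establishment(cfg, small_world["world"],
                                          small_world["species"],
                                          small_classified)
        assert truth["establishment_logit"] == cfg.establishment_logit
        assert truth["country_model"]["beta"] == cfg.country_model["beta"]
        assert truth["p_establish_untraded"] == cfg.p_establish_untraded

    def test_established_records_are_flagged_species(self, small_world,
                                                     small_classified):
        records, truth = generate_establishment(
            small_world["config"], small_world["world"],
            small_world["species"], small_classified)
        flagged = set(truth["flagged_traded"]) | set(truth["flagged_untraded"])
        assert set(records["accepted_name"]) <= flagged


class TestConfigIO:
    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config(seed=42)
        path = tmp_path / "config.yaml"
        cfg.to_yaml(path)
        back = SimConfig.from_yaml(path)
        assert back == cfg
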