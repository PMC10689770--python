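"""Predictor transforms, the 2^p model set, conditional averaging, and the
companion univariate / paired / correlation analyses."""

import numpy as np
import pandas as pd
import pytest

from colpress.inference import (PREDICTORS, akaike_weights,
                                conditional_average, cross_taxa_correlation,
                                enumerate_and_fit, paired_compare, top_models,
                                transform_predictors,
                                univariate_socioeconomic)
from colpress.mixed import fit_lmm_ml


def country_frame(n=30, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "country": [f"C{i}" for i in range(n)],
        "realm": rng.choice(["r1", "r2", "r3"], n),
        "income_class": rng.choice(["upper-middle", "high"], n),
        "insularity": rng.integers(0, 2, n),
        "area_km2": np.exp(rng.normal(11, 1, n)),
        "population": np.exp(rng.normal(15, 1, n)),
        "gdp": np.exp(rng.normal(24, 1, n)),
        "trade_value": np.exp(rng.normal(23, 1, n)),
        "mean_temperature_c": rng.normal(15, 8, n),
        "mean_precipitation_mm": np.exp(rng.normal(6.5, 0.5, n)),
        "sampling_effort": rng.uniform(0.05, 0.4, n),
        "alien_bird": rng.integers(0, 60, n),
        "established_bird": rng.integers(0, 8, n),
        "congeneric_bird": rng.integers(0, 40, n),
        "alien_total": rng.integers(1, 80, n),
    })
    return df


class TestTransform:
    def test_zero_establishment_maps_to_zero_response(self):
        df = country_frame()
        df["established_bird"] = 0
        out = transform_predictors(df, "bird")
        assert np.allclose(out["log1p_establishment"], 0.0)

    def test_nonpositive_area_is_an_error_naming_the_row(self):
        df = country_frame()
        df.loc[3, "area_km2"] = 0.0
        with pytest.raises(ValueError, match="C3"):
            transform_predictors(df, "bird")

    def test_standardized_columns_have_mean_zero_sd_one(self):
        out = transform_predictors(country_frame(), "bird")
        for col in PREDICTORS:
            if col == "insularity":
                assert set(out[col].unique()) <= {0.0, 1.0}
                continue
            assert out[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert out[col].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_income_filter_restricts_rows(self):
        df = country_frame()
        df.loc[:4, "income_class"] = "low"
        out = transform_predictors(df, "bird")
        assert len(out) == (df["income_class"]
                            .isin(["upper-middle", "high"]).sum())


class TestModelSet:
    def small_design(self, p=2, n=60, seed=1):
        rng = np.random.default_rng(seed)
        d = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=list(PREDICTORS[:p]))
        d["realm"] = rng.choice(["a", "b", "c"], n)
        d["log1p_establishment"] = (
            0.5 * d[PREDICTORS[0]] + rng.normal(0, 0.5, n))
        return d

    def test_two_predictors_give_four_models(self):
        ms = enumerate_and_fit(self.small_design(2), predictors=PREDICTORS[:2])
        assert len(ms.models) == 4

    def test_zero_predictors_give_intercept_only(self):
        ms = enumerate_and_fit(self.small_design(1), predictors=())
        assert len(ms.models) == 1 and ms.models[0].subset == ()

    def test_weights_sum_to_one_and_min_delta_zero(self):
        ms = enumerate_and_fit(self.small_design(3), predictors=PREDICTORS[:3])
        w = np.array([m.weight for m in ms.models])
        d = np.array([m.delta for m in ms.models])
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert d.min() == 0.0

    def test_known_delta_weights(self):
        ms = enumerate_and_fit(self.small_design(1), predictors=PREDICTORS[:1])
        # overwrite AICc to the canonical two-model example
        ms.models[0].aicc, ms.models[1].aicc = 100.0, 102.0
        akaike_weights(ms)
        assert ms.models[0].weight == pytest.approx(0.7311, abs=1e-4)
        assert ms.models[1].weight == pytest.approx(0.2689, abs=1e-4)

    def test_top_models_threshold_inclusive(self):
        ms = enumerate_and_fit(self.small_design(2), predictors=PREDICTORS[:2])
        base = min(m.aicc for m in ms.models)
        for m, d in zip(ms.models, [0.0, 1.9, 2.0, 2.1]):
            m.aicc = base + d
        akaike_weights(ms)
        assert len(top_models(ms)) == 3

    def test_full_model_aicc_consistent(self):
        from colpress.mixed import aicc as aicc_fn
        ms = enumerate_and_fit(self.small_design(3), predictors=PREDICTORS[:3])
        full = [m for m in ms.models if len(m.subset) == 3][0]
        assert full.aicc == pytest.approx(
            aicc_fn(full.fit.loglik, full.fit.k, full.fit.n), abs=1e-10)


class TestConditionalAverage:
    def test_single_model_case(self):
        ms = TestModelSet().small_design(1, seed=2)
        out = enumerate_and_fit(ms, predictors=PREDICTORS[:1])
        coefs = {c.predictor: c for c in conditional_average(out)}
        member = [m for m in out.models if m.subset][0]
        c = coefs[PREDICTORS[0]]
        assert c.estimate == pytest.approx(
            member.fit.beta[1], abs=1e-12)
        assert c.se >= member.fit.se[1] - 1e-12

    def test_hand_computed_three_model_average(self):
        """SE formula sum w_i sqrt(var_i + (b_i - bbar)^2) on a synthetic
        three-model set with forced weights."""
        ms = enumerate_and_fit(TestModelSet().small_design(2, seed=3),
                               predictors=PREDICTORS[:2])
        members = [m for m in ms.models if PREDICTORS[0] in m.subset]
        w = np.array([m.weight for m in members])
        w = w / w.sum()
        est = np.array([m.fit.beta[m.fit.names.index(PREDICTORS[0])]
                        for m in members])
        var = np.array([m.fit.cov_beta[i, i]
                        for m, i in ((m, m.fit.names.index(PREDICTORS[0]))
                                     for m in members)])
        bbar = w @ est
        se = w @ np.sqrt(var + (est - bbar) ** 2)
        got = {c.predictor: c for c in conditional_average(ms)}[PREDICTORS[0]]
        assert got.estimate == pytest.approx(bbar, abs=1e-12)
        assert got.se == pytest.approx(se, abs=1e-12)

    def test_degenerates_to_full_model_when_it_has_all_weight(self):
        ms = enumerate_and_fit(TestModelSet().small_design(2, seed=4),
                               predictors=PREDICTORS[:2])
        full = [m for m in ms.models if len(m.subset) == 2][0]
        for m in ms.models:
            m.weight = 1.0 if m is full else 0.0
        coefs = {c.predictor: c for c in conditional_average(ms)}
        for j, p in enumerate(PREDICTORS[:2], start=1):
            assert coefs[p].estimate == pytest.approx(full.fit.beta[j],
                                                      abs=1e-12)


class TestUnivariate:
    def test_noiseless_log_linear_relation(self):
        n = 80
        rng = np.random.default_rng(9)
        df = country_frame(n, seed=9)
        df["trade_value"] = np.exp(rng.normal(23, 1, n))
        df["alien_total"] = np.expm1(2.0 * np.log(df["trade_value"]) - 44.0)
        out = univariate_socioeconomic(df, "trade_value")
        assert out["slope"] > 0
        assert out["r2m"] > 0.99

    def test_permuted_predictor_is_null(self):
        """Shuffling the factor should leave nothing to detect in ~all
        replicates."""
        hits, reps = 0, 20
        base = country_frame(60, seed=10)
        base["alien_total"] = np.expm1(
            0.8 * np.log(base["trade_value"]) - 17.0
            + np.random.default_rng(0).normal(0, 0.5, len(base))).clip(0)
        for r in range(reps):
            rng = np.random.default_rng(200 + r)
            df = base.copy()
            df["trade_value"] = rng.permutation(df["trade_value"].to_numpy())
            out = univariate_socioeconomic(df, "trade_value")
            if out["p"] > 0.05:
                hits += 1
        assert hits >= 0.9 * reps


class TestPairedAndCorrelation:
    def test_identical_vectors(self):
        out = paired_compare([1, 2, 3], [1, 2, 3])
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_constant_nonzero_difference_is_degenerate(self):
        out = paired_compare([2, 3, 4], [1, 2, 3])
        assert out["degenerate"] and np.isnan(out["t"])

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(11)
        a = rng.normal(5, 1, 25)
        b = rng.normal(4.5, 1, 25)
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        out = paired_compare(a, b)
        assert out["t"] == pytest.approx(t_hand, abs=1e-10)

    def test_identical_columns_correlate_perfectly(self):
        df = pd.DataFrame({f"alien_{c}": [1, 2, 3, 4]
                           for c in ["mammal", "bird", "reptile", "amphibian"]})
        r = cross_taxa_correlation(df)
        assert np.allclose(r.to_numpy(), 1.0)

    def test_negated_column(self):
        df = pd.DataFrame({
            "alien_mammal": [1, 2, 3, 4], "alien_bird": [-1, -2, -3, -4],
            "alien_reptile": [1, 2, 3, 4], "alien_amphibian": [1, 2, 3, 4]})
        r = cross_taxa_correlation(df)
        assert r.loc["mammal", "bird"] == pytest.approx(-1.0)

    def test_shared_latent_factor_gives_positive_correlations(self):
        rng = np.random.default_rng(12)
        latent = rng.normal(0, 1, 200)
        df = pd.DataFrame({
            f"alien_{c}": latent + rng.normal(0, 0.5, 200)
            for c in ["mammal", "bird", "reptile", "amphibian"]})
        r = cross_taxa_correlation(df).to_numpy()
        assert (r > 0).all()


class TestLmmVsModelSetIntegration:
    def test_enumeration_contains_the_full_model_fit(self):
        d = TestModelSet().small_design(3, seed=5)
        ms = enumerate_and_fit(d, predictors=PREDICTORS[:3])
        full = [m for m in ms.models if len(m.subset) == 3][0]
        X = np.column_stack([np.ones(len(d))]
                            + [d[p].to_numpy() for p in PREDICTORS[:3]])
        direct = fit_lmm_ml(d["log1p_establishment"].to_numpy(), X,
                            d["realm"].to_numpy())
        assert np.allclose(full.fit.beta, direct.beta, atol=1e-10)
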