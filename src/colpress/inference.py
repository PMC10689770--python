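"""Multimodel inference for establishment richness across countries.

The statistical core: the response is log(1+x)-transformed establishment
richness of traded alien species per country; the nine candidate predictors
are country area, population density, GDP per capita, colonization pressure
(number of alien species in trade), insularity, annual mean temperature,
annual mean precipitation, congeneric richness and sampling effort
(proportion of undiscovered species).  All 2^9 = 512 fixed-effect subsets
of a linear mixed model with a biogeographic-realm random intercept are
fitted by maximum likelihood, ranked by AICc, and coefficients are
conditionally averaged (over only the models containing a term, with Akaike
weights renormalized within that subset) with unconditional standard
errors; significance is judged by |z| >= 1.96.

Analyses are restricted to countries in configured income classes, because
trade-record sampling is far more complete in upper-middle and high income
countries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .mixed import FitError, LMMFit, aicc, fit_lmm_ml

__all__ = [
    "PREDICTORS", "ModelSet", "AveragedCoefficient",
    "transform_predictors", "enumerate_and_fit", "akaike_weights",
    "conditional_average", "top_models", "univariate_socioeconomic",
    "paired_compare", "cross_taxa_correlation",
]

#: The nine candidate predictors, in reporting order.
PREDICTORS = (
    "area", "population_density", "gdp_pc", "colonization_pressure",
    "insularity", "mean_temperature", "mean_precipitation",
    "congeneric_richness", "sampling_effort",
)

#: Income classes kept in the country-level analyses.
DEFAULT_INCOME_FILTER = ("upper-middle", "high")

_LOG = ("area", "population_density", "gdp_pc", "mean_precipitation")
_LOG1P = ("colonization_pressure", "congeneric_richness")
_BINARY = ("insularity",)


def transform_predictors(summary: pd.DataFrame, taxon: str,
                         income_filter=DEFAULT_INCOME_FILTER,
                         standardize: bool = True) -> pd.DataFrame:
    """Build the analysis design table for one taxonomic class.

    Applies the income-class filter, the log / log(1+x) transforms, and
    z-score standardization of the continuous predictors (insularity stays
    0/1).  Returns a frame with the response column ``log1p_establishment``
    plus the nine predictors, ``realm`` and ``country``.
    """
    df = summary[summary["income_class"].isin(income_filter)].copy()
    if df.empty:
        raise ValueError("income-class filter leaves no rows")
    raw = pd.DataFrame({
        "country": df["country"].to_numpy(),
        "realm": df["realm"].to_numpy(),
        "area": df["area_km2"].to_numpy(dtype=float),
        "population_density": (df["population"] / df["area_km2"]).to_numpy(),
        "gdp_pc": (df["gdp"] / df["population"]).to_numpy(),
        "colonization_pressure": df[f"alien_{taxon}"].to_numpy(dtype=float),
        "insularity": df["insularity"].to_numpy(dtype=float),
        "mean_temperature": df["mean_temperature_c"].to_numpy(dtype=float),
        "mean_precipitation": df["mean_precipitation_mm"].to_numpy(dtype=float),
        "congeneric_richness": df[f"congeneric_{taxon}"].to_numpy(dtype=float),
        "sampling_effort": df["sampling_effort"].to_numpy(dtype=float),
    })
    raw["log1p_establishment"] = np.log1p(df[f"established_{taxon}"].to_numpy(dtype=float))
    for col in _LOG:
        vals = raw[col].to_numpy()
        if np.any(vals <= 0):
            bad = raw.loc[vals <= 0, "country"].tolist()
            raise ValueError(f"log transform of non-positive {col} for {bad}")
        raw[col] = np.log(vals)
    for col in _LOG1P:
        if np.any(raw[col].to_numpy() < 0):
            raise ValueError(f"negative values in {col}")
        raw[col] = np.log1p(raw[col].to_numpy())
    if standardize:
        for col in PREDICTORS:
            if col in _BINARY:
                continue
            v = raw[col].to_numpy()
            sd = v.std(ddof=1)
            if sd == 0:
                raise ValueError(f"predictor {col} is constant; cannot standardize")
            raw[col] = (v - v.mean()) / sd
    return raw


@dataclass
class FittedModel:
    subset: tuple[str, ...]
    fit: LMMFit
    aicc: float
    delta: float = np.nan
    weight: float = np.nan


@dataclass
class ModelSet:
    """All-subsets model enumeration with AICc ranking and Akaike weights."""

    response: str
    predictors: tuple[str, ...]
    models: list[FittedModel]
    failures: list[tuple[tuple[str, ...], str]] = field(default_factory=list)

    def best(self) -> FittedModel:
        return min(self.models, key=lambda m: m.aicc)


@dataclass
class AveragedCoefficient:
    predictor: str
    estimate: float
    se: float

    @property
    def z(self) -> float:
        return self.estimate / self.se if self.se > 0 else np.nan

    @property
    def pvalue(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.z)))

    @property
    def significant(self) -> bool:
        return bool(abs(self.z) >= 1.96)


def enumerate_and_fit(design: pd.DataFrame, response: str = "log1p_establishment",
                      predictors=PREDICTORS, grouping: str = "realm") -> ModelSet:
    """Fit every predictor subset (2^p models, intercept always included)."""
    y = design[response].to_numpy(dtype=float)
    groups = design[grouping].to_numpy()
    n = len(y)
    models: list[FittedModel] = []
    failures: list[tuple[tuple[str, ...], str]] = []
    cols = {p: design[p].to_numpy(dtype=float) for p in predictors}
    for r in range(len(predictors) + 1):
        for subset in combinations(predictors, r):
            X = np.column_stack([np.ones(n)] + [cols[p] for p in subset])
            names = ["intercept", *subset]
            try:
                fit = fit_lmm_ml(y, X, groups, names=names)
                models.append(FittedModel(subset=subset, fit=fit,
                                          aicc=aicc(fit.loglik, fit.k, fit.n)))
            except (FitError, ValueError) as exc:
                failures.append((subset, str(exc)))
    if not models:
        raise FitError("every candidate model failed")
    ms = ModelSet(response=response, predictors=tuple(predictors),
                  models=models, failures=failures)
    akaike_weights(ms)
    return ms


def akaike_weights(model_set: ModelSet) -> np.ndarray:
    """Fill in Delta-AICc and normalized Akaike weights w_i ~ exp(-Delta/2)."""
    a = np.array([m.aicc for m in model_set.models])
    delta = a - a.min()
    w = np.exp(-0.5 * delta)
    w /= w.sum()
    for m, d, wi in zip(model_set.models, delta, w):
        m.delta = float(d)
        m.weight = float(wi)
    return w


def top_models(model_set: ModelSet, threshold: float = 2.0) -> list[FittedModel]:
    """Models with Delta-AICc <= threshold (inclusive), best first."""
    sel = [m for m in model_set.models if m.delta <= threshold]
    return sorted(sel, key=lambda m: m.delta)


def conditional_average(model_set: ModelSet) -> list[AveragedCoefficient]:
    """Conditional model-averaged coefficients with unconditional SEs.

    For each predictor, weights are renormalized over the models containing
    it; the averaged SE folds in between-model spread:
    ``SE = sum_i w_i * sqrt(var_i + (beta_i - beta_bar)^2)``.
    The intercept is averaged over every model.
    """
    out: list[AveragedCoefficient] = []
    for predictor in ("intercept", *model_set.predictors):
        members = [m for m in model_set.models
                   if predictor == "intercept" or predictor in m.subset]
        if not members:
            continue
        w = np.array([m.weight for m in members])
        if w.sum() == 0:
            continue
        w = w / w.sum()
        est = np.array([m.fit.beta[m.fit.names.index(predictor)] for m in members])
        var = np.array([m.fit.cov_beta[m.fit.names.index(predictor),
                                       m.fit.names.index(predictor)]
                        for m in members])
        mean = float(w @ est)
        se = float(w @ np.sqrt(var + (est - mean) ** 2))
        out.append(AveragedCoefficient(predictor=predictor, estimate=mean, se=se))
    return out


def univariate_socioeconomic(summary: pd.DataFrame, factor: str,
                             response: str = "alien_total",
                             income_filter=DEFAULT_INCOME_FILTER) -> dict:
    """One-predictor LMM of log1p(alien richness) on a log socio-economic factor.

    ``factor`` is a raw country column (e.g. ``population``, ``trade_value``,
    or the derived ``gdp_pc``); realm is the random intercept.  Reports the
    slope, its p-value and the marginal R^2 as "variation accounted for".
    """
    df = summary[summary["income_class"].isin(income_filter)]
    if factor == "gdp_pc":
        x = (df["gdp"] / df["population"]).to_numpy(dtype=float)
    else:
        x = df[factor].to_numpy(dtype=float)
    if np.any(x <= 0):
        raise ValueError(f"log transform of non-positive {factor}")
    x = np.log(x)
    y = np.log1p(df[response].to_numpy(dtype=float))
    X = np.column_stack([np.ones(len(y)), x])
    fit = fit_lmm_ml(y, X, df["realm"].to_numpy(), names=["intercept", factor])
    z = fit.beta[1] / fit.se[1]
    return {
        "factor": factor,
        "slope": float(fit.beta[1]),
        "se": float(fit.se[1]),
        "p": float(2.0 * stats.norm.sf(abs(z))),
        "r2m": fit.marginal_r2(),
        "n": fit.n,
    }


def paired_compare(a, b) -> dict:
    """Two-sided paired t test on per-country (a - b) differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two paired vectors of equal length n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):  # identical vectors: no effect, no evidence
            return {"t": 0.0, "p": 1.0, "n": int(a.size),
                    "mean_difference": 0.0, "degenerate": False}
        return {"t": np.nan, "p": np.nan, "n": int(a.size),
                "mean_difference": float(d.mean()),
                "degenerate": True}
    t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "p": float(p), "n": int(a.size),
            "mean_difference": float(d.mean()), "degenerate": False}


def cross_taxa_correlation(summary: pd.DataFrame, prefix: str = "alien",
                           log: bool = False) -> pd.DataFrame:
    """Pearson correlations of per-country richness across the 4 classes.

    Zero-variance columns yield NaN entries (reported, not raised).
    """
    from .classify import CLASSES

    cols = {cls: summary[f"{prefix}_{cls}"].astype(float) for cls in CLASSES}
    df = pd.DataFrame(cols)
    if log:
        df = np.log1p(df)
    return df.corr(method="pearson")
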