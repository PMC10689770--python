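"""Simulation configuration: the study conditions for the synthetic world.

Defaults are set to the conditions of the global live-vertebrate-trade
analysis the package implements: a ~200-country world partitioned into the
7 biogeographic realms and 8 economic regions, an IUCN-scale species pool
(34,285 terrestrial vertebrates across four classes), trade-source marginal
totals matching the four compiled data sources, and establishment generated
from a species-level logistic model on trade breadth plus a country-level
log-linear model with realm random intercepts.  Calibrated rates (alien
record probability, establishment logit, untraded-establishment rate) are
derived in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .flows import DEFAULT_REGIONS
from .inference import PREDICTORS

__all__ = ["SimConfig", "DEFAULT_REALMS", "substream"]

DEFAULT_REALMS = (
    "Afrotropics", "Australasia", "Indo-Malay", "Nearctic",
    "Neotropics", "Palaearctic", "Oceania",
)

_DEFAULT_POOL = {"mammal": 5500, "bird": 11000, "reptile": 10500, "amphibian": 7285}
_DEFAULT_MARGINALS = {"CITES": 2371, "LEMIS": 3908, "ISIS": 3116, "OTAPS": 5053}

# Country-model truth: standardized-scale coefficients over the nine
# predictors (Table-1-like magnitudes), written to the truth ledger.
_DEFAULT_BETA = {
    "area": 0.15,
    "population_density": 0.20,
    "gdp_pc": 0.30,
    "colonization_pressure": 0.35,
    "insularity": 0.25,
    "mean_temperature": 0.00,
    "mean_precipitation": 0.10,
    "congeneric_richness": 0.00,
    "sampling_effort": 0.20,
}

_STAGES = {"world": 1, "species": 2, "trade": 3, "establishment": 4, "misc": 5}


def substream(seed: int, stage: str) -> np.random.Generator:
    """Independent named random substream; adding a stage never perturbs others."""
    return np.random.default_rng([int(seed), _STAGES[stage]])


@dataclass
class SimConfig:
    seed: int = 0
    n_countries: int = 200
    n_species_per_class: dict = field(default_factory=lambda: dict(_DEFAULT_POOL))
    realm_names: tuple = DEFAULT_REALMS
    region_names: tuple = DEFAULT_REGIONS
    source_marginals: dict = field(default_factory=lambda: dict(_DEFAULT_MARGINALS))
    #: size of the tradeable subset of the species pool that sources sample
    #: from (only a minority of extant species ever circulate in trade);
    #: ``None`` means the whole pool is tradeable.
    n_tradeable: int | None = 10700
    #: concentration of the shared species-popularity weights that control
    #: how strongly the four sources pick the same species (0 = independent).
    overlap_control: float = 0.8
    #: distinct trading countries per species is 1 + Poisson(this mean)
    trade_countries_mean_extra: float = 1.75
    #: probability that a planned trade record lies outside the native range
    p_alien_trade: float = 0.595
    #: alien destinations drawn with weight trade_value**exponent
    import_weight_exponent: float = 0.7
    establishment_logit: dict = field(
        default_factory=lambda: {"intercept": -2.425, "slope": 0.15})
    #: establishment rate for never-traded species (other pathways)
    p_establish_untraded: float = 0.0086
    country_model: dict = field(default_factory=lambda: {
        "intercept": 0.5,
        "beta": dict(_DEFAULT_BETA),
        "realm_sd": 0.25,
        "residual_sd": 0.4,
    })
    noise: dict = field(default_factory=lambda: {
        "synonym_rate": 0.15, "typo_rate": 0.01, "junk_listing_rate": 0.05})
    #: planted QC violations, recoverable from the generator ledger
    qc_planted: dict = field(default_factory=lambda: {
        "non_live_term": 200, "duplicate_lines": 300,
        "same_importer_exporter": 150, "missing_name": 100,
        "genus_only": 80, "hybrid": 60, "isis_threatened_rows": 120})

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_countries <= 0:
            raise ValueError("n_countries must be positive")
        if len(set(self.realm_names)) != len(self.realm_names):
            raise ValueError("duplicate realm names")
        if len(set(self.region_names)) != len(self.region_names):
            raise ValueError("duplicate region names")
        for cls, n in self.n_species_per_class.items():
            if n <= 0:
                raise ValueError(f"species count for {cls} must be positive")
        for p in (self.p_alien_trade, self.p_establish_untraded,
                  *self.noise.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        pool = sum(self.n_species_per_class.values())
        if self.n_tradeable is not None:
            pool = min(pool, self.n_tradeable)
        for src, m in self.source_marginals.items():
            if m > pool:
                raise ValueError(
                    f"source marginal {src}={m} exceeds tradeable pool {pool}")
        missing = set(PREDICTORS) - set(self.country_model["beta"])
        if missing:
            raise ValueError(f"country_model beta missing predictors: {missing}")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["realm_names"] = list(self.realm_names)
        d["region_names"] = list(self.region_names)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        if "realm_names" in d:
            d["realm_names"] = tuple(d["realm_names"])
        if "region_names" in d:
            d["region_names"] = tuple(d["region_names"])
        return cls(**d)
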