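# colpress

Quantifying **colonization pressure** from the global live-wildlife trade:
how many terrestrial vertebrate species are traded outside their native
range (and are therefore *aliens in trade*), where, and what drives how many
of them establish self-sustaining populations.

`colpress` is a desk-scale, fully tested implementation of that analysis
pipeline for invasion macroecologists and biodiversity-informatics
developers. It covers:

- **Harmonization** of heterogeneous trade records (CITES-like and
  LEMIS-like transaction logs, zoo inventories, free-text online listings)
  to accepted scientific names, via a key table of synonyms, common and
  trade names. Free-text extraction uses sorted-lookup semantics: among all
  keys occurring as a substring of the listing text, the longest
  (ties broken lexicographically) wins. Quality control removes non-live
  terms, duplicated lines, records with identical importer and exporter,
  missing names, genus-only (`sp.`/`spp.`) and hybrid markers, and
  zoo-source records of threatened (VU/EN/CR) species.
- **Classification** of every traded (species, country) combination as
  *alien* (country outside the species' native range) or *native*. The
  native range is the set of countries with native extant, native possibly
  extant, extinct or possibly extinct presence; introduced-presence
  countries never count. Per-country distinct alien species = that
  country's colonization pressure.
- **Establishment analysis**: matching established-species lists to trade,
  trade-breadth comparison (established vs unestablished aliens), and a
  logit-link GLMM `logit P(established) = a + b·n_countries + u_family`
  fitted by adaptive Gauss–Hermite quadrature.
- **Multimodel inference**: all 2⁹ = 512 subsets of the nine country-level
  predictors (log area, log population density, log GDPpc, log1p
  colonization pressure, insularity, mean temperature, log mean
  precipitation, log1p congeneric richness, sampling effort) in a linear
  mixed model with a biogeographic-realm random intercept, fitted by exact
  profiled ML; AICc ranking, Akaike weights, ΔAICc ≤ 2 top-model sets, and
  conditional model averaging with unconditional standard errors
  (significance at |z| ≥ 1.96), plus marginal R².
- **Flow networks**: donor → recipient species-flow matrices among the 8
  economic regions, counting distinct (species, native region, recipient
  region) triples.
- A **synthetic-data generator** that emulates the whole study — country
  covariates, an IUCN-scale species pool with realm-clustered ranges, four
  overlapping trade sources with fixed per-source marginals, name noise and
  planted QC violations, and establishment drawn from the two generative
  models above — with every planted fact written to a truth ledger.

## Worked example

```bash
colpress run-all --seed 1 --out results/run
```

runs simulate → harmonize → classify → establish → infer → flows on the
default synthetic world (34,285-species pool, 200 countries, source
marginals CITES 2,371 / LEMIS 3,908 / ISIS 3,116 / OTAPS 5,053) in ~30 s
and prints per-stage row counts. `results/run/shares.json` then holds the
headline species accounting; with seed 1:

```json
"shares": {
  "traded_of_extant_pct": 22.9,
  "alien_of_traded_pct": 86.0,
  "native_only_of_traded_pct": 14.0,
  "both_of_alien_pct": 66.5,
  "established_of_alien_pct": 12.9,
  "traded_of_established_pct": 78.8
}
```

meaning: 22.9% of the species pool is in trade, 86.0% of traded species are
traded as aliens somewhere (14.0% only within their native range; 66.5% of
aliens are *also* traded natively), 12.9% of traded aliens have established
populations, and 78.8% of all established species are in trade. The same
run writes `averaged_coefficients.csv` (conditional-averaged estimates per
class — colonization pressure and its z-scores), `top_models.csv`
(ΔAICc ≤ 2 sets with marginal R²), `breadth_summary.csv` (established vs
unestablished trade breadth per class) and `flows_*.csv` (8×8 region flow
matrices plus chord-diagram edge lists). `colpress validate --dir
results/run` re-checks schemas and referential integrity.

Each stage is also exposed on its own (`colpress simulate|harmonize|
classify|establish|infer|flows`) over plain CSV artifacts, so real tables
in the same column layout can be substituted for any synthetic input.

## Layout

- `src/colpress/` — `synthetic`, `harmonize`, `classify`, `establishment`,
  `mixed` (LMM/GLMM fitters), `inference`, `flows`, `pipeline`, `cli`
- `tests/` — unit, property and acceptance suites
- `docs/methods.md` — models, calibration, numerical choices, limitations
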