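# Methods

## The analysis in one paragraph

A species is an *alien in trade* in a country when it is traded there but
the country is not part of its native range. Counting distinct alien
species per country gives that country's *colonization pressure*; the
subset with self-sustaining populations gives its *establishment richness*.
The pipeline harmonizes multi-source trade records to accepted names,
classifies every (species, country) combination, and then asks two
statistical questions: at the species level, does being traded more widely
predict establishment (logistic mixed model on trade breadth)? and at the
country level, which of nine socio-economic and environmental factors
predict establishment richness (all-subsets linear mixed models with AICc
model averaging)? A region-level flow network summarizes where alien
species come from and where they are traded to.

## Name harmonization

Keys (accepted names, synonyms, common and trade names) are lowercased and
ordered by character count, ties broken lexicographically — the sorted
lookup array of the original spreadsheet procedure. Extraction from free
text returns the key occurring in the text that sorts *last* in that
order, i.e. the longest (then lexicographically greatest) match; matching
is plain substring search without word boundaries, faithful to
case-folded FIND semantics, so rare false positives on very short keys are
possible (a word-boundary mode is the obvious extension if that matters
for a real corpus). Multi-pattern search uses a small in-package
Aho–Corasick automaton, because scanning ~10⁵ keys against ~10⁴ listings
per key would be quadratic; the test suite proves the automaton equal to
the brute-force scan on randomized inputs.

Cleaning applies, in order: live-term filtering (transaction-log sources
only), exact-duplicate removal, identical importer/exporter, missing
names, genus-only (`sp.`, `spp.`) markers, hybrid markers (`×`, ` x `,
`hybrid`), name resolution (unresolved names are excluded and counted),
and an optional known-country filter. Resolved records are deduplicated
once more on (source, species, country, year), since synonym resolution
can fold two raw lines together. Zoo-inventory rows for VU/EN/CR species
are removed afterwards, on the assumption that zoos hold threatened
species for conservation rather than commerce; the same species' records
from other sources are untouched.

One interpretive choice: each cleaned record carries a single trading
country — the importer for transaction logs, the holding or listing
country otherwise; exporters are retained only for the
importer==exporter rule. This keeps the generator's planted record ledger
exactly conservative through the pipeline.

## Classification and accounting

Native range = (native extant ∪ native possibly extant ∪ extinct ∪
possibly extinct) − introduced, at country resolution (polygon overlays
are out of scope; ranges are explicit country-set columns). Species with
an empty range are labeled `unknown-range` and excluded from richness
numerators and denominators while staying in trade totals. Reported
percentages are rounded half-up to one decimal, ratios to two.

## Establishment models

**Species level.** Among species with at least one alien trade record,
establishment is Bernoulli with
`logit p = a + b·(number of trading countries)`. The fitter is a
logit-link random-intercept GLMM estimated by adaptive Gauss–Hermite
quadrature (default 15 nodes): per group the integrand is re-centered at
its conditional mode (vectorized Newton) and rescaled by the local
curvature before applying the quadrature rule, and the marginal likelihood
is maximized by BFGS over (β, log τ). The original analysis nests
order/family/genus random effects; this implementation uses a single
family-level intercept — the dominant grouping — as a documented
simplification, with nesting as an extension point. Standard errors come
from a central-difference Hessian; `fix_tau2=0` reduces exactly to plain
logistic regression, which is the oracle used in tests.

**Country level.** Establishment richness per country follows
`log(1+richness) = β₀ + Xβ + u_realm + ε`, with X the nine standardized
predictors. Fits are exact profiled maximum likelihood: for a fixed
variance ratio λ = τ²/σ² the marginal covariance is block diagonal with
blocks I + λJ, inverted analytically (Sherman–Morrison), giving
closed-form GLS β̂ and σ̂²; a bounded one-dimensional search over log(1+λ)
(boundary λ = 0 checked explicitly) completes the fit. ML rather than REML
is used throughout because likelihoods must be comparable across
fixed-effect structures for AICc; a REML refit of a chosen model is a
one-line extension. The parameter count is k = (fixed effects incl.
intercept) + 2 for the two variances, and
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1).

**Model set and averaging.** All 2⁹ = 512 predictor subsets are fitted
(intercept always included; failed members are recorded and excluded from
weights). Akaike weights are exp(−Δᵢ/2), normalized; top models are
ΔAICc ≤ 2 (inclusive). Conditional averaging renormalizes weights over the
models containing a term; the unconditional standard error is
Σŵᵢ·sqrt(varᵢ + (βᵢ − β̄)²), z = β̄/SE, two-sided normal p, significance at
|z| ≥ 1.96. Marginal R² is var(Xβ̂)/(var(Xβ̂) + τ̂² + σ̂²), the
fixed-effects variance fraction.

**Transforms and filters.** Area, population density, GDPpc and mean
precipitation are log-transformed; colonization pressure, congeneric
richness and the establishment-richness response are log(1+x); continuous
predictors are then z-scored (insularity stays 0/1). Which standardization
the original standardized-coefficient reference intends is ambiguous
(z-score vs two-SD scaling); z-scoring is the default here and is
configurable. Country-level analyses are restricted to upper-middle and
high income classes, where trade-record sampling is most complete; the
companion univariate socio-economic models (log factor → log1p alien
richness, realm intercept) use the same filter.

## Flows

A species contributes one unit to cell (donor, recipient) when it is
native in ≥1 country of the donor region and alien-traded in ≥1 country of
the recipient region — region-pair triples, so a species native in two
regions and alien-traded in three contributes six units, and the same
species is counted multiple times by design. Native-country trade never
generates flow; intraregional (diagonal) flow arises only from alien trade
within the native region. Region membership ships as data (a
country→region CSV over the 8 economic regions), not code.

## The synthetic world

The generator's defaults are the study conditions; everything planted is
ledgered for recovery tests.

- **Countries** (200): realm-assigned covariates from log-normal/uniform
  families (area ~ lognormal(11.5, 1.8) km²; population coupled to area;
  GDPpc ~ lognormal(9.2, 1.1); trade value coupled to GDP; tropical realms
  warmer). Income classes are GDPpc quartiles, so the upper-middle+high
  filter keeps exactly half the countries (100, the analysis scale).
  Insularity is more common in the Oceania realm.
- **Species pool** (34,285 across mammals 5,500 / birds 11,000 / reptiles
  10,500 / amphibians 7,285, an IUCN-scale total): synthetic binomials
  from a syllable alphabet, family/genus hierarchies, IUCN categories
  (27% threatened), native ranges clustered in a home realm
  (1 + Poisson(3) countries, 15% spillover), occasional extinct-range and
  introduced-range countries (disjoint from native by construction).
  Synonyms are alternative genus placements of the same (globally unique)
  epithet; common names come from a disjoint word space. Junk listing
  text is built from digit-interrupted tokens, so no name key can occur in
  it — noise rows are unresolvable by construction, which is what makes
  the removal ledger exact.
- **Trade**: sources draw their members without replacement from a
  tradeable subset of the pool (10,700 species) with shared popularity
  weights exp(0.8·N(0,1)); the zoo source samples non-threatened species
  only. Per-source marginals are the published source totals, realized
  exactly. Each traded species gets 1 + Poisson(1.75) distinct trading
  countries, each alien with probability 0.595 (alien destinations
  weighted by trade value^0.7, native destinations uniform in range).
  These three numbers are solved analytically so the expected
  species-level shares equal the published 85.7% alien / 14.3%
  native-only / 65.9% both, and the tradeable-pool size and concentration
  are calibrated once so the four-source union (~7,840) and
  unique-to-one-source share (~44%) sit at the published 7,780 / 45.1%.
- **Establishment**: species flags from the logistic model (intercept
  −2.425, slope 0.15, giving ~12% prevalence among traded aliens);
  never-traded species establish at rate 0.0086 via non-trade pathways
  (so the traded share of established species lands near the published
  78.2%). Country targets are drawn per class from the log-linear country
  model (β as in the truth ledger, realm sd 0.25, residual sd 0.4) and
  realized by breadth-weighted sampling among that country's flagged
  aliens; every flagged traded species keeps at least one establishment
  country, which trades a little attenuation in the *pipeline-level*
  country-model signal for exact species-level prevalence. Strict
  coefficient-recovery tests therefore use the direct country-model
  simulator (`simulate_country_response`), not the full pipeline.
- Planted QC violations (duplicates, identical importer/exporter, missing
  names, genus-only, hybrids, non-live terms, zoo rows for threatened
  species) are extra rows built only on pristine base rows, so each
  cleaning rule's removal count must equal its planted count exactly.

What the generator does **not** emulate: trade volumes/prices, temporal
dynamics, legality, multilingual listings, real taxonomic messiness
(homonyms across kingdoms, unresolvable species complexes), and spatially
autocorrelated covariates beyond the realm structure. Passing tests
demonstrate that the *procedures* are correct and that parameters of the
assumed generative models are recoverable — not that the assumed models
describe real trade data.

## Numerical choices and problem sizes

Determinism: one integer seed, split into independent named substreams per
generator stage, so adding a stage never perturbs another's draws. The
LMM profile search uses xatol 1e-10 on log(1+λ) with an explicit λ=0
boundary check; GLMM mode-finding iterates Newton to 1e-9. Degenerate
inputs are values, not crashes: empty share denominators report `None`,
zero-variance paired differences report a degenerate flag (identical
vectors give t=0, p=1), single-member groups report undefined sd,
zero-variance correlation columns give NaN entries.

Default problem sizes are the study's own (34k-species pool, 200
countries, 512 models × 4 classes; the full pipeline runs in ~30 s);
replicated harnesses (logistic-slope recovery, permutation nulls,
coverage of the country-model coefficients) use 20–25 replicates at
n = 120–1,500 per replicate, sizes chosen to keep each harness's Monte
Carlo error well inside the asserted margins.

## Known limitations

- Single-level random intercepts (realm; family) — no nested taxonomic
  effects, no spatial autocorrelation beyond realm.
- Substring name matching can in principle over-match very short keys in
  real free text; word-boundary mode is not the default.
- The flow count adopts the region-pair-triple reading of "counted
  multiple times"; counting country pairs aggregated to regions would give
  larger totals.
- The country-level generator's realized establishment richness is an
  integerized, availability-capped version of the log-linear model, so
  pipeline-level coefficient estimates are attenuated relative to the
  ledgered β; use the direct simulator for calibration studies.
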