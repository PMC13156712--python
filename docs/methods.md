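# Methods

`trophicast` implements a screening-level framework for tracing pesticide
transfer through terrestrial food webs: relative contamination scoring of
soils, wild plants and wildlife; tiered reconstruction of wildlife average
daily doses (ADD); hazard-quotient (HQ) and ecological-carcinogenic-risk
(ECR) characterization; and probabilistic uncertainty and sensitivity
analysis. This note records the models, their assumptions, the defaults that
matter, and the design choices made where the design was genuinely open.

## Unit standardization

All concentrations are brought to mg·kg⁻¹ before any computation: soil and
plant values reported as ng·g⁻¹ scale by 10⁻³; lipid-normalized animal
values (ng·g⁻¹ lipid) additionally multiply by the lipid fraction, giving
mg·kg⁻¹ wet weight. The lipid fraction is looked up record-first, then at
the species level; a lipid-normalized record with neither is rejected.
Soil dry-weight and plant fresh-weight bases are carried as metadata and not
inter-converted. Non-detects are kept with their detection limit (LOD; the
quantification limit stands in when no LOD was reported) and enter all
log-scale computations at the full LOD, not LOD/2.

## Contamination scores

For a country × matrix stratum with M sites and N_m measurements at site m,

    S = (1/M) Σ_m (1/N_m) Σ_n [ log10 C_eff(n, m) − log10 C̄_n ]

where C_eff is the measured value for detects and the LOD for non-detects,
and log10 C̄_n is the arithmetic mean of log10 concentrations of pesticide n
over all global points of the same stratum (the log of the global geometric
mean). Strata are soil, wild plant, and one stratum per animal guild
(herbivore / carnivore / omnivore); animal strata score liver — the
biomonitoring tissue — only, and baselines are computed within each stratum
so compartments never mix. S is dimensionless, in decades: S = 1 means the
country sits one order of magnitude above the global geometric mean. Every
term is a within-chemical log-ratio, so S is exactly invariant to rescaling
any one chemical's global concentrations (unit changes cancel) and to site
and chemical ordering. A `percent_above = (10^S − 1) × 100` diagnostic is
provided as one convenient reading of S; it is an interpretation, not part
of the score definition.

## Tiered dose reconstruction

Exposure uses the most direct data available per country × guild × chemical;
uncertainty grows down the hierarchy:

* **Tier 1 — tissue data.** Reverse dosimetry through the steady-state
  biotransformation factor BTF (tissue concentration per unit daily oral
  intake, (mg·kg⁻¹)/(mg·day⁻¹)): ADD = C_tissue / (BTF_tissue · BW).
  We note the BTF unit question explicitly: dividing a concentration by a
  BTF must yield an intake (mg·day⁻¹) for the dose algebra to close, so the
  (mg·kg⁻¹)/(mg·day⁻¹) convention is used throughout.
* **Tier 2 — measured plant data.** Herbivores: ADD = C_plant · IR / BW.
  Herbivore tissues follow the forward model C_tissue = BTF · IR · C_plant;
  predators consume a tissue-weighted prey mean C̄ = Σ w_t C_t / Σ w_t over
  muscle and fat (liver is monitored, not preferentially eaten); carnivores
  then get ADD = C̄_herb · IR / BW, and omnivores a diet mix
  (f_p C_plant + f_h C̄_herb + f_c C̄_carn) · IR / BW with f_p+f_h+f_c ≤ 1.
* **Tier 3 — soil data only.** A steady-state leaf model supplies the plant
  concentration, C_plant = C_soil · BAF, and the identical Tier-2 chain runs
  on it.

Everything is steady state and linear in the source concentration, which
yields two exact identities used as tests: reverse dosimetry composed with
the forward tissue model collapses to IR·C_food/BW, and Tier 3 equals Tier 2
whenever the modeled plant concentration equals the measured one.

Dataset conventions: multiple records for one (country, species/matrix,
chemical) collapse to their median standardized concentration before
entering the equations (medians propagate through every summary). Within a
guild, species with liver data get Tier-1 estimates; a guild with no liver
data at all falls back to the plant- or soil-driven chain. When a predator
chain needs prey profiles, the full roster participates regardless of which
guilds are being estimated. Prey means average over all roster herbivores
(or carnivores) that carry muscle and fat BTFs plus tissue weights. An
omnivore whose diet references a missing compartment has its fractions
renormalized over the available compartments, preserving the total dietary
fraction, with a logged warning.

## Leaf uptake model

The Tier-3 soil → leaf transfer is a single well-mixed leaf at steady state,
transpiration-driven uptake from soil pore water balanced against air-side
exchange and first-order in-leaf loss:

    BAF = Q · (1/k_d) / (A_LH · g · 1000 / K_LA + λ · M_LH)

Q is the per-leaf transpiration rate (a function of air temperature and
relative humidity whose parameterization is site-specific; it is supplied
precomputed, or through a user hook Q(T, RH)); k_d the soil–water
distribution coefficient; A_LH leaf area; g vapor conductance; K_LA the
leaf–air partition coefficient; λ the total in-leaf loss rate (day⁻¹,
photodegradation + metabolism + growth dilution); M_LH single-leaf mass.
The literal 1000 is the model's published unit-harmonization constant;
parameters must be supplied in one consistent unit system with it (the
synthetic parameter files use the convention k_d = A_LH = g = M_LH = 1,
K_LA = 1000, λ = 0, under which BAF = Q). BAF is strictly increasing in Q
and K_LA, strictly decreasing in k_d, A_LH, g, λ, M_LH, and vanishes as
λ → ∞. When no measured k_d exists, an off-by-default helper derives
k_d = f_oc · K_oc from user-supplied organic-carbon inputs. Root, seed and
fruit compartments, pollen/nectar, and non-steady-state dynamics are out of
scope.

## Risk characterization

HQ = ADD / RfD and ECR = ADD × OSF, with USEPA-style benchmarks (oral
reference dose, mg·kg⁻¹·day⁻¹; oral slope factor, (mg·kg⁻¹·day⁻¹)⁻¹).
Flags use strict inequalities, so boundaries belong to the lower category:
HQ > 1 flags potential non-carcinogenic hazard; ECR ≤ 10⁻⁶ is negligible,
ECR > 10⁻⁴ unacceptable, in between intermediate. On the log10 scale the
elevated-ECR fence is −4. Both metrics are reported on natural and log10
scales; log10(0) is −inf in memory and an empty cell on export. Summaries
are group medians of the log values (species × chemical, or country ×
guild). Human-health benchmarks used for wildlife are a screening
convention, not an ecological threshold — a known limitation of the
framework, and shipped benchmark values are editable placeholders the user
must confirm against an authoritative source.

## Uncertainty analysis

Uncertain inputs are log-normal, matching the right skew of environmental
data, specified by arithmetic mean and coefficient of variation (cv) and
moment-matched on the log scale: σ² = ln(1+cv²), μ = ln(mean) − σ²/2. Where
no variability is reported, cv = 0.30 applies. Monte-Carlo HQ propagation
uses 10,000 iterations by default and reports median, mean, P(HQ > 1) and a
Gaussian-kernel density of log10 HQ. A Pearson screen flags parameters with
|ρ| ≥ 0.4 against the output; constant columns report "undefined, not
flagged" rather than erroring.

Variance-based sensitivity uses Sobol' paired matrices (scrambled Sobol'
sequence over 2d dimensions split into base matrices A and B) with the
Saltelli-2010 first-order estimator and the Jansen total-order estimator;
95% confidence intervals are percentile bootstrap over resampled design
rows (1,000 replicates by default). The quasi-random design wants
power-of-two base sizes, so requested iteration counts round up (2,000 →
2,048; 10,000 → 16,384); total model evaluations are n_base × (d + 2).
Estimates are stored unclamped — small negative values or S1 slightly above
ST are estimator noise and are reported as such. The estimator is verified
against the analytic decomposition of additive Gaussian models and the
Ishigami function's closed-form indices. Same seed and config give
bit-identical output.

## Fox / p,p′-DDE case study

Two ECR pathways for a red fox are decomposed: the direct tissue pathway
ECR = C_tissue/(BTF_liver·BW)·OSF over {BW, OSF, C_tissue} at 2,000 base
iterations, and the full soil pathway (soil → plant → rabbit muscle/fat →
fox) over {IR_fox, BTF_fat, BTF_muscle, BW_fox, IR_rabbit, BAF, C_soil} at
10,000, with OSF fixed and rabbit tissue weights 0.65/0.35.

The shipped input distributions are **synthetic reconstructions**: only the
resulting variance shares of this case are publicly reported, not the input
table. For a product of independent lognormals Y = Π X_i (log-variances
v_i, g_i = e^{v_i}, G = Π g_i) the indices are closed-form —
S1_i = (g_i−1)/(G−1), ST_i = G(1−1/g_i)/(G−1), with analogous expressions
when one factor is a weighted sum of two lognormals — so the unpublished
CVs were recovered by least squares against the reported S1/ST values.
The soil pathway fits closely (ST within ~0.03). The tissue pathway admits
no exact solution: the three reported S1:ST ratios imply mutually
inconsistent total variances under any independent-lognormal product model,
so the fitted CVs are a compromise that preserves the ranking
(BW > OSF > C_tissue), the dominance of the fox intake rate on the soil
pathway, the negligible role of soil concentration, and the ST − S1
interaction structure. Tests assert that qualitative structure; exact index
values are reported, not asserted. Arithmetic means are realistic
placeholder physiology values and do not affect the indices (Sobol indices
are scale-free).

## Synthetic data generator

The generator emulates a compiled multi-country residue literature:
per-chemical log-normal concentrations (log10 site values = global median +
country offset + Normal(0, sd)), left-censoring at the LOD with non-detects
emitted as such, uneven per-country matrix availability to exercise every
tier, and animal tissues produced by running the food-chain equations
forward so each tier must recover a stored ADD truth table. Country offsets
are specified in decades; with equal site counts the expected score of a
country is its offset minus the pool-mean offset, so zero-sum designs give
exact integer truth. Tissue noise, when enabled, is median-preserving
(lognormal with μ = 0) because the estimation pipeline propagates medians —
the default noise cv is 0.30, matching the fallback variability convention.
The `literature_scenario` preset mirrors the shape of the compiled dataset:
30 countries (all with soil, about half with plants, about a third with
animal tissue), 34 chemicals with spread properties, 6 sites per country.
Its chemical codes are synthetic, not real CAS numbers.

What the generator does **not** emulate: real per-country concentration
magnitudes, correlated multi-chemical contamination, spatially structured
sampling, inter-study methodological heterogeneity, or reporting bias.
Passing tests therefore demonstrate the pipeline's internal consistency —
each stage inverts the generating model exactly, and estimators hit
closed-form oracles — not the field accuracy of any particular published
risk figure.

## Numerical conventions

* Log base 10 for scores and risk summaries; natural logs internally for
  log-normal parameters.
* Full-LOD substitution for non-detects everywhere (scores, medians).
* A detected concentration of exactly zero is not log-transformable and is
  a hard error in scoring; zero ADD is legal and reports log10 = −inf.
* Sobol' sample points are clipped away from {0,1} before inverse-CDF
  transforms so unbounded distributions stay finite.
* Degenerate inputs fail loudly: all-zero tissue weights, diet fractions
  summing above 1, zero output variance in the Sobol decomposition, missing
  BTFs or baselines are named errors, not silent NaNs.
* Problem sizes in the default test and acceptance runs (four-country
  noise-free scenario, 2,000-site moment checks, 2¹³–2¹⁴ Sobol bases, 200
  noisy-recovery replicates) were chosen as the smallest designs whose
  sampling error is well below the asserted tolerances.

## Known limitations

Single representative roster per scenario rather than country-specific
faunas; steady-state-only kinetics; no mixture toxicity; human-health
benchmarks as ecological stand-ins; the leaf model's transpiration term is
an input, not a micrometeorological submodel; the case-study distribution
table is a reconstruction, not the original supplementary data.
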