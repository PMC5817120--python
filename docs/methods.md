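# Methods

## Study system and scope

Two three-species communities — native perennial bunchgrasses (PSSP, FEID,
KOCR) and short-lived non-natives (BRTE, CEDI, SILO) — are grown on five
conditioned soil types (PSSP, BRTE, CEDI, SILO, Mixed) in a common-garden
design, and the resulting cover data parameterise a community growth model
that is compared, with and without feedback, against a landscape survey
spanning historical tillage boundaries.  The physical field procedures
(herbicide, seeding, soil preparation) and the microbial/nutrient mechanisms
behind the feedback are out of scope; the package starts from plot-level
percent-cover tables.

## Synthetic data generator

The original plot-level tables are not publicly archived, so the generator
emulates their structure.  What it encodes, and why:

- **Cells.** 2 communities × 5 soils, default 25 replicate plots per cell
  (the experiment realised 15–31; values outside that range are rejected).
- **Suppression structure.** Community totals on the "other" dominant's soil
  are scaled by 0.48 (natives on CEDI soil) and 0.45 (non-natives on PSSP
  soil); all other soils, including Mixed, share the community's baseline.
- **Baselines.** 26% total cover for the native community, 35% for the
  non-native, on non-suppressive soils.  Only the suppression *ratios* are
  reported for the experiment, so the absolute levels are a design choice:
  three growing seasons from seed favour the ruderal non-natives (cheatgrass,
  diffuse knapweed, tumble mustard) over slow-establishing bunchgrasses, and
  the asymmetry is required for the feedback-free model to predict non-native
  dominance — the behaviour the landscape comparison is built around.  With
  symmetric baselines the null model has no direction at all.
- **Within-community split.** Equal thirds by default.  The experiment
  reports community totals only, so any split is a stand-in; a
  landscape-abundance-proportional split (18.9 : 2.9 : 0.2 and
  4.5 : 5.1 : 3.0) is provided as an alternative, but concentrating 86% of
  native cover in PSSP would give that single species a self-soil rate above
  every non-native rate and flip the null model to native dominance, which
  contradicts the qualitative behaviour being modelled.
- **Noise.** Truncated normal on [0, 100] with SD 5 percent-cover points
  (~19% CV at the native baseline, typical of visual cover estimates); a
  mean/SD-matched beta alternative exists for bounded-support realism.  Noise
  applies to the community total; the split is deterministic, so species
  covers conserve the drawn total exactly.
- **Survey.** 25 sites × 4 transects (−50, −5, +5, +50 m from the boundary)
  × 7 years.  Transect means encode the observed origin shares (25/75,
  36/64, 86/14, 94/6) of total target cover (38% on the abandoned side, 43%
  on the never-tilled side), with a site-level random effect (SD 3) to make
  records pairable and residual SD 5.

What the generator does *not* emulate: Phase-I attrition, per-species
year-to-year dynamics, spatial autocorrelation along transects, and
observer bias.  Passing tests therefore demonstrate that the pipeline is
correct and that the reported structure implies the reported conclusions —
not that the original measurements are reproduced.

With the default fixture the derived carrying capacities come out near
37% (native) and 48–50% (non-native) rather than the experiment's printed
42%/41%; the capacity estimator pools the suppressed cells into the SD, and
the fixture's baselines are otherwise unconstrained.  Only rank-order
behaviour, not bar heights, is interpreted downstream.

## Statistics

Percent cover is arcsine-square-root transformed (radians) before testing.
The soil-treatment comparison is a one-way fixed-effects ANOVA on plot-level
community totals, computed directly from sums of squares; pairwise
comparisons use Tukey–Kramer HSD (α = .05) and feed an insert-and-absorb
compact letter display with groups ordered by descending mean (unadjusted
pairwise t tests are available via `adjust="none"`; the original analysis
does not name its procedure).  The survey test averages the 7 years within
site × distance, then fits a site-blocked two-way fixed-effects ANOVA
(origin × distance) with paired per-distance t contrasts.  The original
random-effects (fields) formulation is deliberately replaced: after the
averaging step the design is balanced, the block structure captures the site
variance, and the fixed-effects version is verifiable against a
sums-of-squares oracle.  Degenerate inputs are handled explicitly: all
observations identical → F = 0, one shared letter; zero within-group
variance with real signal → error (F undefined); sites missing a distance
class are dropped with a warning.

## Rates and capacities

Rates: r = (F/I)^(1/55) with I = 0.004 (a seed's ground cover) and F the
mean cover fraction of a species across its community's plots on one soil.
Cell means below I are floored at I (rate exactly 1), so an unobserved
species is static rather than instantaneously extinct.  The null model keeps
one rate per species, from its self soil: conspecific soils for PSSP, BRTE,
CEDI and SILO; the Mixed (community-level "self") soil for FEID and KOCR,
whose conspecific soils were never realised.  Capacities are mean + 2·SD
(sample SD, n−1; convention configurable) of plot-level community totals
pooled over soils.

## Simulator

Per step: grow (cover × soil-weighted additive rate), cap, and — at season
boundaries — update soils.  Three choices deserve justification:

- **Hard ceilings, not damping.**  Rates were derived assuming pure
  exponential transit from I to F over a season, so logistic behaviour is
  realised as exponential growth under proportional-rescale caps; a
  (1 − N/K) damped variant is available (`growth_form="damped"`) for
  sensitivity analysis but systematically undershoots F and is not used in
  the headline analysis.
- **Pot-level plus group-level caps.**  The two origin-group capacities are
  estimates of the same quantity — how much ground a community can hold — so
  the simulator first caps *total* cover at max(k_native, k_nonnative) (the
  pot level), then each group at its own K.  Without the shared pot cap the
  two groups never compete for ground: both simply saturate at their K
  within ~60 steps and every scenario ends native 42% vs non-native 41%,
  erasing the feedback/null contrast entirely.  With it, relative growth
  rates decide how the shared ground is divided, which is what the
  comparison measures.  `pot_capacity=None` restores the independent-caps
  reading; a float overrides the default.
- **Seasonal soil turnover.**  Soil proportions are recomputed from plant
  relative abundance every 55 steps (annually), not every step.  Per-step
  replacement would overwrite the scenario's initial soil composition after
  a single step — every scenario would collapse onto the same near-equal
  state and the across-boundary gradient could not emerge.  Annual turnover
  matches the yearly cadence at which conditioning plausibly shifts and
  retains a season of initial-condition memory.  `soil_update_interval=1`
  gives the per-step variant.

Order of operations is grow → pot cap → group caps → (seasonal) soil update;
the trajectory is deterministic and bit-reproducible, and the null model runs
through the identical code path with the rate matrix collapsed to the
self-soil column, so soil-invariant tables yield bitwise identical feedback
and null trajectories.

All species cultivate the soil named by `species_to_soil`; FEID and KOCR
cultivate the PSSP-type native soil (their own soils do not exist), and the
Mixed soil is cultivated by no one, so it decays at the first update.

## Scenarios and comparison

One scenario per distance class, with the surveyed native cover fraction
(0.25, 0.36, 0.86, 0.94) assigned to the PSSP soil and the remainder split
among BRTE/CEDI/SILO soils in proportion to non-native landscape cover
(equal thirds available).  Mixed soil has no landscape analogue and is
excluded.  Both model variants run 165 steps (three seasons) from equal
propagule cover (0.004 per species), isolating the soil effect from
propagule pressure.  A model "agrees" at a distance class when the sign of
its predicted native-minus-non-native cover matches the observed sign; under
the defaults the feedback model agrees at 4/4 classes and the null model
only on the abandoned-field side (−50 and −5 m, 2/4).  Predicted magnitudes
are not compared to observations — the model omits propagule pressure and
biomass accumulation and is expected to compress the observed contrast.

## Problem sizes and numerics

Default problem sizes used throughout the tests and the acceptance script:
25 plots per cell (250 plots), 25 × 4 × 7 survey records, 165-step
trajectories; Monte-Carlo checks use 100–1,000 generator seeds.  Tolerances:
soil proportions sum to 1 within 1e−9; group totals respect K within 1e−9;
rate round-trips are exact to ≲1e−12 relative error (rates are computed via
exp(log(F/I)/steps)).  Ties in the letter display are broken by descending
group mean; the letter algorithm is deterministic (significant pairs are
processed in sorted order).

## Known limitations

- The equal-split, asymmetric-baseline fixture is one of many tables
  consistent with the reported structure; species-level conclusions (as
  opposed to community-level ones) should not be read off the defaults.
- The simulator's bistable character means scenarios near the tipping
  composition (~0.5 native soil under the defaults) can take either side
  under small rate perturbations; the four landscape scenarios sit well away
  from it, but custom scenarios near 50/50 deserve sensitivity checks.
- The two-way survey ANOVA is fixed-effects; its F statistic is not
  numerically comparable to a mixed-model F with estimated random-effect
  variance, only qualitatively.
- No uncertainty propagation from plot noise into rates; rerun the pipeline
  across generator seeds to see that spread (the acceptance script reports
  one seed's worth).
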