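# Methods

This note documents the models implemented in `webcva`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that matter for reproducing a run.

## Food-web representation

A web is a simple directed graph, edges stored consumer → resource
("predator to prey"). Bottom-up analyses traverse links in reverse;
`invert_links` realizes that as an explicit edge reversal, which makes the
bottom-up homophily computation a literal reversal followed by the standard
top-down index. Self-loops (cannibalism) are dropped at read time with a
warning: the cascade, homophily and motif definitions used here are
ill-defined under self-consumption. Duplicate edge rows collapse with a
warning. Plant nodes must be basal on a valid input web; inverted webs and
randomized nulls legitimately violate this, so basality is checked by
`validate_web` rather than enforced by the container.

Trophic levels are prey-averaged: TL = 1 for basal nodes and
TL(j) = 1 + mean over resources i of TL(i), solved as a dense linear
system, so consumption cycles are allowed provided every consumer has a
directed path to a basal node (a stranded consumer is an error naming the
nodes). Prey-averaging was chosen over shortest-path levels because it is
the standard continuous definition and degrades gracefully on omnivory;
with either convention basal nodes sit at exactly 1.

## Energetics

Interaction strengths are diet fractions from an energy-flux steady state
(the "food-web energetics" framework):

- **Density.** Size–density relationship D = 10^(a + b·log₁₀ M) with
  defaults a = 4.23 (log₁₀ individuals/km² at 1 g) and b = −0.75. The
  −0.75 exponent is the canonical allometric scaling; the intercept is a
  configurable normalization (the source literature reports a family of
  intercepts by taxon; 4.23 is a representative mammalian value).
- **Biomass.** Vertebrates: B = M·D. Aggregated invertebrate orders carry
  surveyed/imputed biomasses as direct overrides (optionally with 95%
  CIs). Plants share one aboveground pool, split equally across plant
  nodes by default; the pool can be derived from September–March
  precipitation P (mm) as log₁₀(ANP g/m²) = 1.976·log₁₀(P − 26.2) − 2.746.
  The grouping of the offset in this regression is ambiguous as printed in
  the source literature; this parse (offset on precipitation, then the
  log) is a documented default and all four constants are configurable.
  The model is undefined at P ≤ 26.2 mm and raises there.
- **Demand.** Per-individual metabolic rate x₀·M^0.71 with x₀ = 38.8
  (vertebrate endotherm), 3.9 (vertebrate ectotherm), 1.8 (invertebrate),
  and identically 0 for plants; population demand X = rate × density.
  These normalizations are editable configuration. They deliberately do
  not pretend to be a specific laboratory regression because the
  downstream quantity of interest — the diet-fraction matrix W, hence the
  cascade — is mathematically independent of X.
- **Diet preferences.** Pure biomass proportionality:
  W[i,j] = B_i / Σ B over j's resources. No selectivity or capture-rate
  term; this is the simplest defensible reading and keeps strengths
  scale-invariant in the biomasses (verified by test).
- **Flux balance.** ē_j F_j = X_j + Σ_k W[j,k] F_k with
  ē_j = Σ_i e_i W[i,j]; assimilation efficiency defaults 0.545 for plant
  resources and 0.906 for animal resources. Solved as one dense linear
  system over consumers; basal influx is pinned at 0. The solver rejects
  singular systems and negative fluxes (e.g. mutually-dependent consumer
  pairs with no basal support) by name. Balance residuals, relative to
  max(1, X_j), stay below 1e−8 on every solvable web in the suite
  (typically ~1e−15).
- **Strengths.** s_ij = f_ij/F_j, which under biomass-proportional
  preferences equals W; columns (consumers) sum to 1 and basal nodes have
  no strengths column.

## Cascade model

Topological, bottom-up, threshold-based. After each primary removal the
system iterates to a fixed point: a surviving non-basal consumer goes
secondarily extinct when its remaining summed strength over *surviving*
resources falls below T, or when it has no surviving resources. Strengths
are frozen at baseline (no renormalization): "remaining interaction
strength" is measured against the original diet. The comparison is
"≥ T survives", with ties resolved to survival at a 1e−12 floating
tolerance. Consequences, both verified by test: at T = 0 only total
resource loss kills; at T = 1 losing any one of several prey kills.

Conventions the model had to fix where the method description is silent:

- Basal (plant) nodes are exempt from secondary extinction; aggregated
  invertebrate orders are not.
- A scheduled primary that already fell as a secondary is skipped and the
  step still advances (logged).
- Per-step fixed-point propagation is order-independent (strength sums
  only decrease); an oracle test recomputes survival from scratch after
  each removal on small webs and matches exactly.

Randomized experiments draw an independent uniform permutation of the pool
per replicate, replicate r seeded from (master seed, r), so ensembles are
reproducible and replicates independent of execution order. Bands are
empirical 2.5/97.5 percentiles across replicates (the natural reading of a
"95% confidence interval from 100 replicates"). Note a property of such
bands: their *width* does not shrink as replicates grow — it converges to
the quantile band of the trajectory distribution, typically from below;
what shrinks is the seed-to-seed variability of the band estimate, which
is what the suite asserts.

The biomass-sensitivity experiment redraws override-node biomasses
uniformly within their 95% CIs, recomputes W (= strengths), reruns a fixed
removal order, and reports the number of distinct secondary-extinction
sequences; one distinct sequence means the cascade is robust to that
biomass uncertainty.

## Homophily

Coleman's index per group on out-links, with p_g = n_g/N (not
(n_g−1)/(N−1); at N = 300 the difference is < 0.002 and the simpler
convention is used throughout). Groups with no out-links, and a group
spanning the entire web (no between-group link possible), report NaN
rather than a misleading 0. The inverted-web variant reverses edges first.

## Motifs and nulls

Two 3-node motifs only. Apparent competition: predator with an unordered
prey pair, counted *induced* by default (prey linked in either direction
are excluded — consistent with the explicit exclusion in the tri-trophic
rule; a non-induced switch exists). Tri-trophic chain: ordered
apex → intermediate → basal with apex → basal absent. Driving positions:
the prey (split into exactly-one-in-group and both-in-group cells) and the
apex respectively. A vectorized tally path is used for null ensembles and
is property-tested equal to the explicit enumeration censuses, which are
themselves tested against O(n³) brute force.

Null model: uniform directed G(n,m) (exact node and edge counts, groups
kept in place), satisfying the "same nodes and expected links" constraint
while removing edge-count variance from the null; a G(n,p) switch exists.
z = (observed − null mean)/null sd over 100 nulls by default;
under-representation gives z < 0. p-values are one-tailed
normal-approximation by default, empirical rank (r+1)/(n+1) as an option;
degenerate cells (sd = 0) are flagged, not zeroed. A self-consistency
check scores an ER draw against ER nulls and finds |z| ≤ 3 in ≥ 99% of
trials.

## Synthetic generator

Emulates the statistical shape of the target desert community: exact group
sizes (150 birds, 43 mammals, 42 reptiles, 26 invertebrate orders, 39
plant orders), independent Bernoulli links per ordered group pair from a
mixing matrix, plants strictly basal, invertebrates feeding only on
invertebrates and plants, vertebrates unrestricted. Consumers left without
resources are rewired to one uniform allowed resource, keeping group sizes
exact and every web flux-solvable. Masses are log₁₀-normal per group
(defaults: birds 10^N(1.45, 0.55), mammals 10^N(1.8, 0.9), reptiles
10^N(1.3, 0.6), invertebrate representative masses 10^N(−0.3, 0.8) g —
chosen as plausible desert assemblage scales, dominated by passerines,
rodents and lizards). Invertebrate-order biomasses are drawn
10^N(5.5, 0.5) g/km² with symmetric synthetic CIs B(1 ± 1.96·CV),
CV = 0.15; the resident fraction of birds defaults to 0.35 (deserts hold
few year-round residents); plant biomass comes from the production
regression at 150 mm winter precipitation.

The preset mixing matrix was calibrated once, before any downstream
analysis, by least squares against the published summary statistics of the
real web — per-group link totals (group mean degree × group size) and
inverted-web homophilies (birds 0.66, mammals 0.07, reptiles 0.36,
invertebrates 0.02, plants −1) — yielding an expected edge count of
4078.65 ≈ 4080. Across seeds the realized edge count stays within a few
percent and bird homophily within roughly ±0.05 of target.

What the generator does **not** emulate: real diets and species
identities, degree heterogeneity beyond the group level (real webs have
heavier-tailed degree distributions), motif abundances (only homophily and
degree totals were calibration targets — observed z-score *signs* match
the bird-subweb expectation but magnitudes are not comparable to the real
web), correlated biomass errors, and phylogenetic structure in traits.
Passing tests on synthetic webs therefore demonstrate correctness and
calibration of the *method*, not reproduction of real-web motif counts or
cascade curves; analyses of the deposited web require its own tables under
`data/mojave/`.

## Problem sizes and seeds

Default experiment sizes follow the study design: 100 cascade replicates,
100 nulls, thresholds {0.6, 0.7, 0.8, 0.9}, five removal pools. Property
tests use webs of 6–60 nodes with seeded generators (200 webs for
threshold monotonicity, 20 for flux residuals, 200 trials for the
self-z-score check); the acceptance script runs the full-size pipeline on
one 300-node web plus a 20-seed calibration sweep. Every stochastic
component takes a named sub-seed derived from one master seed via
`numpy.random.SeedSequence`, so any stage can be re-run in isolation.

## Known limitations

- The cascade is topological; it ignores population dynamics and
  compensatory rewiring, and topological analyses are known to
  under-count secondary extinctions relative to dynamical ones.
- Top-down effects enter only structurally (motif positions), never as
  simulated extinctions.
- The size–density relationship is a regional-scale approximation; desert
  densities fluctuate with productivity pulses, so absolute biomasses are
  order-of-magnitude estimates (the cascade depends only on their ratios
  within each diet).
- Aggregated invertebrate/plant nodes make those groups artificially
  robust as cascade participants and are excluded as primary-removal
  pools.
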