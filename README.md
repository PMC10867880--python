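# webcva

Community viability analysis for trophic networks — a Python pipeline for
asking how resistant an ecological community is to losing species, built
around the terrestrial food web of a desert ecosystem (five groups: birds,
mammals, reptiles, aggregated invertebrate orders, aggregated plant orders).

It is aimed at ecologists who have (or can simulate) a directed consumer →
resource food web with group labels and body-mass traits, and who want to
quantify:

1. **Bottom-up secondary-extinction cascades.** Interaction strengths are
   energy-flux diet fractions: each consumer j satisfies the steady-state
   balance ē_j F_j = X_j + Σ_k W[j,k] F_k, where F_j is total influx, X_j
   the population metabolic demand, W the biomass-proportional diet matrix
   and ē_j the diet-weighted assimilation efficiency; the strength of link
   i→j is s_ij = f_ij / F_j. A primary removal then cascades: any consumer
   whose surviving summed strength drops below a threshold T ∈ {0.6, 0.7,
   0.8, 0.9} (or that loses all resources) goes secondarily extinct, and
   extinctions propagate to a fixed point. Removal orders are randomized
   (100 replicates, empirical 95% bands) over pools such as *all birds*,
   *resident birds only*, *mammals*, *reptiles*.
2. **Top-down risk structure.** Coleman's homophily index on the inverted
   (resource → consumer) web, H_g = (w_g − p_g)/(1 − p_g) for w_g ≥ p_g and
   (w_g − p_g)/p_g otherwise, measures how strongly each group's links stay
   within the group. Censuses of apparent-competition and tri-trophic-chain
   motifs tally how often each group occupies a *driving position* (shared
   prey, or apex of a chain), compared to Erdős–Rényi G(n,m) null ensembles
   via z-scores and p-values.
3. **Trait and density scaffolding.** Population densities from the
   allometric size–density relationship D = 10^(4.23 − 0.75·log₁₀M)
   (individuals/km², M in g), aboveground plant biomass from winter
   precipitation, direct biomass overrides with 95% CIs for aggregated
   nodes, and a CI-resampling sensitivity check for cascades.

A calibrated synthetic-web generator reproduces the statistical shape of
the published desert web (group sizes 150/43/42/26/39, ≈4080 links, a
strongly intra-connected bird subweb with inverted-web homophily ≈ 0.66),
so the entire pipeline is testable without any data download.

## Worked example

```python
from webcva import *
from webcva.cascade import CascadeConfig

syn = generate_web(mojave_like_config(seed=1))
print("nodes:", len(syn.web), " edges:", syn.web.n_edges)
print(coleman_homophily(syn.web, invert=True)["H"].round(2).to_string())

w = diet_preferences(syn.web, syn.traits)
flux = solve_fluxes(syn.web, w, metabolic_demands(syn.web, syn.traits))
s = interaction_strengths(flux)

pool = select_pool(syn.web, "bird")
ens = randomized_cascade_experiment(
    syn.web, s, CascadeConfig(threshold=0.6, pool=pool, n_replicates=100, seed=1)
)
clean = sum(1 for f in ens.first_secondary if f is None or f >= 50)
print(f"birds, T=0.6: {clean}/100 replicates with no secondary extinction "
      f"before 50 removals; mean total secondaries {ens.mean[-1]:.2f}")
```

prints

```
nodes: 300  edges: 4044
bird            0.62
mammal          0.10
reptile         0.40
invertebrate    0.02
plant          -1.00
birds, T=0.6: 100/100 replicates with no secondary extinction before 50 removals; mean total secondaries 0.00
```

Read: this draw of the synthetic web has 300 species/aggregated orders and
4044 feeding links. On the inverted web, birds keep 62% more of their
outgoing links within their own group than group size alone predicts
(a bird "subweb"), plants necessarily score −1 (nothing consumes a plant
*and* is a plant), and mammals/invertebrates sit near the well-mixed
expectation of 0. Under the 0.6 threshold, randomly ordered bird removals
never triggered a secondary extinction within the first 50 removals in any
of 100 replicates — the bird subweb buffers the community against bird
loss.

The same analyses are available from a shell:

```sh
webcva simulate --seed 1 --out-prefix out/syn
webcva homophily --web out/syn_edges.csv --nodes out/syn_nodes.csv
webcva run-all --seed 1 --out out/report
```

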