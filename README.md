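# decgeo

Historical biogeography on dated phylogenies: time-stratified
**Dispersal–Extinction–Cladogenesis** (DEC) models with founder-event
speciation (+J) and distance-dependent dispersal (+x), maximum-likelihood
fitting, AICc/LRT model comparison, ancestral-range estimation, maximum
parsimony ancestral areas — plus a forward simulator of island-arc range
histories so every stage can be validated without external data.

The package is aimed at phylogeneticists reconstructing how a clade
colonized an archipelago: given a dated tree (Newick, branch lengths in
Myr), a species × area presence/absence table, and per-epoch distance /
constraint / availability matrices, it answers which range-evolution model
the data support and where ancestral lineages lived. The motivating system
is the colonization of the Sunda Arc by flightless *Trigonopterus* weevils
(12 areas, ranges capped at three areas, 298 range states, four geological
time slices), and the shipped reference table of published log-likelihoods
for that system is used to exercise the model-selection arithmetic.

## The model

A lineage's state is its geographic range `R` (a non-empty set of at most
`m` areas). Along a branch, the range expands into area `b` at rate
`Σ_{a∈R} d·m[a,b]·dist[a,b]^x` and loses any area at rate `e`; singletons
contract to an absorbing null range (extinction). At a speciation node the
range is inherited by sympatry, subset sympatry, or narrow vicariance
(fixed weight 1 each), or — under +J — by a founder-event jump to an
outside singleton with weight `j` times the (relative-)distance modifier;
weights are normalized per parent. Epochs carry their own distance,
multiplier, and availability matrices; branches are cut at epoch
boundaries and states containing unavailable areas are masked. Models are
compared by AICc (`n` = number of tips), evidence ratios
`exp(−ΔAICc/2)`, relative model probabilities, and likelihood-ratio tests
across the nested DEC ⊂ DEC+J hierarchy. See `docs/methods.md` for the
full account.

## Worked example

Simulate a 40-tip microendemic dataset on a six-island arc under DEC+J+x
(d = 0.02, e = 0.005, j = 0.2, x = −1), then refit and compare three models:

```python
from decgeo import (SimulationConfig, DecParams, simulate_dataset,
                    fit_model, model_spec, comparison_table, lrt)

config = SimulationConfig(seed=7, n_tips=40, n_areas=6,
                          params=DecParams(0.02, 0.005, 0.2, -1.0),
                          tip_mode="collapse")
tree, history, scenario, space = simulate_dataset(config)
tips = history.tip_ranges()

fits = [fit_model(tree, tips, scenario, space, model_spec(name))
        for name in ("DEC", "DEC+J", "DEC+J+x")]
print(comparison_table(fits, n=tree.n_tips).table.to_string(index=False))
stat, p = lrt(fits[0], fits[1])
print(f"LRT DEC vs DEC+J: statistic {stat:.3f}, p = {p:.3g}")
```

prints

```
  model  free_parameters         lnL       AICc  AICc_weight  relative_probability_percent
    DEC                2 -112.172698 228.669720 3.155149e-20                             0
  DEC+J                3  -70.602252 147.871170 1.107138e-02                             1
DEC+J+x                4  -64.860765 138.864387 1.000000e+00                            99
LRT DEC vs DEC+J: statistic 83.141, p = 7.64e-20
```

The data were generated with founder-event jumps, and the comparison
recovers exactly that: adding `j` improves the log-likelihood by 42 units
(LRT p ≈ 1e-20), adding the distance exponent improves it further, and the
AICc evidence ratios put 99% of the model probability on DEC+J+x. The
`AICc_weight` column is the evidence ratio relative to the best model
(best = 1); the last column renders the normalized ratios as whole
percents.

The same workflow is scriptable from the shell (`decgeo simulate`,
`decgeo fit`, `decgeo compare`, `decgeo ancestors`, `decgeo parsimony`,
`decgeo ltt`, `decgeo recover`, and `decgeo pipeline --config run.yaml`
for a fully file-driven run), and `decgeo.run_pipeline` fits the full
set of 12 model variants (DEC/DEC+J/DEC+x/DEC+J+x, each unconstrained,
adjacency-constrained, and adjacency-constrained with a free island chain)
under both stratified and unstratified geography, writing a 24-row
comparison table, best-model ancestral marginals, and the parsimony
summaries.

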