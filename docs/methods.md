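# Methods

## The model

`decgeo` implements the Dispersal–Extinction–Cladogenesis (DEC) family of
geographic range-evolution models on a dated phylogeny. The state of a
lineage is its geographic range — a non-empty subset of `A` discrete areas,
restricted to at most `max_range_size` areas (default 3). With 12 areas and
a 3-area cap the state space holds 298 observable ranges; an empty "null"
range is carried internally as an absorbing extinction state but is never
valid as data.

**Anagenesis** (along branches) is a continuous-time Markov chain. A range
`R` expands into an outside area `b` at rate

    sum_{a in R}  d * m[a, b] * dist[a, b]^x

where `d` is the per-area dispersal rate (events/Myr), `m` is the epoch's
dispersal-multiplier matrix (constraints and uncertainty weights in [0, 1]),
`dist` the epoch's inter-area distance matrix and `x` the distance exponent
(the "+x" extension; `x = 0` disables distance dependence entirely). A range
loses any one of its areas at rate `e` per area; singletons contract to the
null range (local extinction of the lineage's last population).

**Cladogenesis** (at nodes) redistributes the parent range over the two
daughters. Following classic DEC, a singleton parent is copied to both
daughters (sympatry); a widespread parent undergoes subset sympatry (one
daughter a single area of `R`, the other all of `R`) or narrow vicariance
(one daughter a single area, the other the remainder). These events carry
fixed weight 1. The "+J" extension adds founder-event jumps: one daughter is
a singleton *outside* the parent range, with weight `j` times the dispersal
modifier toward that area. Weights are normalized per parent into
probabilities, and each unordered outcome is split equally between the two
daughter assignments. Only `d`, `e`, and optionally `j` and `x` are free —
giving the 2/3/4-parameter models DEC, DEC+J, DEC+x and DEC+J+x.

### Distance units and the jump modifier

Anagenetic dispersal uses the distance matrix as given (km, or any rescaled
version). Cladogenetic jump weights, however, compete with the *fixed,
dimensionless* unit weights of sympatry and vicariance, so their distance
modifier uses relative distances — each epoch's matrix divided by its mean
off-diagonal entry. With this convention the likelihood is exactly invariant
under rescaling all distances by `c > 0` together with `d -> d * c^(-x)`,
which is why analyses with raw kilometres and with matrices rescaled to a
maximum of 1 give identical results. Jumps from a widespread parent average
the modifier over the parent's areas (this reduces to the plain
single-source modifier for singleton parents). A switch
(`jump_distance_scaling=False`) removes the distance factor from jumps
entirely while keeping it on anagenetic dispersal.

The 9,999 km convention for "possible but very unlikely" crossings is
honoured by treating the sentinel as a genuine distance: with a negative
exponent the implied rate is positive but negligible (≈ `d * 1e-8` at
`x = -2`), never a hard zero.

## Time stratification

A `StratifiedScenario` is an ordered, contiguous list of epochs, each with
its own distance matrix, multiplier matrix, and per-area availability mask,
covering root age to present. Branch segments are cut at every epoch
boundary they cross and the per-segment transition matrices are multiplied
old-to-young. When a segment lies in an epoch where some areas do not exist,
rows and columns of states containing those areas are zeroed — masked, not
renormalized: probability mass routed through an impossible state represents
lineages that could not have existed and is simply lost. With identical
geography in every epoch the stratified likelihood equals the unstratified
one to numerical precision.

## Likelihood, fitting, ancestral states

The likelihood is computed by Felsenstein pruning: tip vectors are
indicators of the observed range, daughter vectors are propagated up their
branches and combined through the cladogenesis table of the epoch containing
the node. The root likelihood averages over all non-null states valid at
the root age (uniform root prior; a likelihood-weighted alternative is
provided). Per-node vectors are rescaled by their maximum to avoid
underflow on large trees.

Transition kernels are applied through an eigendecomposition of each
epoch's generator (one decomposition per likelihood evaluation, two matrix–
vector products per branch); if the decomposition fails to reconstruct the
generator to 1e-9 the propagator falls back to scipy's Padé `expm`. The
public `branch_transition` always uses `expm` directly.

Maximum-likelihood fitting runs bounded L-BFGS-B on transformed parameters
(`log d`, `log e`, `log j`; `x` linear) with bounds d, e in [1e-12, 5],
j in [1e-6, 3], x in [-10, 2], from deterministic multi-starts. The default
start set uses 3–4 points covering d/e in {0.01, 0.1} × {0.01, 0.1},
j in {0.01, 0.5} and x in {0, -1}; `OptimizerConfig(full_grid=True)` expands
to the full product (12 starts for DEC+J+x). On the simulated datasets used
here the profile surfaces are unimodal and the reduced start set always
reaches the same optimum; the full grid is retained for harder data.
Non-convergence is flagged on the result rather than raised.

Ancestral-range marginals use the standard up–down algorithm and refer to
the state *at* the node, immediately before its cladogenesis event. A small
set of per-node overrides (fixing a node to a chosen range) can be applied
downstream of the marginal table; no automatic plausibility heuristic is
applied.

## Model comparison

`aicc` implements `-2 lnL + 2k + 2k(k+1)/(n - k - 1)` with `n` the number of
tips (the published 191-tip comparison is reproduced with exactly this
`n`). The comparison table reports, per model, the evidence ratio
`exp(-(AICc_i - AICc_best)/2)` normalized so the best model equals 1, and
relative model probabilities (the same ratios normalized to sum to one,
rendered as whole percents, normalized over all rows of a comparison).
DEC-type models are nested in their +J counterparts, so pairwise
likelihood-ratio tests use a chi-squared reference with df equal to the
parameter-count difference; a full model scoring below its nested model is
clipped to 0 with a warning (an optimizer failure, not evidence).

## Parsimony reconstruction

The assumption-free cross-check treats the tip areas as an unordered
multistate character with uniform unit costs. Change counts come from the
Fitch down-pass; per-node most-parsimonious state sets from the unit-cost
Sankoff dynamic program (every state attained in at least one globally
minimal reconstruction). The Sankoff machinery accepts arbitrary cost
matrices as an extension point. ACCTRAN and DELTRAN resolutions both
realize the minimal change count; event counting defaults to DELTRAN and
additionally reports, per ordered area pair, the number of branches on which
*every* minimal reconstruction forces that exact change — a defensible
lower bound matching "at least N events" phrasing.

Per-area lineage-accumulation tables count, at every `bin_width` (default
2 Myr) age boundary, the branches crossing that age; a branch whose parent
and child resolve to different areas is attributed to the parent's area
strictly above the branch midpoint and to the child's at and below it
(uniform-ignorance placement of the unobserved change).

## The synthetic generator

The simulator emulates the statistical structure of the empirical setting
rather than any particular dataset: a constant-rate birth–death chronogram
conditioned on its extant tip count (default birth 0.4/Myr, death 0);
a linear island arc (default 8 areas) with nearest-neighbour gaps cycling
through 120–280 km, inter-island distances being cumulative gaps expressed
relative to the arc length (maximum 1 — the dimensionless convention under
which the default rates produce realistic event densities); two epochs with
the two youngest islands unavailable before 10 Ma; and DEC+J+x range
evolution by exact Gillespie simulation along branches (epoch-switched at
boundaries) with cladogenetic draws at nodes. The full event log is kept
and replayed to verify that it reproduces the tip ranges.

Microendemic (single-area) tips are produced by a final
contraction-to-singleton (`tip_mode="collapse"`), mimicking taxa observed
only in one area; rejection sampling (`"reject"`) is available but is only
practical for small trees. The recovery harness keeps tips as simulated
(`"as_is"`) so that the fitted model matches the generating process —
collapsing tips censors widespread ranges and would bias `d`/`e` estimates.

What passing the simulation-based tests does *not* show: robustness to
phylogenetic error or dating uncertainty (the tree is known exactly),
detectability of `e` when extinction leaves no signal (with the default
`e = 0.005` the estimate is essentially unidentifiable and pinned near its
bound — only `d`, `j`, `x` are recovered well), or behaviour under range
sizes above the cap.

## Problem sizes used in the shipped checks

Likelihood correctness is verified against brute-force joint enumeration on
trees of up to 4 tips over up to 3 areas (200 random parameter draws).
Parameter recovery uses 25 replicates of 200-tip trees on a 6-area arc
simulated at d = 0.02, e = 0.005, j = 0.2, x = -1; with these conditions the
median relative error of d and j stays under 30% and AICc selects a +J
model in the large majority of replicates. The end-to-end pipeline
demonstration fits all 12 model variants under both stratified and
unstratified geography (24 fits) on a 50-tip, 8-area dataset and is
bit-reproducible under a fixed seed.

## Known limitations

- Only the DEC cladogenesis family is implemented (no BAYAREA- or
  DIVA-style widespread sympatry/vicariance); y/s/v weights are fixed at 1.
- Tips must occupy ranges within the state space; multi-area tip
  *uncertainty* (as opposed to genuine widespread ranges) is not modelled.
- The dense generator limits practical state spaces to a few hundred
  states (about 12 areas at `max_range_size` 3).
- Ultrametric input is required (tolerance 1e-6 Myr); serially sampled tips
  are out of scope.
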