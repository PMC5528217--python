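# flyrange

Host-range dynamics of a phytophagous fruit-fly community around a
biological invasion: phylogeny-aware model selection for community
structure, and bootstrap Hill-number indices of niche breadth and niche
overlap before versus after the invasion.

## Scientific problem

Tephritid fruit flies lay eggs in fruit and their larvae develop inside
it, so rearing flies from field-collected fruit gives a direct per-fruit
measure of which insect exploits which host plant. When a new competitor
invades such a community, resident species may contract their host range
(retreat to preferred hosts) while others are unaffected. Detecting that
pattern from field rearing records raises three coupled problems this
package addresses:

1. **Community structure.** Is host use structured by the fly species,
   the plant species, their interaction, or the plant *phylogeny* (clades
   of related plants being used together)? This is asked of the binary
   plants-by-flies occurrence matrix with clustered binomial-logit GEE
   models compared by QIC.
2. **Niche breadth and overlap.** How many hosts does each fly
   effectively use, and how much do two flies' diets overlap? Answered
   with Shannon number equivalents (Hill numbers) of the interaction
   matrix, with uncertainty from a one-fruit-per-plant bootstrap that is
   robust to extremely uneven sampling depth across plants.
3. **Change detection.** Which flies lost breadth after the invasion,
   and which specific (fly, plant) links weakened?

A synthetic-data generator simulates the whole study design (plant
phylogeny, specialist/generalist/invader guilds, post-invasion diet
contraction, per-fruit counts), so the entire pipeline is testable
end to end against known ground truth.

## Core model

**Occurrence models.** With `p_ij` the probability that fly `i` occurs on
plant `j`, four binomial-logit GEE models are compared:

```
M1: logit p_ij = a + b_i                 (fly effects only)
M2: logit p_ij = a + b_i + c_j           (+ additive plant effects)
M3: logit p_ij = a + b_i + c_j + d_ij    (fly x plant interaction)
M4: logit p_ij = m_ij, one GEE per fly i, all plants in a single
    cluster with fixed working correlation R = Brownian-motion
    correlation from the plant phylogeny; QIC(M4) = sum over flies
```

M1–M3 use plants as clusters with an independence working correlation.
The estimating equations `sum_c D'V^{-1}(y - mu) = 0` with
`V = phi A^{1/2} R A^{1/2}` are solved by damped Newton iteration, with
robust (sandwich) covariances, and models are compared with Pan's
quasi-likelihood criterion

```
QIC = -2 Q(beta) + 2 trace(Omega_I V_robust),
```

where `Q` is the independence binomial quasi-likelihood and
`Omega_I = X'AX`. A QIC gap larger than 10 is treated as decisive.
The Brownian correlation between two plants is the depth of their most
recent common ancestor divided by the geometric mean of their
root-to-tip depths.

**Niche indices.** Each bootstrap replicate draws one fruit uniformly at
random per plant, scales row `j` by the plant's *biotic capacity* `w_j`
(its mean total fly yield per fruit, both periods pooled), and
column-normalizes so each fly's diet `p_i.` sums to 1. Niche breadth is
the Shannon number equivalent

```
D_alpha(i) = exp( - sum_j p_ij ln p_ij ),
```

the count of equally-used hosts with the same entropy. Overlap between
flies `i` and `k` uses the multiplicative Shannon decomposition with
equal weights: `H_gamma` of the mixed diet minus the mean `H_alpha`,
exponentiated to `D_beta in [1, 2]` and rescaled to the turnover index
`T = D_beta - 1` (0 = identical diets, 1 = disjoint diets). Percentile
intervals come from 10,000 replicates; a fly absent from a replicate is
excluded from that replicate (reported as `n_valid_reps`), never imputed.

**Filter.** Only plants with at least 4 sampled fruits in *each* period
enter the analysis.

## Worked example

```python
import numpy as np
from flyrange import (
    RunConfig, ScenarioConfig, simulate_scenario, filter_plants,
    biotic_capacity, bootstrap_indices, compare_periods,
    alpha_diversity, beta_turnover,
)

# analytic indices
print(alpha_diversity([0.5, 0.25, 0.25]))   # 2.82842712474619 (= 2**1.5)
print(beta_turnover([1.0, 0.0], [0.5, 0.5]))  # 0.24080647880279948

# a full simulated study: 36 plants, 7 resident flies + 1 invader
config = RunConfig(seed=1)
dataset, tree, truth = simulate_scenario(ScenarioConfig(seed=1))
dataset = filter_plants(dataset, config).dataset
w = biotic_capacity(dataset)
rng = np.random.default_rng(1)
before = bootstrap_indices(dataset, "before", w, config, rng=rng)
after = bootstrap_indices(dataset, "after", w, config, rng=rng)
changes = compare_periods(before, after).per_fly.set_index("fly_id")
print(changes.loc["GEN1", "delta_d_alpha"])  # -2.748373083194293
print(changes.loc["SOL1", "ci_disjoint"])    # False
```

On this run the three generalists lose breadth (mean change in
`D_alpha` of −2.73 equally-used hosts; the generative truth is −5.24),
no specialist shows an interval-disjoint change, and the invader's
bootstrap turnover against every specialist is exactly
`1.00 [1.00; 1.00]` — it shares no hosts with them.

The same analysis runs from the command line on CSV + newick inputs:

```bash
flyrange simulate --seed 1 --out data/
flyrange validate --samples data/samples.csv --tree data/tree.nwk
flyrange run-all --samples data/samples.csv --tree data/tree.nwk \
    --seed 1 --out results/
```

`run-all` writes the QIC table, per-period diversity reports with
confidence intervals, the before/after change table, flagged weakened
interactions, and a manifest with input/output digests.

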