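# Methods note

This note records the statistical model, its assumptions, the default
parameters and why they were chosen, what the synthetic-data generator
does and does not emulate, the numerical choices, and the known
limitations.

## Data model

The unit of observation is a single field-collected fruit: for each
fruit we record the host plant species, the collection period relative
to an invasion year ("before" / "after"; the invasion year itself counts
as after), and the number of adult flies of each species reared from it.
Plants and flies live in registries that fix a deterministic ordering
inherited by every matrix downstream. Two CSV dialects (wide: one count
column per fly; long: one row per fruit-fly pair) are accepted and
produce identical datasets. The phylogeny is a single rooted newick tree
with branch lengths; tips are matched to plants by an explicit
`tree_tip_label` or, failing that, by `plant_id`.

**Filter.** Only plants with at least `min_samples_before = 4` fruits
before AND `min_samples_after = 4` fruits after the invasion are
retained, regardless of how many flies emerged; all fruits of an
excluded plant are dropped. Four per period is the smallest count at
which a per-plant resampling scheme has any support in both periods
while discarding as little of a sparse field collection as possible.

## Community-structure models (GEE + QIC)

Binary occurrence `y_ij = 1` if at least `presence_threshold = 1` fly of
species `i` emerged from any fruit of plant `j` in the period. Four
binomial-logit models:

- **M1** `a + b_i` — fly effects only;
- **M2** `a + b_i + c_j` — additive plant effects;
- **M3** `a + b_i + c_j + d_ij` — the saturated fly-by-plant
  interaction, coded as one mean per cell;
- **M4** — one GEE per fly species with one parameter per plant, all 36
  plants forming a single cluster whose *fixed* working correlation is
  the Brownian-motion correlation implied by the plant phylogeny;
  `QIC(M4)` is the sum over fly species.

M1–M3 treat plants as clusters with an independence working correlation.
The estimating equations

```
sum_c D_c' V_c^{-1} (y_c - mu_c) = 0,   V_c = phi A_c^{1/2} R_c A_c^{1/2}
```

use the binomial variance `A = mu(1-mu)` and logit link. The dispersion
`phi` is fixed at 1 by default (the binary-data convention; a Pearson
moment estimator is available). The exchangeable correlation, when
requested, is re-estimated each iteration from residual cross-products;
fixed correlations are never re-estimated. Robust covariance is the
sandwich `S^{-1} M S^{-1}` with `M` built from per-cluster scores. Model
comparison uses Pan's criterion

```
QIC = -2 Q(beta_hat) + 2 trace(Omega_I V_robust),
```

`Q` the independence binomial quasi-likelihood (`mu` clipped at 1e-12)
and `Omega_I = X'AX` evaluated at the fitted coefficients. A QIC gap
greater than `qic_delta = 10` between the best and second-best model is
treated as decisive; anything closer is reported "inconclusive" with all
models inside the gap listed.

**Observation unit.** By default one (plant, fly) presence cell is one
observation. This makes M3 and M4 *saturated* (one observation per
parameter); both are then ridge-stabilized (penalty 1e-4) and their
table rows carry a prominent note. An optional per-fruit mode
(`per_sample=True`, CLI `--per-sample`) instead treats each (fruit, fly)
pair as one binary observation — internally aggregated into weighted
binomial cells, which is numerically identical — de-saturating M3 and
giving QIC magnitudes that grow with the number of fruits. Absolute QIC
values are not comparable across modes; only orderings are meaningful.

**A structural limit of QIC here, discovered during implementation.**
M3 and M4 parameterize the *same* cell means. The `-2Q` term is
minimized by the independence fit (M3), because `Q` is exactly the
objective that independence estimation maximizes; any fixed non-identity
working correlation can only move the solution away from that optimum.
Meanwhile both models' sandwich traces collapse: a saturated model
solves every per-cell estimating equation exactly, so per-cluster scores
vanish and `V_robust ≈ 0` (for M4 the single cluster's total score is
zero at any solution, with the same consequence). Hence

```
QIC(M4) >= QIC(M3) - O(ridge),
```

and QIC *cannot* systematically select the phylogenetic working
structure over the independence interaction model, no matter how strong
the phylogenetic clade signal in the data. We verified this empirically:
over 50 simulated communities with clade-confined specialists, M4 never
has the lowest QIC (typical gap ≈ +1 in cell mode), and shuffling the
correlation's plant assignment *shrinks* rather than widens the gap.
This is a known conceptual limitation of QIC — it discriminates mean
structures, not working correlations (that is what CIC was later
proposed for) — sharpened here to an impossibility by the saturation of
both competing models. The corresponding acceptance test is left
failing rather than weakened. The same collapse explains why, with
plants as clusters, QIC also fails to penalize spurious plant main
effects in M2: plant terms are cluster-level, their per-cluster scores
vanish at the solution, and the trace term no longer counts them.

**Phylogenetic correlation.** Under Brownian trait evolution on a rooted
tree, `cov(a,b)` is the depth of the most recent common ancestor of tips
`a` and `b` and `var(a)` is the root-to-tip depth, so the correlation is
`V_ab / sqrt(V_aa V_bb)`. Polytomies need no resolution. Branch lengths
are consumed as given (no ultrametricization). A Pagel-style `lambda`
knob (`scaled(lam)`, default 1) shrinks off-diagonals for sensitivity
analysis. Recently diverged tips give near-singular correlation blocks;
inverses are computed by eigendecomposition with eigenvalues floored at
1e-8 of the largest.

## Niche breadth, overlap, and the bootstrap

Each replicate draws one fruit uniformly at random per plant (in
registry order, from a seeded generator), yielding a raw count matrix
`x` (plants × flies). Row `j` is divided by the plant's *biotic
capacity* `w_j` — its mean total fly yield per fruit, pooled over both
periods — so that hosting many flies of any species does not masquerade
as specialization. Each column with a nonzero total is divided by that
total, giving diet distributions `p_i.` summing to 1; an all-zero column
is marked invalid for the replicate and excluded from that fly's index
pools (reported via `n_valid_reps`), never imputed as monophagy.

Breadth: `D_alpha(i) = exp(-sum_j p_ij ln p_ij)` (natural log,
`0 ln 0 = 0`), ranging from 1 (monophagy) to the number of plants.
Overlap for a pair: `H_alpha = (H(p)+H(q))/2`, `H_gamma = H((p+q)/2)`,
`D_beta = exp(H_gamma - H_alpha) in [1,2]`, turnover
`T = (D_beta - 1)/(N - 1)` with `N = 2` communities, clipped to [0,1]
against floating-point drift. The mixing weight 1/2 and `N = 2` encode
the design decision that a pairwise comparison involves exactly two
equally weighted communities.

Defaults: `bootstrap_reps = 10,000` and 2.5%/97.5% percentile intervals
(a conventional 95% band; 10,000 replicates make the percentile
estimates stable to well under the atom spacing of small problems).
Before/after change is flagged when the two percentile intervals are
disjoint — the only notion of significance this bootstrap supports; it
is conservative relative to a test on the difference. Weakened links are
(fly, plant) cells whose bootstrap-mean proportion dropped by at least
`decrease_threshold = 0.10` between periods.

The one-fruit scheme deliberately discards within-plant sample size: a
plant sampled 300 times and one sampled 4 times contribute equally to
every replicate. This costs efficiency but removes the dominance of
heavily sampled plants and makes replicates exchangeable across plants.

## Synthetic-data generator

The generator emulates the *design* of a long-term rearing study:

- a pure-birth (Yule) phylogeny of `n_plants = 36` tips in
  `n_families = 15` families, two disjoint clades of 4–7 tips hosting
  the specialist guilds;
- seven resident flies (three generalists, three cucurbit specialists,
  one solanum specialist) plus one invader present only after the
  invasion, with per-fly mean loads of 3–6 flies on the most preferred
  host;
- generalist diets drawn on 12–20 non-specialist-clade hosts
  (Gamma(1) weights), specialist diets on their clade (Gamma(2)
  weights), the invader on 8–12 of the generalists' top hosts with
  strongly skewed weights (Gamma(0.25));
- after the invasion every generalist diet is contracted by raising
  preferences to `1/contraction_factor` (default 0.5) and renormalizing
  — a smooth shift of mass toward preferred hosts; specialists are
  unchanged;
- per fruit, counts are Poisson (optionally gamma-mixed negative
  binomial) with mean `mean_load * pref / max(pref)`, conditionally
  independent across fly species given the plant; 5–30 fruits per plant
  and period.

It does **not** emulate: seasonality or within-period time structure,
spatial sites, fruit size/weight effects, between-fly interaction at the
fruit level (competition within a fruit), observation error in species
identification, or phylogenetic correlation in the *residuals* of
occurrence (host use is phylogenetically structured only through the
specialists' clade confinement). That last point matters when
interpreting the model-selection experiment above: even the generative
model contains no residual tree-structured correlation for a working
correlation to exploit.

Ground truth (`true_indices`) exposes the exact `D_alpha` and pairwise
`T` of the generating diets for calibration of the estimators.

## Numerical choices

- GEE solved by damped Newton iteration on the estimating equations with
  a backtracking line search on the penalized score norm; convergence
  when the score norm falls below 1e-8 or the step falls below 1e-8
  (max 200 iterations; non-convergence is flagged, not raised).
- Separation: |linear predictor| > 30, or a creeping predictor (still
  strictly increasing after 20+ iterations beyond |eta| = 12), engages a
  ridge penalty of 1e-4 and flags the fit. Saturated designs (M3/M4 in
  cell mode, per-plant means in M4) are ridge-stabilized from the start.
- Sandwich covariance computed as `L L'` with `L = S^{-1}(scores/phi)`,
  positive semidefinite by construction even for ill-conditioned
  saturated fits.
- Fixed correlation blocks inverted via eigendecomposition with a
  relative eigenvalue floor of 1e-8 (near-singular blocks arise from
  recently diverged tips).
- `mu` clipped at 1e-12 inside the quasi-likelihood.
- The bootstrap is fully vectorized (replicates × plants × flies) with
  one seeded generator streamed plant-by-plant in registry order, so
  results are reproducible and independent of chunking.

## Open design decisions

- Cell-level presence is the default GEE observation unit; per-fruit
  mode is available behind a flag. QIC magnitudes differ by orders of
  magnitude between modes; only orderings are interpretable.
- Turnover uses `N = 2` (a pairwise comparison) and equal community
  weights; other weightings would give a different `H_gamma`.
- Biotic capacity pools both periods into a single `w_j` so that the
  before/after comparison is not confounded by a change in the
  denominator.
- The invasion year itself is classified "after".
- Samples from a plant excluded by the filter are dropped entirely
  rather than pooled elsewhere.

## Limitations

- QIC cannot certify the phylogenetic model against the saturated
  independence interaction model (see above); the M4 row is reported for
  completeness and its QIC should be read with that structural caveat.
- The percentile bootstrap has no second-order accuracy guarantees here;
  with very uneven fruit yields its intervals can be wide.
- `D_alpha` of a fly observed in few replicates (small `n_valid_reps`)
  is biased toward small values: single-fruit draws see only hosts that
  yielded flies that draw.
- The GEE assumes occurrence cells are missing-at-random given the
  design; systematic non-collection of some plant/period combinations
  would bias both the occurrence models and the capacity weights.
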