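# Methods

This note documents the models, numerical choices and deliberate design
decisions behind `canopyweb`, in the spirit of a package methods appendix.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Interaction matrices

Occurrence counts are aggregated to the **tree-species** level (network nodes
are host species and caterpillar morphospecies, not individual trees). The
orientation is fixed — rows = hosts (lower trophic level), columns =
herbivores — because the sign of web asymmetry and the duality of
generality/vulnerability depend on it. Host species censused but carrying no
herbivores are dropped by default (the realized web of the bipartite
tradition); `build_matrix(..., keep_empty_hosts=True)` retains them. Only
living, species-identified trees and confirmed host associations survive
`prune_dataset`, which is idempotent.

## 2. Network statistics

Connectance and nestedness temperature operate on the binarised web;
generality and vulnerability use counts; 0·log 0 := 0; entropies use natural
log with `exp` (identical to 2^H with log₂). Undefined metrics are NaN, never
silent zeros: an empty web raises, a single-row/column web has no packing
freedom and gets NaN temperature.

### Nestedness temperature

The packed presence–absence matrix is mapped onto the unit square (cell
centres at `((j+0.5)/n, (i+0.5)/m)`, packed corner top-left). The isocline of
perfect order is the superellipse `x^p + y^p = 1`, with `p` solved (Brent)
so the enclosed area `Γ(1+1/p)² / Γ(1+2/p)` equals the matrix fill. A
presence outside the isocline, or an absence inside it, is *unexpected* and
scores the squared distance from the cell centre to the isocline along the
45° diagonal through the cell, normalised by that diagonal's length inside
the square (vectorised bisection for the crossing point). Temperature is the
mean unexpectedness scaled by 100/0.04145 — the conventional constant mapping
the maximally disordered matrix to 100 — and clipped to [0, 100]. A
completely filled matrix is exactly 0.

**Packing** is deterministic and seed-free, replacing stochastic
genetic-algorithm packers. The key observation: the temperature of an
ordering is a sum of per-row (per-column) contributions that depend only on
the line's content and its position, so *given* one side's order, the optimal
order of the other side is a linear assignment problem (Hungarian
algorithm). Matrices whose smaller side has ≤ 5 lines are packed **exactly**:
all orderings of the smaller side are enumerated and the other side is
solved by assignment — this covers every web the acceptance-scale
enumeration can check and guarantees the global optimum there. Larger
matrices are packed by alternating optimal row/column assignments from a
marginal-totals seed (ties broken by label) until no strict improvement: a
descent whose result never exceeds the seed ordering's temperature. A
greedy adjacent-swap (or even all-pairs-swap) hill climb was rejected: it
demonstrably sticks in local minima on a few percent of random 4×4
matrices.

## 3. Sampling simulation

- Pooling records the mean total foliage per plot, the numerator of the
  rarefaction quota `F_thresh = mean plot foliage / n_selected`.
- Threshold selection takes the *smallest* foliage-descending prefix whose
  cumulative share ≥ q (deterministic and monotone in q); foliage ties break
  by species label. The family rule takes, per family with ≥ 200 m² sampled
  foliage, its single most foliage-rich species.
- Rarefaction visits a species' trees in uniform random order; trees before
  the quota crossing enter whole; the crossing tree enters with fraction
  `f = (F_thresh − accumulated)/foliage` and contributes
  `round_half_up(f · C_f)` of its `C_f` caterpillar individuals, drawn
  uniformly without replacement. Half-up rounding fixes the tie rule
  platform-independently. If the quota lands exactly on a tree boundary the
  tree enters whole (f = 1). Species with total foliage below the quota
  enter in full and are flagged (`shortfall`) rather than discarded —
  discarding would silently shrink the design. Fractional trees contribute
  fractional foliage to the bookkeeping, which is what makes included
  foliage equal the quota exactly (tested to 1e-9 relative).
- Replicate r draws from `numpy` generator seeded `base_seed + r`, so runs
  are reproducible, parallelisable, and any prefix of replicates is stable
  when `n_reps` changes.
- Confidence intervals: percentile (2.5/97.5) across the 100 scheme
  replicates (distribution-free); Student-t across the handful of plot
  baselines, where percentiles of n = 8 values are meaningless. Both are
  selectable. Degenerate (empty-web) replicates are excluded per metric with
  a logged count, never zero-filled. The plot baseline treats each plot's
  web as one observation — the plots are samples of the forest, not
  replicates of a randomised procedure.

## 4. Synthetic census generator

The generator emulates the statistical structure of an eight-plot (0.1 ha)
tropical highland primary-forest caterpillar census. Its defaults restate
census-level summary statistics of the emulated site and standard
community-ecology shapes; none are fitted to outputs.

| parameter | default | basis |
|---|---|---|
| plots | 8 × 0.1 ha | emulated design |
| tree species / morphospecies | 113 / 186 | emulated census |
| stems per plot | N(133, 62²) trunc ≥ 1, rounded | census mean ± SD |
| foliage per plot | N(3591, 620²) m² trunc > 0 | census mean ± SD |
| caterpillars per plot | Gamma(mean 1103, SD 862) | census mean ± SD; see below |
| rank-abundance curve | lognormal quantiles, σ = 1.3 | see below |
| families | 30, lognormally skewed sizes | typical of such floras |
| host-specificity mixture | 50% mono / 35% oligo / 15% generalist | free parameter (grid below) |
| oligophage / generalist mean host range | 4 / 15 species | plausible ranges |
| host-set abundance bias | abundance², family-clustered (P = 0.6) | resource concentration |
| brood size | geometric, mean 3 | gregarious clutches |
| per-stem foliage | lognormal σ = 0.8, rescaled to plot total | tree-size variation |

Notable choices:

- **Deterministic rank-abundance curve.** Relative tree-species abundances
  are lognormal *quantiles* (σ = 1.3), not i.i.d. draws: the SAD's shape is
  a fixed property of the site, and i.i.d. draws made the top-species share
  swing so widely that the 20% threshold sometimes selected a single species
  (a degenerate single-row web). σ = 1.3 makes the foliage ranking select
  3 / 8 / 18 / 38 species at the 20/40/60/80% thresholds, close to the
  3 / 7 / 15 / 31 of the emulated census. Seed-to-seed variation remains in
  family assignment, stem placement, foliage and herbivore draws.
- **Gamma caterpillar loads.** At CV ≈ 0.78 a truncated normal either clamps
  ~10% of plots to degenerate single-caterpillar censuses (clipping) or
  inflates the realized mean by ≈ +170 (rejection); a gamma with the
  configured mean and SD is strictly positive, honours both moments exactly
  and is the standard overdispersed count model. Stems and foliage keep
  truncated normals — at their CVs the truncation bias is < 1 unit.
- **Resource concentration.** Host-set membership is drawn with weight
  ∝ abundance² (and oligophage/generalist sets clustered in the first
  host's family), and a herbivore's regional commonness is proportional to
  the total abundance of its hosts times lognormal noise — specialists of
  rare plants are themselves rare. Together these express the documented
  premise that locally abundant tree species harbour disproportionately
  diverse herbivore faunas; with weight ∝ abundance¹ the generator does not
  express it and the richness ranking of the sampling schemes is essentially
  flat.
- **Uniform sampling density.** Individuals land on trees foliage-
  proportionally (tree-first), then broods get a morphospecies ∝ commonness ×
  membership. This keeps caterpillar density per m² constant across hosts —
  the plot-census premise — while letting each tree's fauna reflect its
  species' resident pool. Weighting tree intensity by membership *sums*
  (the obvious alternative) makes density scale with host popularity and
  starves rare hosts of their specialists.
- **Broods.** Conspecific individuals arrive in geometric clutches
  (mean 3), giving the overdispersed per-tree counts real caterpillar
  censuses show; independent placement produced unrealistically dense,
  link-rich webs.

**What the generator does not emulate:** real species identities or
phylogeny, spatial autocorrelation between plots, secondary-forest plots,
seasonality, and any guild other than leaf-chewers. A green direction-of-bias
test therefore establishes that the *mechanisms encoded here* reproduce the
qualitative sampling artefacts — not that they are the mechanisms operating
in any particular forest.

### Host-specificity grid

The true specificity distribution of the emulated fauna is unknown, so the
direction-of-bias acceptance test runs in two documented worlds:
(monophage, oligophage, generalist) = **(0.50, 0.35, 0.15)** and
**(0.60, 0.30, 0.10)**, three generator seeds each, 100 replicates per
scheme. The qualitative claims checked: every selective scheme exceeds the
plot baseline in mean connectance, web asymmetry and nestedness temperature,
and the 20% scheme has the highest mean caterpillar richness among the
selective schemes.

## 5. Field calculators

Leaf area per tree: `fresh weight × (frame area / frame weight)` for felled
trees (with a `defoliated_fraction` argument extrapolating partial
defoliation to the whole crown), or `estimated leaf count × (frame area /
frame leaf count)` for standing trees; the caller supplies the already
averaged visual count. Gall abundance: mean of 3–5 per-branch galls-per-leaf
values × total leaves, half-up rounded; outside 3–5 branches the protocol
bound raises. Efficiency: ASE = person-hours × (0.1/plot area),
RSE = person-hours / sampled foliage (NaN when foliage is 0), accessibility
= fraction × 100. The arcsine (proportions) and log (efforts) transforms are
provided as pure helpers; no mixed-model fitting is included.

## 6. Known limitations

- The alternating-assignment packer is exact only when one matrix side has
  ≤ 5 lines; above that it is a descent with no global-optimality guarantee
  (temperatures may be slightly over-estimated for large sparse webs).
- The temperature normalisation constant 0.04145 is the conventional one;
  temperatures are comparable within this implementation but can differ by
  a few degrees from other packers on the same matrix.
- Percentile CIs from 100 replicates have Monte-Carlo noise of a few
  percent in the bounds; seed layouts are fixed to make this reproducible.
- The generator's mixture and bias parameters are stated-world choices, not
  estimates; conclusions about real censuses require real census tables.
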