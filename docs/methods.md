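# Methods

## Data model

A pollinator census is a timed watch of one plant species: the insect taxa
contacting flower reproductive parts, the visit count, the number of flowers
watched and the duration. Censuses are pooled across dates and years before
any index is computed; the interaction frequency of a (plant, pollinator)
pair is the *pooled ratio* — total visits over total flower·minutes — not
the mean of per-census rates. The pooled ratio equals the frequency one
would obtain from summed field totals and absorbs differing census lengths
(3- vs 5-minute protocols) through the per-flower-per-minute normalization.
Zero-visit censuses are accepted on input; they add sampling effort but no
link.

Seed-set experiments pair open-pollinated flower units (OP) with mesh-bagged
units that exclude insects but admit wind- and self-pollination (PE). Mean
seed set per treatment pools flower units across individual plants of a
species; the dependence index is computed from these species-level means,

    IPD = 100 (SS_OP − SS_PE) / SS_OP,

clamped below at zero because sampling noise can make the exclusion mean
exceed the open mean in plants with no real insect contribution. IPD is
undefined (an error, not a zero) when a species set no seed under open
pollination.

## Specialization indices

- **L**: count of pollinator species with positive frequency.
- **H**: Shannon–Wiener diversity of the plant's frequency distribution, in
  natural-log units. `H ≤ ln L`, with equality at uniform frequencies.
- **CC**: closeness in the unweighted plant–plant projection (adjacency =
  shared pollinator), `(p − 1)/Σ d`. In a disconnected projection any node
  with an unreachable peer is assigned CC = 0, the common convention in
  social-network analysis; observed community networks are connected, so
  this only affects degenerate inputs.
- Network-level: `S = p·a`, links, `I = links/(p + a)`, `H₂` over all link
  weights, `E₂ = H₂/ln(links)`. The `E₂` denominator is not uniquely pinned
  down by convention; `ln(links)` is the one consistent with both published
  community values (0.80 and 0.82) to within one unit of their printed last
  digit, and is what a maximum-evenness argument gives (uniform weights over
  k links ⇒ H₂ = ln k ⇒ E₂ = 1).

All logarithms in the package are natural. The published species table's H
values (up to 3.04 at L = 41) are only consistent with nats.

## Regression

OLS fits `IPD ~ x` or `IPD ~ x + x²` with `x` the index or its natural log;
the log transform is applied to linkage level by default (right-skewed
degree distributions). Only the predictor is ever transformed. The reported
estimate, SE, t and two-sided p always refer to the linear term. Model
retention, when both forms are fit, keeps the higher R², ties broken by the
lower p. A constant response returns slope 0 with t = 0 and p = 1 rather
than the numerically meaningless t that floating-point residuals would give.

The phylogenetic fit is Gaussian GEE with a fixed working correlation,
identical to GLS: `β = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y` with `V = φ·corr`, the scale φ
estimated as the whitened residual sum of squares over `n − k`. The
correlation comes from a Brownian-motion model on the community tree:
`cov(i, k)` is the root-to-MRCA path length and
`corr(i, k) = cov(i, k)/√(t_i t_k)`, which normalizes non-ultrametric
inputs. Slope t-tests use phylogenetic degrees of freedom

    dfP = n · (total branch length) / (Σ root-to-tip distances),

minus the parameter count; a star tree gives dfP = n and then the GEE test
coincides with OLS. Polytomies are resolved randomly (seeded) into
bifurcations with zero-length edges; because inserted edges have zero
length this leaves the correlation matrix exactly unchanged. Branch lengths
missing from a newick input default to 1, since family-level megatrees
often carry topology only.

The bootstrap draws species rows (x, y jointly) with replacement up to a
target sample size — 27, the size of the larger community — refits the
same specification per replicate, and reports the fraction significant at
α = 0.05. The transform decision is fixed across replicates. A replicate
with zero predictor variance or an exact fit with zero slope is counted
non-significant; an exact fit with nonzero slope is counted significant.

## Synthetic data

The generator emulates the structure of the field data, with defaults set
to the coastal-dune studied subweb: 27 plants × 126 pollinators at
connectance 0.112 (384 links), skewed plant degrees (propensities
`u^−skew`, u uniform; skew 0 recovers near-uniform degrees), log-normal
link frequencies around 0.005 visits·flower⁻¹·min⁻¹ (σ = 1.5). Dependence
follows

    IPD*_i = clamp(β₀ + β₁ ln L_i + ε_i, 0, 100)

with β₀ = 5, β₁ = 25 and residual sd 30, matching the fitted slope and
scatter of the coastal community; a `lambda_phylo` share of the residual
variance can be drawn Brownian on a supplied tree. Observed seed counts are
Poisson per flower unit (10 seeds/unit baseline, 30 units per treatment);
exclusion units are the same latent Poisson yield thinned binomially with
retention `1 − IPD*/100`, so the expected observed IPD equals the latent
one and counts are integers. Trees are ultrametric Yule simulations of
unit height.

What the generator does *not* emulate: visit-level pollen transfer and
pollinator effectiveness, temporal turnover of interactions, per-individual
variation in floral display, pollen limitation, and year effects. Passing
tests therefore demonstrate correctness of the estimators under the stated
sampling model, not robustness to these field realities.

The parameter-recovery check uses a deliberately linear-regime scenario
(β₀ = 40, β₁ = 10, sd 10) in which clamping at 0/100 is negligible;
under the study-scale defaults the clamp attenuates fitted slopes, which is
a property of the index's bounded range, not an estimator defect.

## Problem sizes

Test simulations use the study-scale community (27 × 126): 100 seeds for
power, 500 for the type-I rate, 200 for confidence-interval coverage, 1000
bootstrap replicates — the same replicate counts as the analyses they
check.

## Reproducing printed values: known limits

- The four ln(L)/H/CC slope–t pairs recomputed from the packaged species
  table match the published regression table exactly for the ln(L) rows
  (L is an integer, so nothing is lost to rounding): 23.506 (t = 3.082)
  and 5.768 (t = 0.674). The H and CC rows differ in the third digit
  (24.451 vs 24.429; 189.28 vs 187.58) because the species table prints H
  and CC to two decimals while the original regressions used unrounded
  index values. These recomputed values are the correct ones *given the
  printed table*; the tests that pin the printed third-decimal values for
  H and CC document the discrepancy by failing.
- Published GEE coefficients depend on the exact community trees, which are
  not distributed; the GEE estimator is instead validated by its identity-
  correlation limit (equals OLS to 1e-8), the star-tree dfP limit, and
  simulation-based coverage of the generating slope.
- The published mean links per species for the coastal site (2.87 from
  696/242 = 2.876) appears truncated rather than rounded; checks allow one
  unit of the last printed digit.
- The published network size for the mountain site (8464 = 92²) contradicts
  its own plant and pollinator counts (34 × 92 = 3128). The package always
  computes `S = p·a`; the printed value is not reproduced.

## Limitations

Nestedness, modularity, d′ specialization and null-model randomizations are
out of scope, as are pollen-limitation endpoints and per-year dependence
estimates. Species matching between census and seed-set inputs is exact
(case-sensitive after whitespace trimming); synonymy must be resolved
upstream.
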