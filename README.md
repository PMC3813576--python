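# pollindep

Does a plant's position in a pollination network predict how much it
actually *needs* its pollinators? `pollindep` is a Python package for
ecologists who have (i) timed pollinator censuses across a plant community
and (ii) pollinator-exclusion seed-set experiments, and who want to relate
species-level network specialization to functional dependence on insect
pollination — with phylogenetic relatedness controlled for.

## The quantities

From the pooled censuses a weighted bipartite network is built with cell
weights

    n_ij = (total visits by pollinator j on plant i) / (total flower·minutes observed)

i.e. visits per flower per minute. For each plant *i* the package computes

- **L** — linkage level, the number of pollinator species it interacts with;
- **H** — Shannon–Wiener diversity of its interaction frequencies,
  `H = −Σ_j p_j ln p_j` with `p_j = n_ij / Σ_j n_ij` (nats);
- **CC** — closeness centrality in the unipartite plant–plant projection
  (plants adjacent when they share ≥ 1 pollinator),
  `CC = (p − 1) / Σ_k d(i, k)`;

and network-level descriptors `S = p·a`, total links, mean links per species
`I`, interaction diversity `H₂` and evenness `E₂ = H₂ / ln(links)`.

From the exclusion experiment, with `SS_OP` and `SS_PE` the mean viable seeds
per flower unit under open pollination and under insect exclusion,

    IPD = 100 · (SS_OP − SS_PE) / SS_OP   (clamped below at 0)

is the percentage of seed set attributable to insect interactions.

IPD is then regressed on each index by OLS (optionally with a quadratic term
or a natural-log transform of the predictor) and by Gaussian GEE with a fixed
Brownian-motion working correlation derived from a community phylogeny —
equivalently generalized least squares with `V = φ·corr` — whose slope tests
use phylogenetic degrees of freedom
`dfP = n · (total branch length) / (Σ root-to-tip distances)`. A bootstrap
procedure resamples a small community with replacement up to a larger sample
size and reports the fraction of replicates whose slope is significant.

The package ships the published per-species table of the two Mallorcan study
communities (coastal dune **SB**, 27 species; mountain shrubland **PM**, 11
species) as a fixture, and a synthetic-data module that generates networks,
seed-set experiments and Yule trees with known ground truth.

## Worked example

```
$ pollindep regress --site SB
response variable type   estimate        se        t        p       r2   df  n
     IPD  log (L)   LM  23.505307  7.626067 3.082232 0.004951 0.275366 25.0 27
     IPD        H   LM  24.451431  9.689253 2.523562 0.018345 0.203019 25.0 27
     IPD       CC   LM 189.277123 64.344275 2.941631 0.006944 0.257128 25.0 27
```

In the coastal community every specialization index predicts dependence:
each extra natural-log unit of linkage level raises expected IPD by ~23.5
percentage points (p = 0.005), and the H and CC slopes are likewise positive
and significant — generalist, central plants are the ones that rely most on
their insects for seed set.

```
$ pollindep bootstrap --site PM --seed 0
predictor  n_boot  n_target  alpha  frac_significant  seed
  log (L)    1000        27   0.05             0.196     0
        H    1000        27   0.05             0.267     1
       CC    1000        27   0.05             0.042     2
```

Resampling the 11 mountain species up to n = 27 leaves the regressions
non-significant in the large majority of replicates (20%, 27% and 4%
significant), so the absence of a relationship there is not a simple
power artifact.

Other subcommands: `network-metrics` and `dependence` compute the indices and
IPD from raw census/seed-set CSVs, `simulate` writes a synthetic community
with a ground-truth sidecar, and `run` drives the whole pipeline from a flat
key=value config file (GEE rows appear when a newick tree is supplied). All
of this is equally usable as a library; see `pollindep.run_pipeline`.

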