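# assemblage-dnci

Community-assembly inference for presence/absence occurrence data:
from site×taxon incidence matrices through sampling-coverage assessment and
cluster validation to permutation-based SIMPER null models and the
dispersal–niche continuum index (DNCI).

The package is aimed at paleoecologists and community ecologists who work
with binary occurrence tables — fossiliferous *levels* (stratigraphically
bounded sampling units) by taxa, or any site-by-species incidence matrix —
and want to ask whether the taxonomic differences between groups of samples
are better explained by **niche processes** (deterministic environmental
filtering; stable, closed communities) or by **dispersal processes**
(stochastic immigration and loss; open, churning communities), or by both.

## The method

Given two clusters of levels, SIMPER decomposes the overall average
dissimilarity (OAD) between them into per-taxon contributions. With binary
data the pairwise dissimilarity between levels *j* and *k* is

    d_jk = Σ_i |x_ij − x_ik| / Σ_i (x_ij + x_ik)

and taxon *i*'s share of the pair is `|x_ij − x_ik| / Σ_i (x_ij + x_ik)`.
Averaging over all between-cluster pairs gives OAD and per-taxon percent
contributions; sorted in decreasing order these form the empirical **SIMPER
profile**.

The empirical profile is compared with profiles from randomised matrices
under three constraint schemes:

* **dispersal null** — column (taxon) totals fixed, occurrences shuffled
  across levels: taxon occurrence frequencies (a dispersal-ability
  signature) are kept, site structure is destroyed;
* **niche null** — row (level) totals fixed, occurrences shuffled across
  taxa: level richness (a local niche-capacity signature) is kept, taxon
  identity structure is destroyed;
* **both margins fixed** — the curveball trial-swap algorithm (diagnostic).

The fit of each null is `E = log10 Σ_r (P_emp(r) − P_perm(r))²` over profile
ranks; the better a null reproduces the empirical profile, the lower its E.
The DNCI contrasts the two single-constraint nulls per permutation,

    DNCI_m = (E_dispersal,m − E_niche,m) / s,

with *s* the pooled standard deviation of all E values; the reported index
is the mean with a ±2·SD interval. **Significantly negative ⇒
dispersal-assembled; significantly positive ⇒ niche-assembled; interval
overlapping zero ⇒ both.** Because uneven cluster sizes bias the index
toward zero, the larger cluster is subsampled to the smaller size (100×
by default) whenever sizes differ.

Supporting stages: sampling effort is quantified as S_obs/S_ex with the
incidence-based Chao2 asymptotic richness estimator and a ratio-of-counts
(Clopper–Pearson) confidence interval; clusters are defined by Jaccard
dissimilarity + UPGMA with a silhouette-chosen cut, singleton clusters are
removed, and the partition is validated with ANOSIM before any DNCI is
attempted. A seedable synthetic-metacommunity generator (Gaussian
coenocline niche component, occupancy-lottery dispersal component,
taphonomic thinning) makes every stage testable without real data.

## Worked example

```python
from assemblage_dnci import (SimulationConfig, simulate, chao2_extrapolate,
                             jaccard_matrix, upgma, assign_clusters, anosim,
                             dnci_pair)

ds = simulate(SimulationConfig(regime="dispersal", seed=1))
m = ds.matrix                       # 40 levels x 80 taxa, 606 occurrences

cov = chao2_extrapolate(m)
# S_obs=80, S_ex=81.56, ratio=0.981, CI=(0.708, 1.344)

d = jaccard_matrix(m)
res = assign_clusters(upgma(d), d)
r, p = anosim(d, res.assignment, n_perm=999, rng=1)
# k=2, no singleton removals, ANOSIM R=0.625, p=0.0040

g = ds.groups
out = dnci_pair(m, g["1"], g["2"], n_perm=1000, rng=1)
# DNCI=-1.986, CI=(-2.323, -1.649) -> "dispersal"
```

Reading the numbers: the simulated metacommunity was assembled as a pure
occupancy lottery, so sampling is essentially complete (S_obs/S_ex ≈ 0.98),
the two level clusters are statistically distinguishable (ANOSIM p < 0.05),
and the DNCI interval is entirely negative — the dispersal null reproduces
the empirical SIMPER profile far better than the niche null, correctly
recovering the planted regime.

The same analysis runs end-to-end from a config file:

```bash
assemblage-dnci run --config config.yaml --out results/ --seed 42
```

which executes, per dataset and stage: metadata filtering (e.g. keep
offshore, non-oxygen-stressed levels) → stage split → coverage → Jaccard →
UPGMA → silhouette cut → singleton removal → ANOSIM gate → multigroup DNCI,
and writes `report.json`, `report.tsv` and a DNCI interval plot. Individual
stages are exposed as `validate`, `coverage`, `cluster`, `dnci`, `simulate`
and `report` subcommands.

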