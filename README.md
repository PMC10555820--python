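# hydrisk

Phylogeny- and niche-based imputation of plant hydraulic traits, mapping of
species-assemblage hydraulic risk, and presence/background models of
drought-induced mortality (DIM).

## The problem

Xylem traits that govern drought survival — the minimum xylem water
potential a species experiences (P_min), and the potentials at 50% and 88%
loss of hydraulic conductivity (P50, P88; all MPa, negative) — are measured
for only a tiny fraction of woody species. Yet the hydraulic safety margin

    HSM = P_min − P50        (P88 for angiosperms in the 50/88 variant)

and its distribution across the species co-occurring at a site are exactly
what one needs to ask where drought-induced die-off is likely. `hydrisk` is
for ecologists who want to:

1. **Impute** species-level P_min/P50/P88 from phylogenetic principal
   coordinates (classical PCoA of cophenetic distances on a genus-level
   tree) and edaphoclimatic niche components (PCA of range-mean
   environments), using an iterative random-forest imputer with repeated
   cross-validation over predictor sets and two tiers of uncertainty;
2. **Aggregate** imputed traits over species ranges into per-pixel
   assemblage metrics — mean(−HSM), minimum HSM, HSM variance, the number
   of species with HSM < 0, richness;
3. **Relate** those metrics to mortality occurrence with balanced,
   background-resampled binomial/Poisson GLMs (Nagelkerke pseudo-R²,
   cross-validated AUC, Mantel residual checks, per-biome trends); and
4. **Project** DIM occurrence probability with a from-scratch hinge-feature
   maximum-entropy model (L1-regularized Gibbs fit, jackknife variable
   contribution, permutation importance, repeated stratified evaluation,
   and an a/b/c model-comparison suite).

A first-class synthetic-world generator produces phylogenies, environments,
niche-derived ranges, traits with known phylogenetic + environmental
signal, sparse observation, and metric-driven mortality — so the whole
pipeline runs and is tested without any external data. See
`docs/methods.md` for the model details and assumptions.

## Worked example

```python
from hydrisk import SyntheticWorldConfig, simulate_world, cross_validate_specs
from hydrisk.pipeline import feature_table, default_specs

world = simulate_world(SyntheticWorldConfig(seed=0))   # ~500 species, 40x40 grid
features = feature_table(world)                        # clade + 5 PCoA axes + 5 PCs + traits
report = cross_validate_specs(features, default_specs(), test_fractions=[0.2],
                              reps=6, seed=0)
print(report[["spec", "trait", "mean_r2", "sd_r2"]])
```

prints (seed 0):

```
              spec  trait   mean_r2     sd_r2
0  phylo+env+clade  p_min  0.569091  0.195381
1  phylo+env+clade    p50  0.727362  0.230506
2       phylo_only  p_min  0.231109  0.153251
3       phylo_only    p50  0.300154  0.123402
4         env_only  p_min  0.343322  0.224677
5         env_only    p50  0.626534  0.206935
```

Read: hiding 20% of the observed trait values and imputing them back, the
predictor set combining phylogenetic coordinates, environmental components
and clade explains ~57–73% of held-out variance (squared Pearson
correlation), and beats either single-family predictor set — the imputation
regime in which genus membership and niche jointly carry the signal. From
here, `impute_traits_ensemble` completes the table with per-species
uncertainty, `hydrisk.assemblage` turns it into risk maps, and
`hydrisk.mortality` / `hydrisk.maxent` relate and project mortality.

The same pipeline runs from the shell:

```bash
hydrisk run-all --config world.yaml --seed 0 --out run/
```

writing the tree (Newick), trait tables (CSV), environment and metric
layers (CSV grids), mortality points (CSV) and a manifest with per-file
hashes — re-running with the same config and seed is byte-identical.

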