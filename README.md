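# fastslow

Trait-based community sensitivity analysis for marine fish assemblages:
rank species along fast–slow life-history continua, integrate the ranks with
presence/absence survey data, and map how "slow" (fishing-sensitive) and
"fast" (resilient) assemblages are distributed in space and time.

## The problem

Marine fish species differ enormously in life-history speed. At one end sit
small, short-lived, early-maturing, highly fecund species; at the other,
large, long-lived, late-maturing species producing few, large offspring.
Position on this fast–slow continuum predicts demographic resilience: slow
species recover poorly from elevated mortality, so assemblages dominated by
slow species are especially sensitive to fishing. In rapidly warming
high-latitude shelf seas, warm-affinity (boreal) species — which tend to be
slower — expand into formerly Arctic areas ("borealization"), moving the
sensitive assemblages poleward.

`fastslow` implements the full analysis chain for quantifying this:

1. **Life-history matrix.** Six traits per species — longevity (yr), age at
   maturity (yr), maximum length (cm), length at maturity (cm), fecundity
   (offspring · female⁻¹ · yr⁻¹), offspring size (mm) — log₁₀-transformed and
   z-scored.
2. **Ordination and ranking.** A PCA of the standardized matrix gives the
   primary fast–slow axis (**FS 1**, ranks 1 = fastest … *n* = slowest). A
   redundancy analysis (RDA) constrained on maximum length removes
   size-driven covariation: its residual PC2 is a size-corrected fast–slow
   axis (**FS 2**) and residual PC1 is the offspring size-and-number
   trade-off (**OSN**, high rank = many small offspring). Variance is
   partitioned as `constrained + Σ residual = 1`.
3. **Phylogenetic structure.** A rank-based taxonomy tree (superclass →
   species, unit branch lengths) supports Faith's phylogenetic diversity
   (PD), phylogenetic dispersion (PDis = residuals of PD ~ SR), and
   Blomberg's *K* with a tip-shuffling permutation test for phylogenetic
   signal in the rank vectors.
4. **Community indices.** Survey stations (presence/absence) are filtered
   (species absent in more than 2 survey years, or never caught at 50–500 m,
   are excluded) and summarized per station-year: species richness, mean
   FS 1 / FS 2 / OSN rank, PD, PDis.
5. **Space and time.** Indices are interpolated by universal kriging
   (linear drift, WLS-fitted semivariogram) and modelled by Gaussian GLMs
   against bottom temperature and depth with polynomial coordinate terms.

A fully ground-truthed synthetic-data generator (`fastslow.simulate`)
emulates a boreal–Arctic species pool and a multi-year warming survey, so
every stage is testable without any external data.

## Worked example

```python
import fastslow as fs

cfg = fs.SimulationConfig()                      # 76-species pool, 6-year survey
pool, truth = fs.simulate_species_pool(cfg, seed=1)
X = fs.transform_traits(pool)                    # log10 + z-score
ranks = fs.fast_slow_ranks(X)                    # PCA -> FS 1; RDA -> FS 2, OSN

print(f"PCA: PC1 {100*ranks.pca.variance_fractions[0]:.1f}%, "
      f"PC2 {100*ranks.pca.variance_fractions[1]:.1f}%")
print(f"RDA: constrained {100*ranks.rda.constrained_fraction:.1f}%, "
      f"residual PC1 {100*ranks.rda.variance_fractions[1]:.1f}%, "
      f"PC2 {100*ranks.rda.variance_fractions[2]:.1f}%")
```

```
PCA: PC1 59.1%, PC2 32.1%
RDA: constrained 51.8%, residual PC1 33.2%, PC2 14.7%
```

Most trait variance loads on one fast–slow axis; constraining on body size
absorbs about half the variance, leaving the offspring trade-off (residual
PC1) and the size-corrected fast–slow axis (residual PC2).

```python
gm = fs.group_mean_ranks(ranks, pool.meta, "biogeography")
print(gm.round(1))

tree = fs.build_taxonomy_tree(pool.meta)
sig = fs.phylo_signal_test(tree, ranks.ranks("fs1"), n_permutations=999, seed=1)
print(f"Blomberg's K (FS 1 ranks) = {sig.K:.2f}, p = {sig.p_value}")
```

```
              fs1_rank  fs2_rank  osn_rank   n
biogeography
Arctic            21.4      30.9      27.9  27
arcto-boreal      46.0      43.3      33.7   3
boreal            48.0      42.6      45.1  46
Blomberg's K (FS 1 ranks) = 0.71, p = 0.001
```

Boreal species rank markedly slower than Arctic species on FS 1 (48 vs 21),
and the ranks carry strong phylogenetic signal. Integrating the ranks with
the simulated warming survey and regressing the station means on the
environment:

```python
stations, report = fs.filter_species(fs.simulate_survey(cfg, pool, truth, seed=2))
idx = fs.station_indices(stations, ranks, tree)
fit = fs.fit_index_glm(idx, "mean_fs1")
print(f"mean FS 1 vs temperature: {fit.marginal_effects['per_degC']:.2f} per degC "
      f"(p = {fit.p_values['temperature']:.2g})")
```

```
mean FS 1 vs temperature: 3.20 per degC (p = 2.2e-28)
```

Warmer stations host slower assemblages — the spatial fingerprint of
borealization.

The same workflow is available from the shell:

```bash
fastslow simulate --seed 1 --out bundle/
fastslow run --config pipeline.yaml --seed 1 --out results/
```

`run` writes `ranks.csv`, `indices.csv`, kriged surfaces per index
(`kriged_*.csv`), GLM summaries, and a `run_log.json` sufficient to
reproduce every output.

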