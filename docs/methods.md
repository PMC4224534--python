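# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical conventions the implementation commits to.

## Trait standardization

The six life-history traits span orders of magnitude and are right-skewed,
so each column is log₁₀-transformed and then z-scored using the sample SD
(n − 1 denominator, the convention matching correlation-matrix PCA). A
zero-variance column is an error rather than silently dropped: a trait
identical across species cannot inform an ordination, and its presence
almost certainly indicates a data problem. Missing values are never imputed
by the software — the input must be complete, with externally estimated
values only *flagged* (`imputed` column) so their share can be reported.
Offspring size is a single numeric column that deliberately mixes egg
diameter, egg-case size and larval length: the quantity of interest is the
per-offspring investment scale, not a strictly homologous measurement.

## Ordination and ranking

**PCA** is computed by SVD of the standardized matrix; eigenvalues are
singular values squared over (n − 1), and species scores use site scaling
(row projections, `U·S`). Only the ranks of scores are consumed downstream,
and ranks are invariant to any positive rescaling of an axis.

**RDA** with a single constraint (maximum body length by default) regresses
every trait column — including the constraint itself — on the standardized
constraint; the fitted rank-1 matrix gives the constrained axis and its
variance share, while a PCA of the residual matrix gives the unconstrained
axes. All variance fractions are relative to the total variance of the
input, so constrained + residual shares sum to 1 to 1e-9. Keeping the
constraint trait among the responses follows the standard constrained-
ordination convention (the constrained axis then absorbs exactly the
size-predictable part of every trait). A partial-RDA reading (size as a
*condition*, removed before any decomposition) differs only in whether the
constrained share is reported; the residual axes are identical, so the
choice does not affect the ranks.

**Axis identification.** The fast–slow axis from the PCA is PC1; in the
size-constrained RDA the residual PC1 is the offspring size-and-number
trade-off and residual PC2 is the size-corrected fast–slow axis. Eigenvector
signs are arbitrary, so each axis is oriented by the sign of its Pearson
correlation with an anchor trait before ranking: FS 1 positively on maximum
length, FS 2 positively on longevity, OSN positively on fecundity. An axis
essentially uncorrelated with its anchor (|r| < 1e-12) is an error, since
its orientation — and hence the meaning of "slow" — would be undefined.

**Ranking** is ascending with average ranks on ties (ties are possible in
principle though not expected with continuous traits); higher FS rank means
slower, higher OSN rank means more and smaller offspring.

## Taxonomy tree and phylogenetic statistics

No molecular phylogeny is assumed. The tree is built from the 6-rank nested
taxonomy with **unit branch lengths per rank step** — with no divergence
times available, equal steps are the only defensible default — and an
artificial root above the superclasses. Every tip sits at depth 6.

**Faith's PD** uses the rooted convention (the spanning subtree includes the
root), so a single species has PD 6 rather than 0. PD is computed by
accumulating the edge union of tip-to-root paths; an exhaustive
edge-enumeration oracle verifies it over all subsets of 10-tip trees in the
test suite.

**PDis** is the OLS residual of PD on species richness, fitted pooled across
years by default so that residuals are comparable between yearly map
panels; a per-year fit is available (`pdis_scope="per_year"`). Constant
richness leaves the slope unidentifiable and is an error.

**Blomberg's K** follows the standard ratio form: K =
(MSE₀/MSE) / E[MSE₀/MSE], with the root state estimated by GLS under the
tree's Brownian covariance and E[MSE₀/MSE] = (tr V − n/Σ(V⁻¹)) / (n − 1).
On a star tree K = 1 exactly for any trait; under Brownian simulation on the
taxonomy tree the mean K over replicates is ≈ 1. The **signal test**
shuffles trait values across tips: p = (1 + #{K_perm ≥ K_obs}) /
(n_perm + 1), so 999 permutations (the default) give a minimum attainable
p of 0.001. K is applied to the rank vectors themselves, since the ranks
are the quantity propagated into the community indices. An alternative
randomization based directly on MSE rather than K would test the same null;
the K-based version is used because K is also the reported effect size.

## Survey filtering and community indices

Surveys are presence/absence only; abundance is deliberately ignored.
Species absent in more than 2 survey years, or never recorded at stations
inside the 50–500 m trawling window, are excluded; out-of-window stations
are dropped, and stations emptied by the filter are removed. Indices per
station-year: richness, mean FS 1/FS 2/OSN rank over the ranked species
present, PD, PDis. A species present in the survey but missing from the
trait table is dropped from rank means but still counts toward richness and
PD when it is in the taxonomy; both counts are logged.

## Spatial interpolation and GLMs

Coordinates are projected to kilometres with a local equirectangular
projection about the station centroid (R = 6371 km) — adequate over a
sub-basin-scale study window and free of any CRS machinery.

**Variogram.** An OLS drift (linear in x, y by default) is removed, the
residual semivariogram is binned up to one third of the maximum pairwise
distance (beyond that, bin estimates are too unstable to help), and an
exponential model (default; spherical and gaussian available) is fitted by
weighted least squares with gstat-style weights N_j/h_j². The exponential
family is the most forgiving default when the true covariance is unknown.
A noiseless-drift field yields an explicit degenerate (flat) variogram
rather than a fitting failure. Note that the range of a strongly correlated
field is intrinsically hard to estimate from a single realization; recovery
tests use correlation lengths well inside the domain.

**Universal kriging** solves the semivariogram-form UK system (drift
handled by Lagrange multipliers) with one factorization of the left-hand
side for all grid cells. With zero nugget the predictor interpolates
exactly and has zero variance at data points; negative round-off variances
are clipped at zero. Duplicate station locations are jittered by ~1 m
(or rejected, per configuration) to keep the system nonsingular.

**GLMs** are Gaussian with identity link — the indices are continuous means
and the reported marginal effects are linear (per °C, per 100 m). Broad-
scale spatial autocorrelation is absorbed by coordinate polynomial terms,
degree 2 by default (x, y, x², y², xy). Standardized coefficients are
raw × SD(predictor)/SD(response). A design whose z-scored condition number
exceeds 1e8 is rejected with the most collinear term pair named.

## Synthetic-data generator

The generator emulates a boreal–Arctic shelf fish community and its
monitoring survey; its defaults are the package's canonical study
conditions.

* **Pool structure.** 76 species (27 Arctic, 46 boreal, 3 arcto-boreal) on
  a random but consistently nested taxonomy (2 superclasses … 40 genera).
* **Trait model.** Log-scale traits are driven by three latent factors:
  size (→ maximum length; length at maturity is size times a logit-normal
  maturity ratio, guaranteeing the ordering invariant), slowness
  (correlation 0.7 with size; → longevity, age at maturity), and an
  offspring trade-off loading positively on fecundity and negatively on
  offspring size — with zero noise and zero taxonomy effects, log fecundity
  and log offspring size are exactly anti-correlated. Family (SD 1.0) and
  genus (SD 0.5) random effects, correlated across the size/slowness
  components like the species-level factors, make relatives resemble each
  other and give the rank vectors detectable phylogenetic signal.
* **Biogeography.** Groups are assigned by a warm-affinity score that
  combines a family-level propensity with the family's slowness effect, so
  affiliation is phylogenetically conserved and boreal species end up
  slower, larger, more fecund and smaller-offspringed — the group contrasts
  the analysis is designed to detect.
* **Survey.** A 14 × 14 station lattice over a 20–50°E × 70–76°N window,
  six years, bottom temperature declining 6 °C from SW to NE, warming
  0.25 °C · yr⁻¹, station noise 0.3 °C. Occupancy is a thermal niche
  window: the product of two logistics around each species' optimum
  (Arctic optima ≈ −0.5 °C, boreal ≈ 3.5 °C, SD 0.6, half-width 1.5 °C,
  steepness 2 °C⁻¹, plateau 0.5); infinite steepness degenerates to a hard
  presence window, which the tests exploit as a deterministic oracle. These
  values give station richness of roughly 1–30 and a gradual northeastward
  expansion of boreal species under warming.
* **Ground truth** (latent factors, thermal optima, per-station mean latent
  slowness, injected warming) is stored with every dataset, and all
  randomness flows through one seeded generator: the same seed reproduces
  every file byte for byte.

What the generator does **not** emulate: gear catchability and
effort variation, abundance structure, species interactions, bathymetric
realism, interannual circulation anomalies, or taxa identified above
species level. Passing recovery tests therefore demonstrates that the
statistical chain recovers known structure of this idealized kind — not
that any field estimate is unbiased under real sampling artifacts.

## Problem sizes in routine runs

The test suite and the acceptance script run the full pipeline at the
default conditions (76 species; ~1,100 station-years) and use 20 seeded
replicates for recovery-rate checks, 200 Brownian replicates for the K
calibration, and 500 replicates (199 permutations each) for the
type-I-error calibration of the signal test; the kriging demonstrations use
40–500 points. These sizes give stable rates while keeping a full run in
the low minutes on one core.

## Known limitations

* Unit-branch-length taxonomy trees compress real divergence-time
  variation; K values are interpretable relative to this tree only.
* The equirectangular projection distorts distances for study windows much
  wider than ~10° of latitude.
* The GLM treats stations as independent given the coordinate polynomial;
  residual fine-scale autocorrelation will make reported p-values
  anti-conservative, as in any trend-surface correction.
* With a single constraining trait the RDA constrained space is
  one-dimensional; multi-constraint designs are out of scope.
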