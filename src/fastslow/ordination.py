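"""PCA and body-size-constrained RDA on standardized traits; fast-slow ranking.

Two ordinations identify the main continua of life-history covariation:

* an unconstrained PCA, whose first axis is the fast-slow continuum driven
  jointly by size and timing traits ("FS 1");
* a redundancy analysis (RDA) constrained on maximum body length, whose
  constrained axis absorbs size-driven covariation.  The residual (size-
  corrected) axes are the offspring size-and-number trade-off (residual PC1,
  "OSN") and a size-independent fast-slow continuum (residual PC2, "FS 2").

Species are ranked 1..n by their oriented scores on each axis; higher rank
means slower life history (FS axes) or more, smaller offspring (OSN axis).
Eigenvector signs are arbitrary, so each axis is anchored by the sign of its
correlation with a named trait before ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from fastslow.trait_io import StandardizedTraitMatrix


@dataclass
class OrdinationResult:
    """Eigen-decomposition output shared by PCA and RDA.

    ``variance_fractions`` are shares of the *total* trait variance; for an
    RDA the constrained fraction plus all residual fractions sum to 1.
    Species scores use site scaling (row projections, U @ diag(s)).
    """

    method: str
    axis_labels: list[str]
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    species_scores: np.ndarray
    trait_loadings: np.ndarray
    species_ids: list[str]
    trait_names: list[str]
    constrained_fraction: float | None = None
    constraint_name: str | None = None

    def axis_scores(self, label: str) -> np.ndarray:
        return self.species_scores[:, self.axis_labels.index(label)]


@dataclass
class FastSlowRanks:
    """Per-species FS 1, FS 2 and OSN ranks with axis provenance.

    fs1: rank on PCA PC1; fs2: rank on RDA residual PC2; osn: rank on RDA
    residual PC1.  Higher FS rank = slower; higher OSN rank = more, smaller
    offspring.
    """

    table: pd.DataFrame  # index species_id; columns fs1_score..osn_rank
    pca: OrdinationResult
    rda: OrdinationResult

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "species_id"
        out.to_csv(path)

    def ranks(self, axis: str) -> pd.Series:
        """Rank vector for axis in {'fs1', 'fs2', 'osn'}."""
        return self.table[f"{axis}_rank"]


def _svd_ordination(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD of a column-centred matrix -> (scores U@S, eigenvalues, axes V)."""
    n = M.shape[0]
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    eig = s**2 / (n - 1)
    scores = U * s
    return scores, eig, Vt.T


def pca(X: StandardizedTraitMatrix) -> OrdinationResult:
    """Principal component analysis of the standardized trait matrix."""
    M = np.asarray(X.values, dtype=float)
    n, p = M.shape
    if n <= p:
        raise ValueError(f"need more species ({n}) than traits ({p}) for PCA")
    scores, eig, axes = _svd_ordination(M)
    total = eig.sum()
    return OrdinationResult(
        method="PCA",
        axis_labels=[f"PC{k + 1}" for k in range(len(eig))],
        eigenvalues=eig,
        variance_fractions=eig / total,
        species_scores=scores,
        trait_loadings=axes,
        species_ids=list(X.species_ids),
        trait_names=list(X.trait_names),
    )


def rda(
    X: StandardizedTraitMatrix, constraint: str | np.ndarray
) -> OrdinationResult:
    """Redundancy analysis with one constraining variable.

    ``constraint`` is either the name of a trait column (the usual body-size
    correction, where the constraint trait remains a response as well) or an
    external centred vector.  Every trait column is regressed on the
    constraint; the fitted part yields the constrained axis RDA1 and the
    residual matrix is decomposed by PCA.  All variance fractions are
    relative to the total variance of X, so constrained + residual fractions
    sum to 1.
    """
    M = np.asarray(X.values, dtype=float)
    n = M.shape[0]
    if isinstance(constraint, str):
        if constraint not in X.trait_names:
            raise ValueError(f"constraint {constraint!r} is not a trait column")
        z = X.column(constraint)
        constraint_name = constraint
    else:
        z = np.asarray(constraint, dtype=float)
        if z.shape != (n,):
            raise ValueError("external constraint must be one value per species")
        z = z - z.mean()
        constraint_name = "external"
    denom = float(z @ z)
    if denom < 1e-12:
        raise ValueError(f"constraint column {constraint_name!r} is constant")
    # single-regressor projection; columns of M are already centred
    fitted = np.outer(z, (z @ M) / denom)
    resid = M - fitted
    total_var = (M**2).sum() / (n - 1)

    s_con, eig_con, ax_con = _svd_ordination(fitted)
    s_res, eig_res, ax_res = _svd_ordination(resid)
    # the fitted matrix has rank 1 with a single constraint
    n_con = 1
    eig = np.concatenate([eig_con[:n_con], eig_res])
    scores = np.column_stack([s_con[:, :n_con], s_res])
    axes = np.column_stack([ax_con[:, :n_con], ax_res])
    labels = ["RDA1"] + [f"PC{k + 1}" for k in range(eig_res.shape[0])]
    constrained_fraction = float(eig_con[:n_con].sum() / total_var)
    return OrdinationResult(
        method="RDA",
        axis_labels=labels,
        eigenvalues=eig,
        variance_fractions=eig / total_var,
        species_scores=scores,
        trait_loadings=axes,
        species_ids=list(X.species_ids),
        trait_names=list(X.trait_names),
        constrained_fraction=constrained_fraction,
        constraint_name=constraint_name,
    )


def orient_axis(
    scores: np.ndarray,
    X: StandardizedTraitMatrix,
    anchor: str,
    direction: str = "+",
) -> np.ndarray:
    """Fix the arbitrary sign of an ordination axis against an anchor trait.

    Returns the scores multiplied by -1 when their Pearson correlation with
    the anchor trait column does not have the requested sign.
    """
    if direction not in {"+", "-"}:
        raise ValueError("direction must be '+' or '-'")
    anchor_col = X.column(anchor)
    r = float(np.corrcoef(scores, anchor_col)[0, 1])
    if not np.isfinite(r) or abs(r) < 1e-12:
        raise ValueError(
            f"axis orientation undefined: |correlation| with {anchor!r} < 1e-12"
        )
    want = 1.0 if direction == "+" else -1.0
    return scores * (1.0 if np.sign(r) == want else -1.0)


def rank_scores(scores: np.ndarray) -> np.ndarray:
    """Ascending ranks (1..n), average ranks on ties."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    return stats.rankdata(scores, method="average")


def fast_slow_ranks(
    X: StandardizedTraitMatrix,
    constraint: str = "max_length",
    fs1_anchor: str = "max_length",
    fs2_anchor: str = "longevity",
    osn_anchor: str = "fecundity",
) -> FastSlowRanks:
    """Run both ordinations and rank species on FS 1, FS 2 and OSN axes."""
    pca_res = pca(X)
    rda_res = rda(X, constraint)
    fs1 = orient_axis(pca_res.axis_scores("PC1"), X, fs1_anchor, "+")
    fs2 = orient_axis(rda_res.axis_scores("PC2"), X, fs2_anchor, "+")
    osn = orient_axis(rda_res.axis_scores("PC1"), X, osn_anchor, "+")
    table = pd.DataFrame(
        {
            "fs1_score": fs1,
            "fs1_rank": rank_scores(fs1),
            "fs2_score": fs2,
            "fs2_rank": rank_scores(fs2),
            "osn_score": osn,
            "osn_rank": rank_scores(osn),
        },
        index=pd.Index(X.species_ids, name="species_id"),
    )
    return FastSlowRanks(table=table, pca=pca_res, rda=rda_res)


def group_mean_ranks(
    ranks: FastSlowRanks, meta: pd.DataFrame, group_field: str
) -> pd.DataFrame:
    """Mean FS/OSN ranks per metadata category, with group sizes.

    Species lacking metadata raise; empty categories are simply absent from
    the groupby result.
    """
    missing = set(ranks.table.index) - set(meta.index)
    if missing:
        raise ValueError(f"no metadata for ranked species: {sorted(missing)}")
    joined = ranks.table.join(meta[group_field])
    grouped = joined.groupby(group_field)[["fs1_rank", "fs2_rank", "osn_rank"]].mean()
    grouped["n"] = joined.groupby(group_field).size()
    return grouped
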