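"""Positive-lasso matching of single-cell cluster profiles to grid squares,
and gene-gene correlation concordance between modalities.

Each square's expression vector (over the shared genes) is regressed on the
cluster mean-expression profiles with an L1 penalty and a nonnegativity
constraint — objective ``(1/2n)*||y - Xw||^2 + penalty*sum(w)`` with
``w >= 0`` (scikit-learn's Lasso scaling). A square is assigned to the
cluster of its largest weight, and only when that weight strictly exceeds
the confidence threshold (default 0.2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.linear_model import Lasso

from .grid_quant import CountGrid

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterProfiles",
    "TransferResult",
    "lasso_transfer",
    "gene_correlation_concordance",
]

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ClusterProfiles:
    """Clusters x genes mean-expression matrix."""

    values: np.ndarray
    clusters: tuple[str, ...]
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.clusters), len(self.genes)):
            raise ValueError("profile matrix shape does not match labels")
        if (values < 0).any():
            raise ValueError("mean expression profiles must be non-negative")
        object.__setattr__(self, "values", values)

    @classmethod
    def from_tsv(cls, path) -> "ClusterProfiles":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), tuple(df.index.astype(str)), tuple(df.columns))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=list(self.clusters), columns=list(self.genes)).to_csv(
            path, sep="\t"
        )


@dataclass
class TransferResult:
    weights: np.ndarray              # (squares, clusters), all >= 0
    clusters: tuple[str, ...]
    assigned: np.ndarray             # object array: cluster name or "unassigned"
    weight_threshold: float
    shared_genes: tuple[str, ...]
    converged: np.ndarray            # bool per square

    def to_frame(self, squares: pd.DataFrame | None = None) -> pd.DataFrame:
        base = squares.reset_index(drop=True).copy() if squares is not None else pd.DataFrame(
            index=range(len(self.assigned))
        )
        base["assigned"] = self.assigned
        order = np.argsort(-self.weights, axis=1)[:, :5]
        for rank in range(min(5, len(self.clusters))):
            idx = order[:, rank]
            base[f"top{rank + 1}_cluster"] = np.asarray(self.clusters, dtype=object)[idx]
            base[f"top{rank + 1}_weight"] = self.weights[np.arange(len(idx)), idx]
        return base


def lasso_transfer(
    grid: CountGrid,
    profiles: ClusterProfiles,
    penalty: float = 1.0,
    weight_threshold: float = 0.2,
    *,
    max_iter: int = 10_000,
    tol: float = 1e-6,
) -> TransferResult:
    """Fit one positive lasso per square against the cluster profiles.

    Ties at the maximal weight are broken by lexical cluster-name order (and
    logged). Squares whose fit does not converge are flagged and left
    unassigned.
    """
    if not penalty > 0:
        raise ValueError("penalty must be > 0")
    shared = tuple(g for g in grid.genes if g in set(profiles.genes))
    if len(shared) < 2:
        raise ValueError("need at least 2 genes shared between grid and profiles")
    gi = [list(grid.genes).index(g) for g in shared]
    pi = [list(profiles.genes).index(g) for g in shared]
    X = profiles.values[:, pi].T          # genes x clusters design
    Y = np.asarray(grid.counts, dtype=float)[:, gi]

    n_squares = Y.shape[0]
    n_clusters = len(profiles.clusters)
    weights = np.zeros((n_squares, n_clusters))
    converged = np.ones(n_squares, dtype=bool)
    # objective (1/2n)||y - Xw||^2 + penalty*sum(w), w >= 0, no intercept:
    # the profiles themselves must explain the square
    model = Lasso(alpha=penalty, positive=True, fit_intercept=False,
                  max_iter=max_iter, tol=tol)
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    for s in range(n_squares):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            model.fit(X, Y[s])
            if any(issubclass(w.category, ConvergenceWarning) for w in caught):
                converged[s] = False
        weights[s] = model.coef_

    weights = np.maximum(weights, 0.0)  # numerical guard; positivity is structural

    cluster_arr = np.asarray(profiles.clusters, dtype=object)
    lex_order = np.argsort(cluster_arr.astype(str), kind="stable")
    assigned = np.full(n_squares, UNASSIGNED, dtype=object)
    max_w = weights.max(axis=1) if n_clusters else np.zeros(n_squares)
    confident = (max_w > weight_threshold) & converged
    for s in np.flatnonzero(confident):
        top = np.flatnonzero(weights[s] == max_w[s])
        if len(top) > 1:
            top = top[np.argsort(cluster_arr[top].astype(str), kind="stable")]
            logger.info("square %d: weight tie broken lexically -> %s", s, cluster_arr[top[0]])
        assigned[s] = cluster_arr[top[0]]

    return TransferResult(
        weights=weights,
        clusters=profiles.clusters,
        assigned=assigned,
        weight_threshold=weight_threshold,
        shared_genes=shared,
        converged=converged,
    )


def gene_correlation_concordance(
    matrix_a: pd.DataFrame, matrix_b: pd.DataFrame
) -> tuple[float, float, int]:
    """Concordance of gene-gene correlation structure between two modalities.

    Inputs are observations x genes frames. Each modality's gene-gene Pearson
    matrix is computed over the shared genes; returned is the Pearson r (and
    p-value) between the strictly-upper-triangle entries of the two matrices,
    plus the number of gene pairs excluded because either modality had zero
    variance for a member gene.
    """
    shared = [g for g in matrix_a.columns if g in set(matrix_b.columns)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes")
    a = matrix_a[shared].to_numpy(float)
    b = matrix_b[shared].to_numpy(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        corr_a = np.corrcoef(a, rowvar=False)
        corr_b = np.corrcoef(b, rowvar=False)
    iu = np.triu_indices(len(shared), k=1)
    va, vb = corr_a[iu], corr_b[iu]
    valid = np.isfinite(va) & np.isfinite(vb)
    n_excluded = int((~valid).sum())
    if valid.sum() < 2:
        raise ValueError("fewer than 2 defined gene pairs")
    r, p = pearsonr(va[valid], vb[valid])
    return float(r), float(p), n_excluded
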