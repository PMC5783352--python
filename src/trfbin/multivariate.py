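"""Sample-level analyses: mutual information, PCA and Ward clustering.

Mutual information between two expression profiles is estimated from the
Spearman rank correlation rho under a Gaussian-copula assumption:
``MI_raw = -1/2 ln(1 - rho^2)``, normalized to ``1 - exp(-2 MI_raw)`` which
equals rho^2 and lies in [0, 1] with 1 on the diagonal.  The estimator uses
the ranks only, so it needs no discretization and is invariant under
strictly monotone transforms of either profile.

Hierarchical clustering uses Ward linkage on Euclidean distances; trees are
serializable to Newick, and two trees over the same leaves (e.g. the male
and the female clustering of the same tRFs) are compared by cophenetic
correlation and by co-membership agreement at small cut heights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .errors import ValidationError

_RHO_CLIP = 1.0 - 1e-12


def spearman_mi(x, y) -> float:
    """Normalized mutual information of two profiles via the Spearman
    estimator.  Equals rho^2; raises on a constant profile (undefined
    correlation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("profiles must share at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant profile: correlation undefined")
    rho = float(spearmanr(x, y).statistic)
    r = min(abs(rho), _RHO_CLIP)
    raw = -0.5 * np.log(1.0 - r * r)
    return float(1.0 - np.exp(-2.0 * raw))


def mi_matrix(counts: pd.DataFrame, samples: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Symmetric matrix of pairwise normalized MI between sample profiles,
    with the diagonal defined as 1."""
    cols = list(samples) if samples is not None else list(counts.columns)
    if len(cols) < 2:
        raise ValidationError("MI matrix requires at least two samples")
    vals = np.eye(len(cols))
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            mi = spearman_mi(counts[cols[i]].to_numpy(), counts[cols[j]].to_numpy())
            vals[i, j] = vals[j, i] = mi
    return pd.DataFrame(vals, index=cols, columns=cols)


def pca_scores(counts: pd.DataFrame, n_components: int = 2):
    """Principal-component scores of samples over bin profiles.

    Bins (features) are centered across samples and the centered matrix is
    decomposed by SVD.  The sign convention fixes each component so that
    its loading vector sums to a non-negative value.  Returns
    ``(scores, explained_variance_fractions)`` with one row per sample.
    """
    X = counts.T.to_numpy(dtype=float)  # samples x bins
    n_samples, n_bins = X.shape
    if n_samples < 2:
        raise ValidationError("PCA requires at least two samples")
    if n_bins < n_components:
        raise ValidationError(
            f"fewer bins ({n_bins}) than requested components ({n_components})"
        )
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    flip = np.where(Vt.sum(axis=1) < 0, -1.0, 1.0)
    U = U * flip
    total = float((s**2).sum())
    evr = (s**2) / total if total > 0 else np.zeros_like(s)
    scores = (U * s)[:, :n_components]
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(scores, index=counts.columns, columns=cols), evr[:n_components]


@dataclass
class Dendrogram:
    """Ward agglomeration over a set of leaves, wrapping a SciPy linkage."""

    leaf_ids: list
    linkage_matrix: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        """Newick string with branch lengths.

        Merge heights are halved (the usual hclust-to-phylo convention) so
        the path distance between two leaves equals their cophenetic
        distance.  Leaf names are single-quoted so ids containing ':' are
        preserved.
        """
        Z = self.linkage_matrix
        n = self.n_leaves

        def height(node: int) -> float:
            return 0.0 if node < n else float(Z[node - n, 2]) / 2.0

        def render(node: int) -> str:
            if node < n:
                name = self.leaf_ids[node].replace("'", "''")
                return f"'{name}'"
            i, j = int(Z[node - n, 0]), int(Z[node - n, 1])
            h = height(node)
            return (
                f"({render(i)}:{h - height(i):.10g},"
                f"{render(j)}:{h - height(j):.10g})"
            )

        root = n + len(Z) - 1 if len(Z) else 0
        return render(root) + ";"

    def cophenetic_matrix(self) -> pd.DataFrame:
        d = squareform(cophenet(self.linkage_matrix))
        return pd.DataFrame(d, index=self.leaf_ids, columns=self.leaf_ids)

    def cut(self, k: int) -> pd.Series:
        labels = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.leaf_ids)


def ward_tree(counts: pd.DataFrame, axis: str = "samples") -> Dendrogram:
    """Ward-linkage hierarchical clustering of samples or tRFs.

    Euclidean distances on the row/column profiles as given (callers are
    expected to pass log-scale normalized counts).  SciPy's deterministic
    nearest-neighbor chain agglomeration is used, which resolves distance
    ties by the smallest cluster index.
    """
    data = counts.T if axis == "samples" else counts
    if axis not in ("samples", "trfs"):
        raise ValidationError("axis must be 'samples' or 'trfs'")
    leaves = list(data.index)
    if len(leaves) < 2:
        raise ValidationError("clustering requires at least two leaves")
    Z = linkage(data.to_numpy(dtype=float), method="ward")
    return Dendrogram(leaves, Z)


@dataclass(frozen=True)
class TreeComparison:
    """Agreement between two dendrograms over identical leaves."""

    cophenetic_r: float
    co_clustering: dict  # k -> fraction of leaf pairs with concordant co-membership


def compare_trees(a: Dendrogram, b: Dendrogram, ks: Sequence[int] = (2, 3, 4)) -> TreeComparison:
    """Cophenetic correlation and leaf-pair co-clustering agreement."""
    if set(a.leaf_ids) != set(b.leaf_ids):
        raise ValidationError("trees have different leaf sets")
    ca = a.cophenetic_matrix()
    cb = b.cophenetic_matrix().loc[ca.index, ca.columns]
    da = squareform(ca.to_numpy(), checks=False)
    db = squareform(cb.to_numpy(), checks=False)
    if np.ptp(da) == 0 or np.ptp(db) == 0:
        r = 1.0 if np.allclose(da, db) else 0.0
    else:
        r = float(np.corrcoef(da, db)[0, 1])
    agreement = {}
    n = a.n_leaves
    order = ca.index
    iu = np.triu_indices(n, k=1)
    for k in ks:
        if k > n:
            continue
        la = a.cut(k).reindex(order).to_numpy()
        lb = b.cut(k).reindex(order).to_numpy()
        same_a = (la[:, None] == la[None, :])[iu]
        same_b = (lb[:, None] == lb[None, :])[iu]
        agreement[int(k)] = float((same_a == same_b).mean())
    return TreeComparison(cophenetic_r=r, co_clustering=agreement)
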