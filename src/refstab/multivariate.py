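"""Multivariate overview: PCA of samples and hierarchical clustering.

PCA treats samples as observations and genes as variables; columns are
mean-centred, with optional unit-variance scaling (off by default — centring
alone reproduces the published variance shares for the packaged dataset).

Hierarchical clustering uses correlation distance (1 - Pearson r) with
average linkage (UPGMA) on both genes (rows) and samples (columns), with a
"tighter cluster first" leaf ordering: at every merge the subtree that was
itself merged at the lower height is placed first. The exported heatmap
matrix is the per-gene row-centred Ct matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .datamodel import CtTable, ValidationError


@dataclass(frozen=True)
class PcaResult:
    scores: pd.DataFrame  # samples x PCs
    explained: pd.Series  # % of total variance per PC, sums to 100
    loadings: pd.DataFrame  # genes x PCs


@dataclass(frozen=True)
class ClusteringResult:
    gene_linkage: np.ndarray  # scipy linkage matrix over genes (rows)
    sample_linkage: np.ndarray  # scipy linkage matrix over samples (columns)
    gene_order: tuple[str, ...]  # tighter-cluster-first leaf order
    sample_order: tuple[str, ...]
    gene_tree: dict  # nested {label} / {height, children} dicts
    sample_tree: dict
    heatmap: pd.DataFrame  # genes x samples, per-gene row-centred Ct
    original_samples: tuple[str, ...] = ()  # input order, for cut_samples

    def cut_samples(self, k: int) -> pd.Series:
        """Flat cluster labels for the samples at ``k`` clusters."""
        labels = fcluster(self.sample_linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=list(self.original_samples))


def pca(
    table: CtTable,
    scale: bool = False,
    orientation: Literal["samples", "genes"] = "samples",
) -> PcaResult:
    """PCA of the Ct matrix.

    ``orientation="samples"`` (default) treats samples as observations and
    genes as variables; ``"genes"`` transposes. Columns are mean-centred;
    ``scale=True`` additionally scales each variable to unit variance (a
    zero-variance variable is then an error).
    """
    table.require_complete("PCA")
    X = table.matrix()
    obs, var = (table.samples, table.genes)
    if orientation == "genes":
        X = X.T
        obs, var = var, obs
    elif orientation != "samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValidationError("PCA requires >= 3 observations and >= 2 variables")
    if scale:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            flat = [var[i] for i in np.flatnonzero(sd == 0)]
            raise ValidationError(f"cannot scale zero-variance variables: {flat}")
        X = (X - X.mean(axis=0)) / sd

    k = min(X.shape[0] - 1, X.shape[1])
    fit = PCA(n_components=k).fit(X)
    pcs = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(fit.transform(X), index=obs, columns=pcs)
    explained = pd.Series(fit.explained_variance_ratio_ * 100.0, index=pcs)
    loadings = pd.DataFrame(fit.components_.T, index=var, columns=pcs)
    return PcaResult(scores=scores, explained=explained, loadings=loadings)


def _tight_first_order(Z: np.ndarray, labels: list[str]) -> tuple[list[int], dict]:
    """Leaf order and nested tree with the tighter (lower merge height)
    subtree first at every internal node. Ties break toward the subtree whose
    alphabetically smallest leaf label comes first."""
    n = len(labels)

    def node(idx: int) -> tuple[list[int], float, str, dict]:
        # returns (leaves, height, min label, tree dict)
        if idx < n:
            return [idx], 0.0, labels[idx], {"label": labels[idx]}
        left, right = int(Z[idx - n, 0]), int(Z[idx - n, 1])
        height = float(Z[idx - n, 2])
        a = node(left)
        b = node(right)
        first, second = sorted((a, b), key=lambda t: (t[1], t[2]))
        return (
            first[0] + second[0],
            height,
            min(a[2], b[2]),
            {"height": height, "children": [first[3], second[3]]},
        )

    leaves, _, _, tree = node(2 * n - 2)
    return leaves, tree


def hierarchical_cluster(table: CtTable) -> ClusteringResult:
    """UPGMA clustering of genes and samples under correlation distance."""
    table.require_complete("hierarchical clustering")
    X = table.matrix()  # samples x genes
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("clustering requires >= 2 genes and >= 2 samples")
    for axis, names, what in ((0, table.genes, "gene"), (1, table.samples, "sample")):
        mat = X.T if axis == 0 else X
        flat = [names[i] for i in range(mat.shape[0]) if np.ptp(mat[i]) == 0]
        if flat:
            raise ValidationError(
                f"correlation distance undefined for constant {what}(s): {flat}"
            )

    gene_Z = linkage(pdist(X.T, metric="correlation"), method="average")
    sample_Z = linkage(pdist(X, metric="correlation"), method="average")
    gene_idx, gene_tree = _tight_first_order(gene_Z, table.genes)
    sample_idx, sample_tree = _tight_first_order(sample_Z, table.samples)

    heatmap = table.ct.T
    heatmap = heatmap.sub(heatmap.mean(axis=1), axis=0)  # per-gene row centring
    return ClusteringResult(
        gene_linkage=gene_Z,
        sample_linkage=sample_Z,
        gene_order=tuple(table.genes[i] for i in gene_idx),
        sample_order=tuple(table.samples[i] for i in sample_idx),
        gene_tree=gene_tree,
        sample_tree=sample_tree,
        heatmap=heatmap,
        original_samples=tuple(table.samples),
    )
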