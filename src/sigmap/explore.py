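"""Exploratory structure: PCA with explained-variance reporting and per-gene
loading weights, and agglomerative hierarchical clustering of samples.

PCA is gene-centered and unscaled (no unit-variance reduction), matching the
convention used for dataset-effect removal: scaling genes to unit variance
would misrepresent their relative importance. Clustering uses Pearson
correlation distance (1 - r) between sample columns with Ward or average
linkage applied directly to the distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import Compendium


@dataclass
class PcaResult:
    """Scores (samples x components), unit-norm loadings (genes x components)
    and per-component explained variance fractions."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_fraction: np.ndarray

    def summary(self, n: int = 5) -> str:
        lines = ["PCA (gene-centered, unscaled)"]
        for i, frac in enumerate(self.explained_fraction[:n], start=1):
            lines.append(f"  PC{i}: {100 * frac:.1f}% of variance")
        return "\n".join(lines)


def pca(compendium: Compendium) -> PcaResult:
    """Singular value decomposition of the gene-centered matrix.

    Deterministic sign convention: each loading column's largest-magnitude
    entry is positive. Raises on a constant (zero-variance) matrix.
    """
    if compendium.n_samples < 2 or compendium.n_genes < 2:
        raise ValueError("PCA needs at least 2 genes and 2 samples")
    X = compendium.values.to_numpy(float)
    Xc = X - X.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s**2).sum())
    if total <= 0:
        raise ValueError("constant matrix: total gene-centered variance is zero")
    n_comp = min(compendium.n_genes, compendium.n_samples - 1)
    U, s, Vt = U[:, :n_comp], s[:n_comp], Vt[:n_comp, :]
    # sign convention
    flip = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(n_comp)])
    flip[flip == 0] = 1.0
    U = U * flip
    Vt = Vt * flip[:, None]
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    scores = pd.DataFrame(
        (Vt * s[:, None]).T, index=compendium.values.columns, columns=comp_names
    )
    loadings = pd.DataFrame(U, index=compendium.values.index, columns=comp_names)
    return PcaResult(scores=scores, loadings=loadings, explained_fraction=s**2 / total)


def top_pc_contributors(result: PcaResult, component: int, quantile: float = 0.01) -> list:
    """Genes in the upper tail of a component's squared loading weights.

    ``component`` is 1-based; ``quantile`` is the fraction of genes to keep
    (default 0.01, the top 1% of loading weights — the scale of the
    strongest-contributor gene lists this selection emulates). The top
    round(quantile * n) genes by squared loading are returned, ties broken
    by gene id, so quantile -> 1 selects every gene. Intersect the returned
    lists across components to find shared contributors.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    name = f"PC{component}"
    if name not in result.loadings.columns:
        raise ValueError(f"component {component} not available")
    w = result.loadings[name] ** 2
    k = min(len(w), max(1, int(round(quantile * len(w)))))
    order = sorted(w.index, key=lambda g: (-w[g], str(g)))
    return order[:k]


@dataclass
class Dendrogram:
    """Agglomerative merge history for samples.

    ``linkage_matrix`` is the standard (n-1) x 4 merge table (node ids, merge
    height, cluster size); ``leaf_ids`` are sample ids in input (lexicographic)
    order.
    """

    linkage_matrix: np.ndarray
    leaf_ids: list
    distance_name: str
    linkage_name: str

    def leaf_order(self) -> list:
        order = hierarchy.leaves_list(self.linkage_matrix)
        return [self.leaf_ids[i] for i in order]

    def cut(self, n_clusters: int) -> dict:
        """Sample id -> cluster label for a flat cut into n clusters."""
        labels = hierarchy.fcluster(self.linkage_matrix, t=n_clusters, criterion="maxclust")
        return dict(zip(self.leaf_ids, labels))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.leaf_ids[node.id]}:{length:g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def hierarchical_cluster(
    compendium: Compendium, distance: str = "pearson_correlation", linkage: str = "ward"
) -> Dendrogram:
    """Cluster samples under 1 - Pearson(r) distance and the named linkage.

    Ward linkage is applied to the correlation-derived distances directly
    (the Lance-Williams Ward update on the given matrix, Ward.D style), which
    matches the behavior of the classic hierarchical-clustering tooling this
    pipeline mirrors; the distances are not Euclidean, so this is a declared
    convention rather than a geometric Ward. Columns are processed in
    lexicographic sample-id order so ties break deterministically.
    """
    if distance != "pearson_correlation":
        raise ValueError("only 'pearson_correlation' distance is supported")
    if linkage not in ("ward", "average"):
        raise ValueError("linkage must be 'ward' or 'average'")
    if compendium.n_samples < 3:
        raise ValueError("clustering needs at least 3 samples")
    ids = sorted(map(str, compendium.values.columns))
    X = compendium.values[ids].to_numpy(float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance sample column(s): {bad[:5]} (correlation undefined)")
    corr = np.corrcoef(X, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    return Dendrogram(
        linkage_matrix=Z,
        leaf_ids=ids,
        distance_name="pearson_correlation",
        linkage_name=linkage,
    )
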