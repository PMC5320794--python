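"""Co-expression clustering: k-means and UPGMA over expression profiles.

The function-inference workflow clusters genes by their expression across
conditions (Euclidean distance, k-means with k=100 in the original
analysis) and asks which genes of known function share a cluster with a
gene of interest. UPGMA provides the complementary hierarchical view; its
ultrametric node heights are half the average pairwise distance between the
merged groups. No normalization is applied implicitly; an explicit log2
transform is available.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .io_formats import FormatError


def read_expression_tsv(path, log2: bool = False) -> pd.DataFrame:
    """Genes x conditions TSV (header row, first column gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise FormatError(f"{path}: non-finite expression values")
    if log2:
        df = np.log2(df + 1.0)
    return df


@dataclass
class ClusterResult:
    """A k-means partition of genes (cluster ids 1..k)."""

    assignment: dict
    k: int
    inertia: float
    seed: int

    def members(self, cluster_id: int) -> list:
        return sorted(g for g, c in self.assignment.items()
                      if c == cluster_id)


def kmeans(matrix: pd.DataFrame, k: int = 100, seed: int = 0,
           restarts: int = 10) -> ClusterResult:
    """Euclidean k-means (k-means++ init, best of ``restarts`` by inertia),
    deterministic given ``seed``."""
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds the number of genes ({len(matrix)})")
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts,
                random_state=seed)
    labels = km.fit_predict(matrix.to_numpy(dtype=float))
    assignment = {g: int(c) + 1 for g, c in zip(matrix.index, labels)}
    return ClusterResult(assignment, k, float(km.inertia_), seed)


def co_clustered(result: ClusterResult, gene_id: str) -> list:
    """All genes sharing the query's cluster, query excluded, sorted."""
    if gene_id not in result.assignment:
        raise KeyError(f"unknown gene {gene_id!r}")
    cid = result.assignment[gene_id]
    return [g for g in result.members(cid) if g != gene_id]


@dataclass
class Dendrogram:
    """UPGMA tree: scipy linkage matrix plus leaf ids and node heights."""

    linkage_matrix: np.ndarray
    ids: list

    @property
    def merge_heights(self) -> np.ndarray:
        """Ultrametric heights of the internal nodes (distance / 2)."""
        return self.linkage_matrix[:, 2] / 2.0

    def to_newick(self) -> str:
        n = len(self.ids)
        heights = np.concatenate([np.zeros(n), self.merge_heights])

        def render(node: int) -> str:
            if node < n:
                return self.ids[node]
            a, b = (int(self.linkage_matrix[node - n, 0]),
                    int(self.linkage_matrix[node - n, 1]))
            h = heights[node]
            return (f"({render(a)}:{h - heights[a]:.10g},"
                    f"{render(b)}:{h - heights[b]:.10g})")

        return render(2 * n - 2) + ";"

    def cophenetic(self) -> np.ndarray:
        """Condensed cophenetic distance matrix (2x the merge height of the
        lowest common ancestor)."""
        from scipy.cluster.hierarchy import cophenet

        return cophenet(self.linkage_matrix)


def upgma(matrix: pd.DataFrame) -> Dendrogram:
    """Average-linkage agglomerative clustering of Euclidean distances.

    Merge heights are monotone non-decreasing (UPGMA is reducible), and the
    resulting tree is ultrametric: every leaf lies at the same distance
    from the root.
    """
    if len(matrix) < 2:
        raise ValueError("need at least two genes for UPGMA")
    d = pdist(matrix.to_numpy(dtype=float), metric="euclidean")
    Z = linkage(d, method="average")
    return Dendrogram(Z, list(matrix.index))


def write_assignment_tsv(result: ClusterResult, path) -> None:
    df = pd.DataFrame(
        {"gene": list(result.assignment),
         "cluster": [result.assignment[g] for g in result.assignment]}
    ).sort_values(["cluster", "gene"])
    df.to_csv(path, sep="\t", index=False)
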