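"""Hierarchical clustering of methylation profiles and panel classification.

Samples (or probes) are clustered agglomeratively on raw beta values with
the Euclidean metric and complete linkage — the classic two-way
methylation-heatmap recipe.  Rows are not standardised by default.  How
well a sample dendrogram separates the tumor entities is scored as
*cluster purity*: cut the tree into k clusters (k = number of distinct
entity labels unless overridden) and report the fraction of samples that
carry their cluster's majority label.

A reduced *gene panel* representation averages, per gene, all probes that
passed QC; clustering the resulting genes x samples matrix mirrors a
targeted multi-locus assay.  Finally, a single-locus caller classifies a
sample from one marker gene's average alone by comparing it with the
reference-group mean at the same delta-beta threshold used for
differential calling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .dm_marker import DMCallSet
from .io_formats import ValidationError

__all__ = [
    "Dendrogram",
    "PurityScore",
    "select_clustering_probes",
    "hierarchical_cluster",
    "cluster_purity",
    "build_panel_matrix",
    "single_locus_call",
    "DEFAULT_PANEL_GENES",
]

DEFAULT_PANEL_GENES = ("ADRA1D", "MGMT", "VHL", "THBS1")


@dataclass
class Dendrogram:
    """An agglomerative clustering result over samples or probes.

    ``linkage`` is a scipy linkage matrix: n-1 merges, each a pair of
    cluster indices with its merge height (complete-linkage Euclidean
    distance in beta space, so heights are non-decreasing).
    """

    linkage: np.ndarray
    labels: list[str]
    axis: str  # "samples" or "probes"
    metric: str = "euclidean"
    method: str = "complete"

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, k: int) -> pd.Series:
        """Assign each leaf to one of k flat clusters (cut by merge height)."""
        if k < 1:
            raise ValidationError("number of clusters must be >= 1")
        if k > self.n_leaves:
            raise ValidationError(f"cannot cut {self.n_leaves} leaves into {k} clusters")
        assign = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(assign, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        """Serialise the tree as Newick with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


@dataclass
class PurityScore:
    k: int
    purity: float
    majority_labels: pd.DataFrame  # cluster, majority_label, n_samples, n_majority
    assignments: pd.Series


def select_clustering_probes(callsets: Iterable[DMCallSet]) -> tuple[list[str], int]:
    """Union of hyper+hypo probes over all contrasts; (probe ids, n unique).

    Each probe is counted once no matter how many contrasts call it.
    Order follows the first callset's probe order.
    """
    callsets = list(callsets)
    called: set[str] = set()
    for cs in callsets:
        called |= cs.called
    if not called:
        raise ValidationError("no differentially methylated probes to cluster")
    ordered: list[str] = []
    seen: set[str] = set()
    for cs in callsets:
        for p in cs.table.index:
            if p in called and p not in seen:
                ordered.append(p)
                seen.add(p)
    return ordered, len(ordered)


def hierarchical_cluster(
    data: pd.DataFrame,
    axis: str = "samples",
    metric: str = "euclidean",
    method: str = "complete",
    standardize_rows: bool = False,
) -> Dendrogram:
    """Cluster the columns (axis="samples") or rows (axis="probes") of a
    features x samples matrix.

    Rows containing missing values are dropped (and must leave at least
    one feature).  Observation input order does not affect the merge
    heights; scipy breaks ties deterministically for a fixed input.
    """
    if axis not in ("samples", "probes"):
        raise ValidationError(f"axis must be 'samples' or 'probes', got {axis!r}")
    clean = data.dropna(axis=0, how="any")
    if clean.empty:
        raise ValidationError("no complete rows left after dropping missing values")
    if standardize_rows:
        sd = clean.std(axis=1, ddof=1).replace(0.0, 1.0)
        clean = clean.sub(clean.mean(axis=1), axis=0).div(sd, axis=0)
    obs = clean.T if axis == "samples" else clean
    labels = list(obs.index)
    if len(labels) < 2:
        raise ValidationError("clustering needs at least two leaves")
    z = hierarchy.linkage(obs.to_numpy(dtype=float), method=method, metric=metric)
    return Dendrogram(linkage=z, labels=labels, axis=axis, metric=metric, method=method)


def cluster_purity(
    dendrogram: Dendrogram,
    labels: Mapping[str, str] | pd.Series,
    k: int | None = None,
) -> PurityScore:
    """Cut the sample dendrogram into k clusters and score label purity.

    purity = (sum over clusters of the majority-label count) / n_samples.
    k defaults to the number of distinct labels.
    """
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    leaf_labels = labels.loc[dendrogram.labels]
    if k is None:
        k = leaf_labels.nunique()
    assign = dendrogram.cut(k)
    rows = []
    majority_total = 0
    for cluster_id, members in assign.groupby(assign).groups.items():
        counts = leaf_labels.loc[members].value_counts()
        majority_total += int(counts.iloc[0])
        rows.append(
            {
                "cluster": cluster_id,
                "majority_label": counts.index[0],
                "n_samples": len(members),
                "n_majority": int(counts.iloc[0]),
            }
        )
    purity = majority_total / dendrogram.n_leaves
    return PurityScore(
        k=k,
        purity=purity,
        majority_labels=pd.DataFrame(rows),
        assignments=assign,
    )


def build_panel_matrix(
    beta: pd.DataFrame,
    gene_of: pd.Series,
    genes: Sequence[str] = DEFAULT_PANEL_GENES,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene mean methylation over each gene's passing probes.

    Returns (genes x samples matrix, excluded samples).  A sample missing
    *all* probes of any requested gene cannot be placed on the panel and
    is excluded (and listed), mirroring assay failures in targeted
    validation runs.
    """
    rows = {}
    for gene in genes:
        probes = gene_of.index[gene_of == gene]
        if len(probes) == 0:
            raise ValidationError(f"gene {gene!r} has no probes in the gene map")
        present = [p for p in probes if p in beta.index]
        if not present:
            raise ValidationError(f"gene {gene!r} has no probes in the matrix")
        rows[gene] = beta.loc[present].mean(axis=0, skipna=True)
    panel = pd.DataFrame(rows).T
    panel.index.name = "gene_symbol"
    excluded = [s for s in panel.columns if panel[s].isna().any()]
    panel = panel.drop(columns=excluded)
    return panel, excluded


def single_locus_call(
    value: float,
    reference_mean: float,
    threshold: float = 0.3,
    positive_label: str = "CCSK-like",
) -> str:
    """Classify one sample from a single marker-gene average.

    Positive iff ``value - reference_mean > threshold`` (strict); a
    missing marker value yields ``"indeterminate"``, distinct from a
    negative call.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "indeterminate"
    if np.isnan(reference_mean):
        raise ValidationError("reference mean for the marker gene is missing")
    # decimal rounding as in the delta-beta caller: a difference that is
    # exactly the threshold must not clear the strict inequality
    return positive_label if round(value - reference_mean, 10) > threshold else "other"
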