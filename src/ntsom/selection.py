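"""Two-way hierarchical clustering and "unknown common" compound selection.

The screened, z-scored table is clustered on both axes with Euclidean
distance and Ward's linkage (Ward.D2 convention: the merge objective is
the increase in total within-cluster sum of squares, heights are on the
distance scale).  Compound clusters that are strongly and specifically
elevated in some industrial site are "industrial-peculiar"; the union of
the remaining clusters is the set of unknown common compounds, the
substrate for the outlier models.  Finally the table is split into its
urban and industrial sample blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy

from .data_io import FeatureTable, ValidationError


@dataclass
class Dendrogram:
    """Agglomeration result for one axis of the table."""

    #: (node_a, node_b, height) triples in scipy convention: leaves are
    #: 0..n-1, the merge at position i creates node n+i
    merges: list[tuple[int, int, float]]
    leaf_order: list[int]
    items: list[str]
    linkage: str = "ward"
    distance: str = "euclidean"

    @property
    def n_leaves(self) -> int:
        return len(self.items)

    def linkage_matrix(self) -> np.ndarray:
        """Reassemble the scipy linkage matrix (with cluster sizes)."""
        n = self.n_leaves
        Z = np.zeros((len(self.merges), 4))
        sizes = {i: 1 for i in range(n)}
        for i, (a, b, h) in enumerate(self.merges):
            size = sizes[a] + sizes[b]
            sizes[n + i] = size
            Z[i] = [a, b, h, size]
        return Z

    def check_monotone(self) -> None:
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValidationError("merge heights are not non-decreasing")


@dataclass
class CommonSelection:
    """Partition of the compounds into unknown commons and peculiar clusters."""

    unknown_common_ids: list[str]
    #: per discarded cluster: (member compound ids, peculiarity score)
    discarded_clusters: list[tuple[list[str], float]]
    #: peculiarity score of every cluster, flagged or not
    cluster_scores: list[float]
    k: int
    delta: float

    @property
    def discarded_ids(self) -> list[str]:
        return [cid for ids, _ in self.discarded_clusters for cid in ids]


def hca(matrix: np.ndarray, axis: str = "compounds",
        items: list[str] | None = None) -> Dendrogram:
    """Ward/Euclidean agglomerative clustering of one axis.

    ``matrix`` is samples x compounds; ``axis='compounds'`` clusters the
    columns, ``axis='samples'`` the rows.  Heights follow the Ward.D2
    convention (scipy's ``ward``), which guarantees monotone merges.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValidationError("hca expects a 2-D matrix")
    if not np.isfinite(matrix).all():
        raise ValidationError("hca input contains non-finite values")
    if axis == "compounds":
        X = matrix.T
    elif axis == "samples":
        X = matrix
    else:
        raise ValidationError(f"unknown axis {axis!r}")
    n = X.shape[0]
    if items is not None and len(items) != n:
        raise ValidationError("items list does not match axis length")
    if items is None:
        items = [str(i) for i in range(n)]
    if n < 1:
        raise ValidationError("nothing to cluster")
    if n == 1:
        return Dendrogram(merges=[], leaf_order=[0], items=list(items))

    Z = hierarchy.linkage(X, method="ward")
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in Z]
    leaf_order = [int(i) for i in hierarchy.leaves_list(Z)]
    dend = Dendrogram(merges=merges, leaf_order=leaf_order, items=list(items))
    dend.check_monotone()
    return dend


def cut_clusters(dend: Dendrogram, k: int) -> np.ndarray:
    """Labels in 1..k from cutting the dendrogram into k clusters."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > dend.n_leaves:
        raise ValidationError(
            f"cannot cut {dend.n_leaves} items into {k} clusters"
        )
    if k == 1 or dend.n_leaves == 1:
        return np.ones(dend.n_leaves, dtype=int)
    return hierarchy.fcluster(dend.linkage_matrix(), t=k, criterion="maxclust")


def select_unknown_common(
    table: FeatureTable,
    dend: Dendrogram,
    k: int = 5,
    delta: float = 2.0,
    manual_discard_ids: list[str] | None = None,
) -> CommonSelection:
    """Extract the unknown-common compound set from a z-scored table.

    The compound dendrogram is cut into ``k`` clusters.  A cluster is
    industrial-peculiar iff, over its compounds, the largest value of

        mean z within one industrial site  -  mean z over all urban samples

    exceeds ``delta`` (z-units).  Unknown commons are the union of the
    non-peculiar clusters.  ``manual_discard_ids`` bypasses the automatic
    rule with an explicit list of compounds to discard.
    """
    if dend.items != table.compound_ids:
        raise ValidationError("dendrogram was not built on this table's compounds")
    urban = table.sample_mask(site_type="urban")
    industrial = table.sample_mask(site_type="industrial")
    if not industrial.any():
        raise ValidationError("table has no industrial samples")
    if not urban.any():
        raise ValidationError("table has no urban samples")

    if manual_discard_ids is not None:
        unknown = set(table.compound_ids) - set(manual_discard_ids)
        extra = set(manual_discard_ids) - set(table.compound_ids)
        if extra:
            raise ValidationError(f"manual discard ids not in table: {sorted(extra)}")
        return CommonSelection(
            unknown_common_ids=[c for c in table.compound_ids if c in unknown],
            discarded_clusters=[(sorted(manual_discard_ids), float("nan"))]
            if manual_discard_ids
            else [],
            cluster_scores=[],
            k=0,
            delta=delta,
        )

    labels = cut_clusters(dend, k)
    ind_sites = sorted({s.site for s, m in zip(table.samples, industrial) if m})

    unknown: list[str] = []
    discarded: list[tuple[list[str], float]] = []
    scores: list[float] = []
    for label in range(1, labels.max() + 1):
        cols = np.flatnonzero(labels == label)
        block = table.areas[:, cols]
        urban_mean = block[urban].mean()
        peculiarity = max(
            block[table.sample_mask(site=site)].mean() - urban_mean
            for site in ind_sites
        )
        scores.append(float(peculiarity))
        member_ids = [table.compound_ids[j] for j in cols]
        if peculiarity > delta:
            discarded.append((member_ids, float(peculiarity)))
        else:
            unknown.extend(member_ids)

    # keep original column order in the output
    unknown_set = set(unknown)
    return CommonSelection(
        unknown_common_ids=[c for c in table.compound_ids if c in unknown_set],
        discarded_clusters=discarded,
        cluster_scores=scores,
        k=k,
        delta=delta,
    )


def split_subsets(table: FeatureTable) -> tuple[FeatureTable, FeatureTable]:
    """Partition the samples into (urban, industrial) blocks.

    Blank rows are excluded; row order within each block is preserved.
    """
    for s in table.samples:
        if s.site_type not in ("urban", "industrial", "blank"):
            raise ValidationError(f"unknown site_type {s.site_type!r}")
    urban = table.sample_mask(site_type="urban")
    industrial = table.sample_mask(site_type="industrial")
    if not urban.any():
        raise ValidationError("no urban samples to split out")
    urban_t = table.select_samples(urban)
    industrial_t = (
        table.select_samples(industrial) if industrial.any() else None
    )
    return urban_t, industrial_t


def ordered_heatmap(
    table: FeatureTable,
    sample_dend: Dendrogram,
    compound_dend: Dendrogram,
):
    """z-value matrix reordered by the two dendrogram leaf orders."""
    rows = sample_dend.leaf_order
    cols = compound_dend.leaf_order
    frame = table.to_frame()
    return frame.iloc[rows, cols]
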