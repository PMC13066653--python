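"""Stage 3: Ward minimum-variance clustering of species trait means.

Species are represented by their per-trait arithmetic means on the
selected taxonomic indicators, optionally column-standardized (default:
on, since traits mix measurement units and Ward is scale-sensitive).
Agglomeration merges, at every step, the pair of clusters whose fusion
minimally increases the total within-cluster sum of squares.  Reported
merge heights follow the metric-scale convention height = sqrt(2·ΔESS)
(ESS = within-cluster sum of squares), under which two singletons at
Euclidean distance d merge at height d; this is the convention of
scipy's and R's ``ward.D2`` and is guaranteed inversion-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .distance import DistanceMatrix
from .molphylo.tree import Tree

log = logging.getLogger(__name__)

__all__ = [
    "SpeciesTraitTable",
    "Dendrogram",
    "species_trait_table",
    "euclidean_distances",
    "ward_cluster",
    "cut_clusters",
    "suggest_k",
]


@dataclass
class SpeciesTraitTable:
    """Species x selected-trait matrix of per-species means."""

    table: pd.DataFrame  # index: species; columns: traits
    standardized: bool

    @property
    def species(self) -> list[str]:
        return list(self.table.index)


def species_trait_table(
    matrix: pd.DataFrame, traits: list[str], standardize: bool = True
) -> SpeciesTraitTable:
    """Per-species trait means, optionally z-scored per column."""
    if not traits:
        raise ValueError("no traits selected")
    missing_cols = [t for t in traits if t not in matrix.columns]
    if missing_cols:
        raise ValueError(f"traits not in matrix: {missing_cols}")
    means = matrix.groupby("species", sort=True)[traits].mean()
    for sp in means.index:
        for t in traits:
            if pd.isna(means.loc[sp, t]):
                raise ValueError(f"species {sp!r} has no data for trait {t!r}")
    if standardize:
        sd = means.std(ddof=1)
        degenerate = sd[sd == 0].index.tolist()
        if degenerate:
            raise ValueError(f"cannot standardize constant columns: {degenerate}")
        means = (means - means.mean()) / sd
    return SpeciesTraitTable(table=means, standardized=standardize)


def euclidean_distances(table: SpeciesTraitTable) -> DistanceMatrix:
    d = squareform(pdist(table.table.to_numpy(), metric="euclidean"))
    return DistanceMatrix(labels=table.species, matrix=d)


@dataclass
class Dendrogram:
    """Agglomeration record: scipy linkage matrix plus leaf labels."""

    labels: list[str]
    linkage_matrix: np.ndarray

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def merges(self) -> list[tuple[frozenset[str], frozenset[str], float]]:
        """(member set A, member set B, height) per agglomeration step."""
        members: dict[int, frozenset[str]] = {
            i: frozenset([lab]) for i, lab in enumerate(self.labels)
        }
        out = []
        for step, (a, b, h, _) in enumerate(self.linkage_matrix):
            sa, sb = members[int(a)], members[int(b)]
            out.append((sa, sb, float(h)))
            members[self.n + step] = sa | sb
        return out

    def to_tree(self) -> Tree:
        """Ultrametric display tree; branch = half the height difference."""
        tree = Tree()
        node_of: dict[int, int] = {}
        height_of: dict[int, float] = {}
        for i, lab in enumerate(self.labels):
            node_of[i] = tree.add_node(lab)
            height_of[i] = 0.0
        for step, (a, b, h, _) in enumerate(self.linkage_matrix):
            new = tree.add_node()
            for child in (int(a), int(b)):
                tree.add_edge(new, node_of[child], (h - height_of[child]) / 2.0)
            node_of[self.n + step] = new
            height_of[self.n + step] = float(h)
        return tree

    def to_newick(self) -> str:
        return self.to_tree().to_newick()


def ward_cluster(d: DistanceMatrix) -> Dendrogram:
    """Ward minimum-variance agglomeration from a Euclidean matrix."""
    if d.n < 2:
        raise ValueError("clustering needs at least 2 items")
    z = linkage(squareform(d.matrix, checks=False), method="ward")
    heights = z[:, 2]
    if np.any(np.diff(heights) < -1e-9):
        raise AssertionError("Ward heights must be nondecreasing")
    return Dendrogram(labels=list(d.labels), linkage_matrix=z)


def cut_clusters(dend: Dendrogram, k: int) -> dict[str, int]:
    """Partition into exactly k blocks by undoing the last k-1 merges."""
    if not 1 <= k <= dend.n:
        raise ValueError(f"k must be in [1, {dend.n}]")
    if k == dend.n:
        assignment = np.arange(1, dend.n + 1)
    else:
        assignment = fcluster(dend.linkage_matrix, t=k, criterion="maxclust")
    return dict(zip(dend.labels, (int(c) for c in assignment)))


def suggest_k(dend: Dendrogram) -> int:
    """Cut at the largest relative gap between successive merge heights."""
    h = dend.heights
    if len(h) < 2:
        return min(2, dend.n)
    best_k, best_gap = 2, -np.inf
    for i in range(len(h) - 1):
        if h[i + 1] <= 0:
            continue
        gap = (h[i + 1] - h[i]) / h[i + 1]
        k = dend.n - (i + 1)
        if gap > best_gap:
            best_gap, best_k = gap, k
    log.info("suggested k=%d from the largest relative height gap", best_k)
    return best_k
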