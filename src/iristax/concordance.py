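"""Stage 5: agreement between morphological clusters and molecular clades.

Monophyly on an unrooted tree is read off the bipartitions: a taxon set
is a clade iff the set or its complement is induced by some edge.  The
concordance score is the fraction of evaluable morphological clusters
(those with at least two taxa shared with the tree) that are
monophyletic on the molecular tree.  The score is this package's
operationalization of a qualitative "clusters coincide" claim and is
labeled as such in every output.  Robinson-Foulds distances between the
morphological dendrogram and the molecular tree (restricted to shared
taxa) are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .molphylo.tree import Tree, TreeError

__all__ = [
    "ConcordanceReport",
    "tree_splits",
    "prune_to_shared",
    "robinson_foulds",
    "cluster_concordance",
    "concordance_report",
]


def tree_splits(tree: Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions of the leaf set, canonically oriented."""
    return tree.splits()


def prune_to_shared(tree: Tree, taxa: set[str]) -> Tree:
    """Restrict the tree to the given taxa (>= 3 required).

    Degree-2 nodes are suppressed with branch lengths summed, so leaf
    path lengths are preserved.
    """
    shared = set(taxa) & set(tree.leaf_labels())
    if len(shared) < 3:
        raise TreeError(f"only {len(shared)} shared taxa; need at least 3")
    if shared == set(tree.leaf_labels()):
        return tree.copy()
    return tree.prune_to(shared)


def robinson_foulds(t1: Tree, t2: Tree) -> tuple[int, float]:
    """RF distance (split symmetric difference) and its normalization.

    Normalized by 2(n-3), the maximum for binary trees on n shared
    leaves.
    """
    l1, l2 = set(t1.leaf_labels()), set(t2.leaf_labels())
    if l1 != l2:
        raise TreeError("leaf sets differ; prune to shared taxa first")
    s1, s2 = t1.splits(), t2.splits()
    rf = len(s1 ^ s2)
    denom = 2 * (len(l1) - 3)
    return rf, (rf / denom if denom > 0 else 0.0)


@dataclass
class ConcordanceReport:
    """Cluster-by-cluster monophyly and the summary concordance score."""

    shared_taxa: list[str]
    monophyly: dict[int, bool]          # evaluable cluster id -> clade on tree?
    singletons: list[int]               # clusters with < 2 shared taxa
    score: float                        # monophyletic / evaluable
    rf: int | None = None
    normalized_rf: float | None = None
    notes: list[str] = field(default_factory=list)


def cluster_concordance(partition: dict[str, int], tree: Tree) -> ConcordanceReport:
    """Score how many morphological clusters are molecular clades.

    Each cluster is restricted to taxa present in the tree; clusters
    with fewer than 2 shared taxa are vacuous and excluded from the
    denominator.  A cluster whose shared taxa are the whole leaf set,
    or whose complement is a single leaf, is trivially monophyletic.
    """
    leaves = set(tree.leaf_labels())
    clusters: dict[int, set[str]] = {}
    for sp, cid in partition.items():
        if sp in leaves:
            clusters.setdefault(cid, set()).add(sp)
    splits = tree.splits()
    monophyly: dict[int, bool] = {}
    singletons: list[int] = []
    for cid, members in sorted(clusters.items()):
        if len(members) < 2:
            singletons.append(cid)
            continue
        if members == leaves or len(leaves - members) <= 1:
            monophyly[cid] = True
            continue
        fs = frozenset(members)
        monophyly[cid] = fs in splits or frozenset(leaves - members) in splits
    if not monophyly:
        raise ValueError("no evaluable cluster (need >= 2 shared taxa in some cluster)")
    score = sum(monophyly.values()) / len(monophyly)
    return ConcordanceReport(
        shared_taxa=sorted(leaves & set(partition)),
        monophyly=monophyly,
        singletons=singletons,
        score=score,
    )


def concordance_report(
    partition: dict[str, int], morpho_tree: Tree, molecular_tree: Tree
) -> ConcordanceReport:
    """Full report: cluster monophyly score plus RF between the trees.

    Both trees are pruned to their shared taxa before the RF
    comparison; the monophyly score uses the molecular tree as-is.
    """
    report = cluster_concordance(partition, molecular_tree)
    shared = set(morpho_tree.leaf_labels()) & set(molecular_tree.leaf_labels())
    try:
        a = prune_to_shared(morpho_tree, shared)
        b = prune_to_shared(molecular_tree, shared)
        report.rf, report.normalized_rf = robinson_foulds(a, b)
    except TreeError as exc:
        report.notes.append(f"RF comparison skipped: {exc}")
    report.notes.append(
        "concordance score is this package's operationalization of "
        "morphological/molecular cluster agreement"
    )
    return report
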