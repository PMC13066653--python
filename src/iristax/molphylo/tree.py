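"""Unrooted phylogenetic trees with branch lengths and edge supports.

The tree is stored as an adjacency structure over integer node ids.
Leaves carry string labels (species or accession names); internal nodes
are unlabeled.  Branch lengths are expected substitutions per site.
Trees are treated as unrooted throughout; Newick serialization roots
the tree at an arbitrary deterministic internal node for display only.
"""

from __future__ import annotations

import io
from typing import Iterable, Iterator

import dendropy

__all__ = ["Tree", "TreeError"]


class TreeError(ValueError):
    pass


class Tree:
    """Unrooted tree: nodes are ints, leaves labeled, edges have lengths.

    ``adj[u]`` maps neighbor node -> edge id; ``edges[e]`` is the pair
    ``(u, v)`` or ``None`` for a removed edge; ``supports[e]`` holds an
    optional bootstrap percentage for internal edges.
    """

    __slots__ = ("adj", "edges", "lengths", "labels", "supports")

    def __init__(self) -> None:
        self.adj: list[dict[int, int]] = []
        self.edges: list[tuple[int, int] | None] = []
        self.lengths: list[float] = []
        self.labels: list[str | None] = []
        self.supports: dict[int, float] = {}

    # -- construction -------------------------------------------------

    def add_node(self, label: str | None = None) -> int:
        self.adj.append({})
        self.labels.append(label)
        return len(self.adj) - 1

    def add_edge(self, u: int, v: int, length: float = 0.0) -> int:
        if u == v:
            raise TreeError("self-edge")
        if v in self.adj[u]:
            raise TreeError(f"edge {u}-{v} already present")
        eid = len(self.edges)
        self.edges.append((u, v))
        self.lengths.append(float(length))
        self.adj[u][v] = eid
        self.adj[v][u] = eid
        return eid

    def remove_edge(self, eid: int) -> None:
        u, v = self.edges[eid]
        del self.adj[u][v]
        del self.adj[v][u]
        self.edges[eid] = None
        self.supports.pop(eid, None)

    def copy(self) -> "Tree":
        t = Tree.__new__(Tree)
        t.adj = [dict(d) for d in self.adj]
        t.edges = list(self.edges)
        t.lengths = list(self.lengths)
        t.labels = list(self.labels)
        t.supports = dict(self.supports)
        return t

    # -- basic queries -------------------------------------------------

    def degree(self, u: int) -> int:
        return len(self.adj[u])

    def nodes(self) -> Iterator[int]:
        return iter(range(len(self.adj)))

    def leaf_nodes(self) -> list[int]:
        return [u for u in self.nodes() if self.labels[u] is not None]

    def leaf_labels(self) -> list[str]:
        return [self.labels[u] for u in self.leaf_nodes()]  # type: ignore[misc]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_nodes())

    def edge_ids(self) -> list[int]:
        return [e for e, uv in enumerate(self.edges) if uv is not None]

    def internal_edge_ids(self) -> list[int]:
        out = []
        for e in self.edge_ids():
            u, v = self.edges[e]  # type: ignore[misc]
            if self.labels[u] is None and self.labels[v] is None:
                out.append(e)
        return out

    def is_binary_unrooted(self) -> bool:
        return all(
            self.degree(u) in (1, 3) for u in self.nodes() if self.adj[u]
        )

    def other_end(self, eid: int, u: int) -> int:
        a, b = self.edges[eid]  # type: ignore[misc]
        return b if a == u else a

    # -- traversal -----------------------------------------------------

    def postorder(self, root: int, banned: int = -1) -> list[tuple[int, int]]:
        """(node, parent) pairs, children before parents, rooted at ``root``.

        ``banned`` excludes one neighbor of the root, restricting the
        traversal to a single component of the edge ``root``-``banned``.
        """
        order: list[tuple[int, int]] = []
        stack = [(root, banned)]
        while stack:
            node, par = stack.pop()
            order.append((node, par))
            for nb in self.adj[node]:
                if nb != par:
                    stack.append((nb, node))
        order.reverse()
        return order

    def path_length(self, a: int, b: int) -> float:
        """Sum of branch lengths on the unique a-b path."""
        dist = {a: 0.0}
        stack = [(a, -1)]
        while stack:
            node, par = stack.pop()
            if node == b:
                return dist[b]
            for nb, eid in self.adj[node].items():
                if nb != par:
                    dist[nb] = dist[node] + self.lengths[eid]
                    stack.append((nb, node))
        raise TreeError("nodes not connected")

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """All pairwise leaf path lengths, keyed by sorted label pairs."""
        leaves = self.leaf_nodes()
        if not leaves:
            return {}
        out: dict[tuple[str, str], float] = {}
        for i, a in enumerate(leaves):
            dist = {a: 0.0}
            stack = [(a, -1)]
            while stack:
                node, par = stack.pop()
                for nb, eid in self.adj[node].items():
                    if nb != par:
                        dist[nb] = dist[node] + self.lengths[eid]
                        stack.append((nb, node))
            for b in leaves[i + 1 :]:
                la, lb = sorted((self.labels[a], self.labels[b]))  # type: ignore[arg-type]
                out[(la, lb)] = dist[b]
        return out

    # -- splits --------------------------------------------------------

    def edge_split(self, eid: int) -> frozenset[str]:
        """Canonical bipartition side induced by an edge.

        The side NOT containing the lexicographically smallest leaf label
        is returned, so splits compare across re-rootings and trees.
        """
        u, v = self.edges[eid]  # type: ignore[misc]
        side = frozenset(
            self.labels[n]
            for n, _ in self.postorder(v, banned=u)
            if self.labels[n] is not None
        )
        ref = min(self.leaf_labels())
        if ref in side:
            side = frozenset(self.leaf_labels()) - side
        return side

    def splits(self) -> set[frozenset[str]]:
        """Nontrivial bipartitions (canonical sides) of the leaf set."""
        out: set[frozenset[str]] = set()
        n = self.n_leaves
        for e in self.edge_ids():
            s = self.edge_split(e)
            if 2 <= len(s) <= n - 2:
                out.add(s)
        return out

    # -- editing -------------------------------------------------------

    def prune_to(self, taxa: Iterable[str]) -> "Tree":
        """Restrict to the given leaf labels; suppress degree-2 nodes.

        Branch lengths across suppressed nodes are summed, so pairwise
        path lengths among kept leaves are preserved.
        """
        keep = set(taxa)
        missing = keep - set(self.leaf_labels())
        if missing:
            raise TreeError(f"taxa not in tree: {sorted(missing)}")
        if len(keep) < 3:
            raise TreeError("need at least 3 shared taxa after pruning")
        t = self.copy()
        t.supports = {}
        # iteratively strip unwanted leaves and bare internal stubs
        changed = True
        while changed:
            changed = False
            for u in t.nodes():
                if len(t.adj[u]) == 1 and (
                    t.labels[u] is None or t.labels[u] not in keep
                ):
                    (eid,) = t.adj[u].values()
                    t.remove_edge(eid)
                    changed = True
        # suppress degree-2 internal nodes
        for u in t.nodes():
            if t.labels[u] is None and len(t.adj[u]) == 2:
                (a, ea), (b, eb) = t.adj[u].items()
                total = t.lengths[ea] + t.lengths[eb]
                t.remove_edge(ea)
                t.remove_edge(eb)
                t.add_edge(a, b, total)
        return t.compact()

    def compact(self) -> "Tree":
        """Drop isolated nodes and deleted edges; renumber densely."""
        t = Tree()
        remap: dict[int, int] = {}
        for u in self.nodes():
            if self.adj[u]:
                remap[u] = t.add_node(self.labels[u])
        for e in self.edge_ids():
            u, v = self.edges[e]  # type: ignore[misc]
            ne = t.add_edge(remap[u], remap[v], self.lengths[e])
            if e in self.supports:
                t.supports[ne] = self.supports[e]
        return t

    # -- Newick --------------------------------------------------------

    def _display_root(self) -> int:
        internal = [u for u in self.nodes() if self.adj[u] and self.labels[u] is None]
        if internal:
            return internal[0]
        return self.leaf_nodes()[0]

    def to_newick(self, include_supports: bool = False) -> str:
        root = self._display_root()

        def fmt(node: int, par: int) -> str:
            children = [nb for nb in sorted(self.adj[node]) if nb != par]
            if not children:
                return self.labels[node] or ""
            inner = ",".join(
                f"{fmt(nb, node)}:{self.lengths[self.adj[node][nb]]:.10g}"
                for nb in children
            )
            label = ""
            if include_supports and par >= 0:
                eid = self.adj[node][par]
                if eid in self.supports:
                    label = str(int(round(self.supports[eid])))
            return f"({inner}){label}"

        return fmt(root, -1) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(
            file=io.StringIO(newick),
            schema="newick",
            preserve_underscores=True,
        )
        t = cls()
        node_map: dict[int, int] = {}
        for nd in dt.preorder_node_iter():
            label = nd.taxon.label if nd.taxon is not None else None
            node_map[id(nd)] = t.add_node(label)
            if nd.parent_node is not None:
                length = nd.edge.length if nd.edge.length is not None else 0.0
                t.add_edge(node_map[id(nd.parent_node)], node_map[id(nd)], length)
        # unroot: suppress a degree-2 root
        root = node_map[id(dt.seed_node)]
        if t.labels[root] is None and len(t.adj[root]) == 2:
            (a, ea), (b, eb) = t.adj[root].items()
            total = t.lengths[ea] + t.lengths[eb]
            t.remove_edge(ea)
            t.remove_edge(eb)
            t.add_edge(a, b, total)
        return t.compact()

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Tree n_leaves={self.n_leaves} edges={len(self.edge_ids())}>"
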