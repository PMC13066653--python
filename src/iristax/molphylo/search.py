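"""Tree inference: neighbor joining, NNI hill climbing, bootstrap supports.

The maximum-likelihood search follows the classic recipe: a
neighbor-joining starting tree from JC69 distances, full branch-length
optimization, then repeated nearest-neighbor-interchange passes.  Every
internal edge contributes two candidate rearrangements; candidates are
scored with a local re-optimization of the five branches around the
edge (the four subtree partials are unchanged by the swap, so this is
exact for the local problem), the single best strictly improving move
is applied, branch lengths are re-optimized globally, and the cycle
repeats until no move improves the log-likelihood by more than 1e-6.

Bootstrap supports resample alignment columns with replacement and run
the full pipeline per replicate; the support of an internal edge of the
full-data tree is the percentage of replicate trees containing the same
bipartition.
"""

from __future__ import annotations

import logging

import numpy as np

from ..distance import DistanceMatrix
from .alignment import Alignment
from .distances import jc69_distance_matrix, jc69_from_codes
from .likelihood import JCEngine, optimize_branch_lengths
from .tree import Tree, TreeError

log = logging.getLogger(__name__)

__all__ = ["neighbor_joining", "nni_search", "bootstrap_support", "infer_ml_tree"]

NNI_MIN_GAIN = 1e-6  # lnL improvement required to accept a rearrangement


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with the standard Q criterion.

    Exact (topology and branch lengths) on additive matrices.  Negative
    branch-length estimates are clamped to zero and the deficit logged.
    """
    n = dm.n
    if n < 3:
        raise TreeError("neighbor joining needs at least 3 taxa")
    size = 2 * n - 2
    D = np.zeros((size, size))
    D[:n, :n] = dm.matrix
    tree = Tree()
    node_of = {i: tree.add_node(dm.labels[i]) for i in range(n)}
    active = list(range(n))
    nxt = n

    def clamp(t: float, what: str) -> float:
        if t < 0:
            log.debug("NJ: clamped negative branch %s (%.3g) to 0", what, t)
            return 0.0
        return t

    while len(active) > 3:
        r = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = divmod(int(np.argmin(q)), r)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        vi = 0.5 * D[i, j] + (row_sums[ai] - row_sums[aj]) / (2.0 * (r - 2))
        vj = D[i, j] - vi
        u = nxt
        nxt += 1
        node_u = tree.add_node()
        node_of[u] = node_u
        tree.add_edge(node_u, node_of[i], clamp(vi, dm.labels[i] if i < n else "internal"))
        tree.add_edge(node_u, node_of[j], clamp(vj, dm.labels[j] if j < n else "internal"))
        for k in active:
            if k not in (i, j):
                D[u, k] = D[k, u] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    center = tree.add_node()
    va = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    vb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    vc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for k, v in ((a, va), (b, vb), (c, vc)):
        tree.add_edge(center, node_of[k], clamp(v, "terminal"))
    return tree


# -- NNI ----------------------------------------------------------------


def _local_optimize(
    engine: JCEngine,
    parts: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    ts: tuple[float, float, float, float, float],
    rounds: int = 2,
) -> tuple[tuple[float, float, float, float, float], float]:
    """Optimize the five branches around one internal edge.

    ``parts`` are the partials of the four flanking subtrees (A,B attach
    to one end; C,D to the other); ``ts`` the pendant lengths and the
    central length.  Only these five lengths vary; the subtree partials
    are fixed, so each coordinate step is the exact concave line search.
    """
    ga, gb, gc, gd = parts
    ta, tb, tc, td, tm = ts
    prop = engine.propagate
    lnl = -np.inf
    for _ in range(rounds):
        lv = prop(gc, tc) * prop(gd, td)
        ta, _ = engine.optimize_edge(ga, prop(gb, tb) * prop(lv, tm), ta)
        tb, _ = engine.optimize_edge(gb, prop(ga, ta) * prop(lv, tm), tb)
        lu = prop(ga, ta) * prop(gb, tb)
        tc, _ = engine.optimize_edge(gc, prop(gd, td) * prop(lu, tm), tc)
        td, _ = engine.optimize_edge(gd, prop(gc, tc) * prop(lu, tm), td)
        lv = prop(gc, tc) * prop(gd, td)
        tm, lnl = engine.optimize_edge(lu, lv, tm)
    return (ta, tb, tc, td, tm), lnl


def nni_search(aln_or_engine: Alignment | JCEngine, start: Tree) -> Tree:
    """NNI hill climbing with local scoring and global re-optimization.

    Deterministic: moves are enumerated in a fixed edge order and ties
    on the gain go to the earliest edge.  Trees without internal edges
    are returned unchanged.
    """
    engine = (
        aln_or_engine
        if isinstance(aln_or_engine, JCEngine)
        else JCEngine.from_alignment(aln_or_engine)
    )
    if not start.internal_edge_ids():
        return start
    if not start.is_binary_unrooted():
        raise TreeError("NNI search requires a binary unrooted tree")
    tree, lnl = optimize_branch_lengths(engine, start)

    while True:
        best_gain = 0.0
        best_move = None
        for eid in sorted(tree.internal_edge_ids()):
            u, v = tree.edges[eid]  # type: ignore[misc]
            nu = [n for n in sorted(tree.adj[u]) if n != v]
            nv = [n for n in sorted(tree.adj[v]) if n != u]
            a, b = nu
            c, d = nv
            ga = engine.component_partial(tree, a, banned=u)
            gb = engine.component_partial(tree, b, banned=u)
            gc = engine.component_partial(tree, c, banned=v)
            gd = engine.component_partial(tree, d, banned=v)
            ta = tree.lengths[tree.adj[u][a]]
            tb = tree.lengths[tree.adj[u][b]]
            tc = tree.lengths[tree.adj[v][c]]
            td = tree.lengths[tree.adj[v][d]]
            tm = tree.lengths[eid]
            # swap b<->c : (a,c | b,d);  swap b<->d : (a,d | b,c)
            for which, parts, ts in (
                ("bc", (ga, gc, gb, gd), (ta, tc, tb, td, tm)),
                ("bd", (ga, gd, gb, gc), (ta, td, tb, tc, tm)),
            ):
                new_ts, cand_lnl = _local_optimize(engine, parts, ts)
                gain = cand_lnl - lnl
                if gain > max(NNI_MIN_GAIN, best_gain):
                    best_gain = gain
                    best_move = (eid, which, new_ts)
        if best_move is None:
            return tree
        eid, which, new_ts = best_move
        u, v = tree.edges[eid]  # type: ignore[misc]
        nu = [n for n in sorted(tree.adj[u]) if n != v]
        nv = [n for n in sorted(tree.adj[v]) if n != u]
        a, b = nu
        c, d = nv
        swap_in, stays = (c, d) if which == "bc" else (d, c)
        ta, tx, tb, ty, tm = new_ts
        tree.remove_edge(tree.adj[u][b])
        tree.remove_edge(tree.adj[v][swap_in])
        tree.add_edge(u, swap_in, tx)
        tree.add_edge(v, b, tb)
        tree.lengths[tree.adj[u][a]] = ta
        tree.lengths[tree.adj[v][stays]] = ty
        tree.lengths[eid] = tm
        tree, lnl = optimize_branch_lengths(engine, tree)


# -- bootstrap -----------------------------------------------------------


def _infer_from_codes(codes: np.ndarray, ids: list[str]) -> Tree:
    dm = jc69_from_codes(codes, ids)
    start = neighbor_joining(dm)
    engine = JCEngine(codes, ids)
    return nni_search(engine, start)


def bootstrap_support(
    aln: Alignment, b_replicates: int, seed: int, tree: Tree | None = None
) -> Tree:
    """Nonparametric bootstrap: site resampling, full re-inference.

    Returns the best full-data tree with a support percentage attached
    to every internal edge.  Deterministic given the seed.
    """
    if b_replicates < 1:
        raise ValueError("bootstrap needs at least 1 replicate")
    codes = aln.encoded()
    if tree is None:
        tree = _infer_from_codes(codes, list(aln.ids))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    length = codes.shape[1]
    for _ in range(b_replicates):
        idx = rng.integers(0, length, size=length)
        rep_tree = _infer_from_codes(codes[:, idx], list(aln.ids))
        for split in rep_tree.splits():
            counts[split] = counts.get(split, 0) + 1
    out = tree.copy()
    out.supports = {}
    for eid in out.internal_edge_ids():
        split = out.edge_split(eid)
        out.supports[eid] = 100.0 * counts.get(split, 0) / b_replicates
    return out


def infer_ml_tree(
    aln: Alignment, bootstrap: int = 0, seed: int | None = None
) -> Tree:
    """Full inference: JC distances -> NJ -> branch opt -> NNI [-> bootstrap]."""
    dm = jc69_distance_matrix(aln)
    start = neighbor_joining(dm)
    engine = JCEngine.from_alignment(aln)
    tree = nni_search(engine, start)
    if bootstrap > 0:
        if seed is None:
            raise ValueError("bootstrap requires a seed")
        tree = bootstrap_support(aln, bootstrap, seed, tree=tree)
    return tree
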