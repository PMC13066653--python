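"""Felsenstein-pruning log-likelihood under JC69, with branch optimization.

The JC69 transition matrix has a one-parameter structure: with
e = exp(-4t/3), P(t) v = e v + ((1-e)/4) (sum of v).  Both the pruning
recursion and the per-branch likelihood exploit this: for any edge the
site likelihood is linear in e, L_p(e) = a_p + b_p e, computed from the
partial likelihoods of the two components flanking the edge.  log of a
linear function is concave, so the per-branch line search has a unique
maximum on the branch-length box.

Gaps and N contribute all-ones partials (missing data).  Site patterns
are compressed with multiplicities before any computation.
"""

from __future__ import annotations

import numpy as np

from .alignment import Alignment
from .tree import Tree, TreeError

__all__ = ["JCEngine", "tree_log_likelihood", "optimize_branch_lengths",
           "MIN_BRANCH", "MAX_BRANCH", "LNL_TOL"]

MIN_BRANCH = 1e-8   # lower branch-length bound (substitutions/site)
MAX_BRANCH = 10.0   # upper bound; far beyond biological saturation
LNL_TOL = 1e-4      # stop sweeping when a full sweep gains less lnL


def compress_patterns(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique site patterns (n, P) and their multiplicities (P,)."""
    patterns, counts = np.unique(codes.T, axis=0, return_counts=True)
    return patterns.T.copy(), counts.astype(float)


class JCEngine:
    """Pruning likelihood for one alignment over arbitrary trees.

    Trees are matched to the alignment by leaf label == accession id.
    """

    def __init__(self, codes: np.ndarray, ids: list[str]):
        self.ids = list(ids)
        self.patterns, self.weights = compress_patterns(codes)
        self.n_sites = int(self.weights.sum())
        base = np.arange(4, dtype=np.uint8)[:, None]
        self.tips: dict[str, np.ndarray] = {}
        for k, acc in enumerate(self.ids):
            pat = self.patterns[k]
            tip = ((pat[None, :] == base) | (pat[None, :] == 4)).astype(float)
            self.tips[acc] = tip

    @classmethod
    def from_alignment(cls, aln: Alignment) -> "JCEngine":
        return cls(aln.encoded(), aln.ids)

    # -- primitives ----------------------------------------------------

    @staticmethod
    def propagate(partial: np.ndarray, t: float) -> np.ndarray:
        """Apply the JC69 transition matrix across a branch of length t."""
        e = np.exp(-4.0 * t / 3.0)
        return e * partial + ((1.0 - e) / 4.0) * partial.sum(axis=0)

    def _check_tree(self, tree: Tree) -> None:
        labels = tree.leaf_labels()
        if sorted(labels) != sorted(self.ids):
            raise TreeError("tree leaf labels do not match alignment ids")
        for e in tree.edge_ids():
            if tree.lengths[e] < 0:
                raise TreeError(f"negative branch length on edge {e}")

    def component_partial(self, tree: Tree, node: int, banned: int = -1) -> np.ndarray:
        """Partial likelihood at ``node`` of the component away from ``banned``."""
        partials: dict[int, np.ndarray] = {}
        for nd, par in tree.postorder(node, banned=banned):
            label = tree.labels[nd]
            part = self.tips[label].copy() if label is not None else None
            for nb, eid in tree.adj[nd].items():
                if nb == par or (nd == node and nb == banned):
                    continue
                contrib = self.propagate(partials.pop(nb), tree.lengths[eid])
                part = contrib if part is None else part * contrib
            if part is None:  # isolated internal node (cannot happen on valid trees)
                raise TreeError("internal node with no children in traversal")
            partials[nd] = part
        return partials[node]

    def loglik(self, tree: Tree) -> float:
        self._check_tree(tree)
        root = tree._display_root()
        part = self.component_partial(tree, root)
        site_l = 0.25 * part.sum(axis=0)
        if np.any(site_l <= 0) or not np.all(np.isfinite(site_l)):
            raise ArithmeticError("non-finite site likelihood")
        return float(self.weights @ np.log(site_l))

    # -- per-branch line search -----------------------------------------

    def edge_ab(self, fu: np.ndarray, fv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Coefficients of L_p(e) = a_p + b_p e for one edge."""
        a = fu.sum(axis=0) * fv.sum(axis=0) / 16.0
        b = 0.25 * (fu * fv).sum(axis=0) - a
        return a, b

    def edge_loglik(self, fu: np.ndarray, fv: np.ndarray, t: float) -> float:
        a, b = self.edge_ab(fu, fv)
        e = np.exp(-4.0 * t / 3.0)
        return float(self.weights @ np.log(np.maximum(a + b * e, 1e-300)))

    def optimize_edge(self, fu: np.ndarray, fv: np.ndarray, t0: float) -> tuple[float, float]:
        """Best branch length (and lnL) for the edge flanked by fu, fv.

        Works on e = exp(-4t/3): the objective sum w log(a + b e) is
        concave in e, so a safeguarded Newton iteration on its (strictly
        decreasing) derivative finds the unique interior maximum; if the
        derivative does not change sign on the box, the maximum sits on
        the corresponding branch-length bound.
        """
        a, b = self.edge_ab(fu, fv)
        w = self.weights
        e_lo = np.exp(-4.0 * MAX_BRANCH / 3.0)
        e_hi = np.exp(-4.0 * MIN_BRANCH / 3.0)

        def lnl_at(e: float) -> float:
            return float(w @ np.log(np.maximum(a + b * e, 1e-300)))

        def deriv(e: float) -> tuple[float, float]:
            ratio = b / np.maximum(a + b * e, 1e-300)
            wr = w * ratio
            return float(wr.sum()), -float(wr @ ratio)

        d_hi, _ = deriv(e_hi)
        d_lo, _ = deriv(e_lo)
        if d_hi >= 0.0:
            e_best = e_hi
        elif d_lo <= 0.0:
            e_best = e_lo
        else:
            lo, hi = e_lo, e_hi  # deriv(lo) > 0 > deriv(hi)
            e = min(max(np.exp(-4.0 * t0 / 3.0), e_lo), e_hi)
            for _ in range(60):
                d1, d2 = deriv(e)
                if d1 > 0.0:
                    lo = e
                else:
                    hi = e
                step = d1 / d2 if d2 < 0.0 else 0.0
                e_new = e - step
                if not lo < e_new < hi:
                    e_new = 0.5 * (lo + hi)
                if abs(e_new - e) <= 1e-12 * max(e, 1e-12) or hi - lo <= 1e-14:
                    e = e_new
                    break
                e = e_new
            e_best = e
        t_best = float(min(max(-0.75 * np.log(e_best), MIN_BRANCH), MAX_BRANCH))
        t_cur = min(max(t0, MIN_BRANCH), MAX_BRANCH)
        lnl_best = lnl_at(np.exp(-4.0 * t_best / 3.0))
        lnl_cur = lnl_at(np.exp(-4.0 * t_cur / 3.0))
        if lnl_cur > lnl_best:
            return t_cur, lnl_cur
        return t_best, lnl_best


def tree_log_likelihood(aln: Alignment, tree: Tree) -> float:
    """Pruning log-likelihood of the alignment on the tree under JC69."""
    return JCEngine.from_alignment(aln).loglik(tree)


def optimize_branch_lengths(
    aln_or_engine: Alignment | JCEngine,
    tree: Tree,
    tol: float = LNL_TOL,
    max_sweeps: int = 50,
) -> tuple[Tree, float]:
    """Coordinate-wise branch-length optimization.

    Sweeps every branch with the concave JC line search until a full
    sweep improves lnL by less than ``tol``.  lnL is nondecreasing
    across sweeps by construction.
    """
    engine = (
        aln_or_engine
        if isinstance(aln_or_engine, JCEngine)
        else JCEngine.from_alignment(aln_or_engine)
    )
    engine._check_tree(tree)
    tree = tree.copy()
    prev = engine.loglik(tree)
    cur = prev
    for _ in range(max_sweeps):
        for eid in tree.edge_ids():
            u, v = tree.edges[eid]  # type: ignore[misc]
            fu = engine.component_partial(tree, u, banned=v)
            fv = engine.component_partial(tree, v, banned=u)
            t_opt, lnl = engine.optimize_edge(fu, fv, tree.lengths[eid])
            tree.lengths[eid] = t_opt
            cur = lnl
        if not np.isfinite(cur):
            raise ArithmeticError("non-finite log-likelihood during optimization")
        if cur - prev < tol:
            break
        prev = cur
    return tree, cur
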