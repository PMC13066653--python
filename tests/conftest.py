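"""Shared fixtures and independent reference implementations (oracles)."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from iristax.molphylo.tree import Tree

settings.register_profile("suite", derandomize=True, max_examples=25)
settings.load_profile("suite")


# -- random tree construction -------------------------------------------


def random_binary_tree(n_leaves: int, rng: np.random.Generator,
                       min_bl: float = 0.02, max_bl: float = 0.3) -> Tree:
    """Random unrooted binary tree grown by stepwise leaf insertion."""
    t = Tree()
    center = t.add_node()
    for i in range(3):
        leaf = t.add_node(f"t{i + 1}")
        t.add_edge(center, leaf, rng.uniform(min_bl, max_bl))
    for i in range(3, n_leaves):
        eid = rng.choice(t.edge_ids())
        u, v = t.edges[eid]
        length = t.lengths[eid]
        t.remove_edge(eid)
        mid = t.add_node()
        split = rng.uniform(0.2, 0.8)
        t.add_edge(u, mid, length * split)
        t.add_edge(mid, v, length * (1 - split))
        leaf = t.add_node(f"t{i + 1}")
        t.add_edge(mid, leaf, rng.uniform(min_bl, max_bl))
    return t.compact()


# -- likelihood oracle: exhaustive state enumeration --------------------


def _jc_p(t: float) -> np.ndarray:
    e = np.exp(-4.0 * t / 3.0)
    p = np.full((4, 4), (1.0 - e) / 4.0)
    np.fill_diagonal(p, 0.25 + 0.75 * e)
    return p


def loglik_enumeration(tree: Tree, codes: dict[str, np.ndarray]) -> float:
    """Brute-force JC69 log-likelihood: sum over all unobserved states.

    Every internal node — and every leaf site that is missing — is
    summed over its four states explicitly.  Exponential in tree size;
    usable up to ~6 leaves.
    """
    import itertools

    nodes = list(tree.nodes())
    leaves = {u for u in nodes if tree.labels[u] is not None}
    free = [u for u in nodes if u not in leaves]
    length = len(next(iter(codes.values())))
    edge_list = [(u, v, _jc_p(tree.lengths[e]))
                 for e, (u, v) in ((e, tree.edges[e]) for e in tree.edge_ids())]
    root = free[0] if free else nodes[0]
    total = 0.0
    for site in range(length):
        site_sum = 0.0
        leaf_state = {u: int(codes[tree.labels[u]][site]) for u in leaves}
        missing = [u for u in leaves if leaf_state[u] == 4]
        enum_nodes = free + missing
        for assign in itertools.product(range(4), repeat=len(enum_nodes)):
            state = dict(zip(enum_nodes, assign))
            for u in leaves:
                if u not in state:
                    state[u] = leaf_state[u]
            prob = 0.25  # stationary at the (arbitrary) root
            for u, v, p in edge_list:
                prob *= p[state[u], state[v]]
            site_sum += prob
        total += np.log(site_sum)
    return float(total)


# -- Ward oracle: greedy minimum-variance merging -----------------------


def ward_greedy_oracle(points: np.ndarray, labels: list[str]):
    """Exhaustive greedy Ward agglomeration on raw coordinates.

    At every step all cluster pairs are scanned and the merge with the
    smallest increase in total within-cluster sum of squares is taken.
    Returns [(member set A, member set B, sqrt(2*delta_ESS))].
    """
    clusters: list[tuple[frozenset[str], np.ndarray]] = [
        (frozenset([lab]), points[i : i + 1]) for i, lab in enumerate(labels)
    ]

    def ess(block: np.ndarray) -> float:
        return float(((block - block.mean(axis=0)) ** 2).sum())

    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                merged = np.vstack([clusters[i][1], clusters[j][1]])
                delta = ess(merged) - ess(clusters[i][1]) - ess(clusters[j][1])
                if best is None or delta < best[0] - 1e-15:
                    best = (delta, i, j)
        delta, i, j = best
        merges.append(
            (clusters[i][0], clusters[j][0], float(np.sqrt(2.0 * delta)))
        )
        merged = (
            clusters[i][0] | clusters[j][0],
            np.vstack([clusters[i][1], clusters[j][1]]),
        )
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return merges


# -- textbook statistic oracles -----------------------------------------


def anova_textbook(groups) -> float:
    """One-way ANOVA F from the definition (sums of squares)."""
    groups = [np.asarray(g, float) for g in groups]
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = len(allv) - len(groups)
    if ssw == 0 and ssb == 0:
        return 0.0
    return float((ssb / dfb) / (ssw / dfw))


def kruskal_textbook(groups) -> float:
    """Kruskal-Wallis H with the standard tie correction."""
    from scipy.stats import rankdata  # ranking only; H is assembled by hand

    groups = [np.asarray(g, float) for g in groups]
    allv = np.concatenate(groups)
    n = len(allv)
    ranks = rankdata(allv)
    pos = 0
    h = 0.0
    for g in groups:
        r = ranks[pos : pos + len(g)]
        h += r.sum() ** 2 / len(g)
        pos += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(allv, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if correction == 0:
        return 0.0
    return float(h / correction)


def rm2_naive(matrix, species: str, trait: str) -> float:
    """Mean squared Pearson correlation by an explicit double loop."""
    sub = matrix[matrix["species"] == species]
    traits = [c for c in matrix.columns
              if c not in ("species", "year", "individual_id")]
    x = sub[trait].to_numpy(float)
    out = []
    for other in traits:
        if other == trait:
            continue
        y = sub[other].to_numpy(float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
            continue
        xm, ym = x[ok] - x[ok].mean(), y[ok] - y[ok].mean()
        r = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
        out.append(r * r)
    return float(np.mean(out))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
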