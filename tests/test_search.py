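"""NJ exactness, NNI search vs exhaustive quartets, bootstrap behavior."""

import numpy as np
import pytest

from iristax.distance import DistanceMatrix
from iristax.molphylo import (
    Alignment,
    bootstrap_support,
    infer_ml_tree,
    jc69_distance_matrix,
    neighbor_joining,
    nni_search,
    optimize_branch_lengths,
)
from iristax.molphylo.likelihood import JCEngine
from iristax.molphylo.tree import Tree, TreeError
from iristax.simulate import SeqSimSpec, simulate_alignment

from conftest import random_binary_tree


def matrix_from_tree(tree: Tree) -> DistanceMatrix:
    labels = sorted(tree.leaf_labels())
    dists = tree.leaf_distances()
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = dists[tuple(sorted((labels[i], labels[j])))]
    return DistanceMatrix(labels=labels, matrix=m)


def test_nj_recovers_quartet_with_internal_branch():
    # additive matrix of AB|CD with tip branches 0.1 and internal 0.1
    labels = ["A", "B", "C", "D"]
    m = np.array([
        [0.0, 0.2, 0.3, 0.3],
        [0.2, 0.0, 0.3, 0.3],
        [0.3, 0.3, 0.0, 0.2],
        [0.3, 0.3, 0.2, 0.0],
    ])
    tree = neighbor_joining(DistanceMatrix(labels=labels, matrix=m))
    assert frozenset({"C", "D"}) in tree.splits() or frozenset({"A", "B"}) in tree.splits()
    d = tree.leaf_distances()
    assert d[("A", "B")] == pytest.approx(0.2, abs=1e-12)
    assert d[("A", "C")] == pytest.approx(0.3, abs=1e-12)


def test_nj_three_leaves_exact():
    m = np.array([[0.0, 0.3, 0.4], [0.3, 0.0, 0.5], [0.4, 0.5, 0.0]])
    tree = neighbor_joining(DistanceMatrix(labels=["a", "b", "c"], matrix=m))
    d = tree.leaf_distances()
    assert d[("a", "b")] == pytest.approx(0.3, abs=1e-12)
    assert d[("a", "c")] == pytest.approx(0.4, abs=1e-12)
    assert d[("b", "c")] == pytest.approx(0.5, abs=1e-12)


def test_nj_exact_on_random_additive_matrices(rng):
    for _ in range(20):
        n = int(rng.integers(4, 9))
        truth = random_binary_tree(n, rng)
        dm = matrix_from_tree(truth)
        inferred = neighbor_joining(dm)
        assert inferred.splits() == truth.splits()
        d = inferred.leaf_distances()
        for pair, dist in truth.leaf_distances().items():
            assert d[pair] == pytest.approx(dist, abs=1e-10)


def test_nj_requires_three_taxa():
    with pytest.raises(TreeError):
        neighbor_joining(
            DistanceMatrix(labels=["a", "b"], matrix=np.array([[0.0, 1.0], [1.0, 0.0]]))
        )


def quartet_alignment(rng, seed: int):
    tree = random_binary_tree(4, rng, min_bl=0.03, max_bl=0.25)
    spec = SeqSimSpec(
        species_tree=tree.to_newick(), seq_length=500,
        accessions_per_species=1, intra_species_subs=0, seed=seed,
    )
    aln, _ = simulate_alignment(spec)
    aln = Alignment(
        ids=[i.removesuffix("_a1") for i in aln.ids],
        species=aln.species, seqs=aln.seqs,
    )
    return aln


def exhaustive_quartet_ml(aln: Alignment):
    """Oracle: optimize all three quartet topologies, return the best."""
    a, b, c, d = aln.ids
    best = None
    for pairing in ((b, c, d), (c, b, d), (d, b, c)):
        t = Tree()
        u, v = t.add_node(), t.add_node()
        t.add_edge(u, v, 0.05)
        t.add_edge(u, t.add_node(a), 0.1)
        t.add_edge(u, t.add_node(pairing[0]), 0.1)
        t.add_edge(v, t.add_node(pairing[1]), 0.1)
        t.add_edge(v, t.add_node(pairing[2]), 0.1)
        opt, lnl = optimize_branch_lengths(aln, t)
        if best is None or lnl > best[1]:
            best = (opt, lnl)
    return best


def test_nni_finds_quartet_ml_topology(rng):
    hits = 0
    for k in range(10):
        aln = quartet_alignment(rng, seed=100 + k)
        oracle_tree, oracle_lnl = exhaustive_quartet_ml(aln)
        result = nni_search(aln, neighbor_joining(jc69_distance_matrix(aln)))
        engine = JCEngine.from_alignment(aln)
        lnl = engine.loglik(result)
        if result.splits() == oracle_tree.splits():
            hits += 1
        assert lnl >= oracle_lnl - 1e-3
    assert hits >= 9


def test_nni_keeps_ml_topology_fixed_point(rng):
    aln = quartet_alignment(rng, seed=7)
    oracle_tree, _ = exhaustive_quartet_ml(aln)
    result = nni_search(aln, oracle_tree)
    assert result.splits() == oracle_tree.splits()


def test_nni_three_taxa_returned_unchanged():
    t = Tree()
    c = t.add_node()
    for lab in "abc":
        t.add_edge(c, t.add_node(lab), 0.1)
    aln = Alignment(ids=["a", "b", "c"], species=["s"] * 3, seqs=["ACGT"] * 3)
    assert nni_search(aln, t) is t


def test_bootstrap_unanimous_split_gets_full_support():
    # every variable site supports ab|cd; constant sites keep p < 3/4
    seqs = ["AAAACCCCCCCC", "AAAACCCCCCCC", "GGGGCCCCCCCC", "GGGGCCCCCCCC"]
    aln = Alignment(ids=list("abcd"), species=list("abcd"), seqs=seqs)
    tree = bootstrap_support(aln, b_replicates=20, seed=5)
    (eid,) = tree.internal_edge_ids()
    assert tree.supports[eid] == pytest.approx(100.0)


def test_bootstrap_supports_bounded_and_deterministic():
    spec = SeqSimSpec(
        species_tree="((a:0.05,b:0.05):0.03,(c:0.05,d:0.05):0.03,e:0.08);",
        seq_length=300, accessions_per_species=1, intra_species_subs=0, seed=3,
    )
    aln, _ = simulate_alignment(spec)
    t1 = bootstrap_support(aln, b_replicates=20, seed=9)
    t2 = bootstrap_support(aln, b_replicates=20, seed=9)
    s1 = {t1.edge_split(e): v for e, v in t1.supports.items()}
    s2 = {t2.edge_split(e): v for e, v in t2.supports.items()}
    assert s1 == s2
    assert all(0.0 <= v <= 100.0 for v in s1.values())


def test_bootstrap_needs_at_least_one_replicate():
    aln = Alignment(ids=list("abcd"), species=list("abcd"), seqs=["ACGT"] * 4)
    with pytest.raises(ValueError):
        bootstrap_support(aln, b_replicates=0, seed=1)


def test_infer_ml_tree_recovers_simulated_splits():
    spec = SeqSimSpec(
        species_tree="((a:0.03,b:0.03):0.04,(c:0.03,d:0.03):0.04,(e:0.03,f:0.03):0.04);",
        seq_length=1000, accessions_per_species=1, intra_species_subs=0, seed=21,
    )
    aln, _ = simulate_alignment(spec)
    aln = Alignment(
        ids=[i.removesuffix("_a1") for i in aln.ids],
        species=aln.species, seqs=aln.seqs,
    )
    tree = infer_ml_tree(aln)
    truth = Tree.from_newick(spec.species_tree)
    assert truth.splits() <= tree.splits()
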