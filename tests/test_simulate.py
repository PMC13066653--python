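"""Generators: determinism, planted structure, moment convergence."""

import numpy as np
import pandas as pd
import pytest

from iristax.molphylo import read_alignment, write_alignment
from iristax.simulate import (
    MorphoSimSpec,
    SeqSimSpec,
    SimulationError,
    TraitSpec,
    default_study_spec,
    simulate_alignment,
    simulate_morphometrics,
    with_seed,
)


def small_spec(seed=5, **kwargs):
    traits = kwargs.pop("traits", (
        TraitSpec("a", "taxonomic", 4.0),
        TraitSpec("b", "taxonomic", 3.0),
        TraitSpec("c", "systemic", 15.0, "blk", 0.8),
        TraitSpec("d", "systemic", 15.0, "blk", 0.8),
    ))
    return MorphoSimSpec(traits=traits, n_species=3,
                         n_individuals_per_species=10, seed=seed, **kwargs)


def test_morphometrics_deterministic():
    m1, _ = simulate_morphometrics(small_spec())
    m2, _ = simulate_morphometrics(small_spec())
    pd.testing.assert_frame_equal(m1, m2)


def test_different_seed_changes_data():
    m1, _ = simulate_morphometrics(small_spec(seed=5))
    m2, _ = simulate_morphometrics(small_spec(seed=6))
    assert not m1.equals(m2)


def test_default_study_dimensions():
    morpho, seq = default_study_spec()
    assert len(morpho.traits) == 14
    assert morpho.n_species == 11
    assert morpho.n_individuals_per_species == 25
    planted = [t for t in morpho.traits if t.planted_class == "taxonomic"]
    assert len(planted) == 10
    assert len(set(morpho.species_groups)) == 5
    matrix, truth = simulate_morphometrics(morpho)
    assert len(matrix) == 11 * 25
    assert matrix.shape[1] == 3 + 14
    assert set(truth.species_clusters.values()) == {1, 2, 3, 4, 5}


def test_realized_cv_near_target_across_species():
    # cv target 4 %: realized per-species CV should mostly sit in [2, 6]
    morpho, _ = default_study_spec()
    hit = total = 0
    for seed in range(10):
        matrix, _ = simulate_morphometrics(with_seed(morpho, seed))
        for sp, grp in matrix.groupby("species"):
            v = grp["outer_perianth_lobe_length"]
            cv = 100 * v.std(ddof=1) / v.mean()
            total += 1
            hit += 2.0 <= cv <= 6.0
    assert hit / total >= 0.9


def test_moment_convergence_at_large_n():
    spec = MorphoSimSpec(
        traits=(
            TraitSpec("x", "taxonomic", 5.0),
            TraitSpec("y", "systemic", 12.0, "blk", 0.7),
            TraitSpec("z", "systemic", 12.0, "blk", 0.7),
        ),
        n_species=2, n_individuals_per_species=10_000, n_years=1, seed=1,
    )
    matrix, _ = simulate_morphometrics(spec)
    sub = matrix[matrix["species"] == "sp01"]
    cv = 100 * sub["x"].std(ddof=1) / sub["x"].mean()
    assert cv == pytest.approx(5.0, rel=0.02)
    r = np.corrcoef(sub["y"], sub["z"])[0, 1]
    assert r == pytest.approx(0.7, rel=0.02)


def test_year_shift_moves_year_means():
    spec = small_spec(year_shifts=(("a", 5.0),), n_years=2)
    matrix, _ = simulate_morphometrics(spec)
    shifts = []
    for _, grp in matrix.groupby("species"):
        y1 = grp[grp["year"] == "Y1"]["a"]
        y2 = grp[grp["year"] == "Y2"]["a"]
        within_sd = 0.5 * (y1.std(ddof=1) + y2.std(ddof=1))
        shifts.append((y2.mean() - y1.mean()) / within_sd)
    assert min(shifts) > 2.0


def test_invalid_specs_rejected():
    with pytest.raises(SimulationError):
        MorphoSimSpec(traits=(TraitSpec("a", "taxonomic", 4.0),), n_species=1)
    with pytest.raises(SimulationError):
        TraitSpec("a", "nonsense", 4.0)
    with pytest.raises(SimulationError):
        TraitSpec("a", "taxonomic", -1.0)
    with pytest.raises(SimulationError):
        SeqSimSpec(species_tree="(a:0.1,b:0.1);", seq_length=0)
    with pytest.raises(SimulationError):
        SeqSimSpec(species_tree="(a:0.1,b:0.1);", seq_length=5,
                   intra_species_subs=9)


# -- sequences -----------------------------------------------------------

TRIPLE = "((a:0.02,b:0.02):0.03,(c:0.02,d:0.02):0.03,e:0.05);"


def test_alignment_deterministic():
    spec = SeqSimSpec(species_tree=TRIPLE, seq_length=200, seed=4)
    a1, t1 = simulate_alignment(spec)
    a2, t2 = simulate_alignment(spec)
    assert a1.seqs == a2.seqs
    assert t1.haplotypes == t2.haplotypes


def test_zero_branch_lengths_give_identical_sequences():
    spec = SeqSimSpec(
        species_tree="((a:0,b:0):0,(c:0,d:0):0);", seq_length=100,
        accessions_per_species=2, intra_species_subs=0, seed=8,
    )
    aln, _ = simulate_alignment(spec)
    assert len(set(aln.seqs)) == 1


def test_two_leaf_mismatch_fraction_matches_closed_form():
    # total path t = 0.1 split across two branches; long sequence
    length = 100_000
    spec = SeqSimSpec(species_tree="(a:0.05,b:0.05);", seq_length=length,
                      accessions_per_species=1, intra_species_subs=0, seed=13)
    aln, _ = simulate_alignment(spec)
    mism = sum(x != y for x, y in zip(aln.seqs[0], aln.seqs[1])) / length
    expected = 0.75 * (1 - np.exp(-0.4 / 3))
    se = np.sqrt(expected * (1 - expected) / length)
    assert abs(mism - expected) <= 3 * se


def test_accession_variant_construction_bounds():
    spec = SeqSimSpec(species_tree=TRIPLE, seq_length=400,
                      accessions_per_species=3, intra_species_subs=1, seed=17)
    aln, truth = simulate_alignment(spec)
    for sp in set(aln.species):
        idx = aln.records_for_species(sp)
        assert len(idx) == 3
        haps = {truth.haplotypes[aln.ids[i]] for i in idx}
        assert len(haps) <= 3
        for i in idx:
            for j in idx:
                diff = sum(x != y for x, y in zip(aln.seqs[i], aln.seqs[j]))
                assert diff <= 2


def test_generated_fasta_round_trips_through_reader(tmp_path):
    spec = SeqSimSpec(species_tree=TRIPLE, seq_length=150,
                      accessions_per_species=2, seed=19)
    aln, _ = simulate_alignment(spec)
    path = tmp_path / "sim.fasta"
    write_alignment(aln, path)
    back = read_alignment(path)
    assert back.ids == aln.ids
    assert back.species == aln.species
    assert back.seqs == aln.seqs
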