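"""Summary statistics, normality routing, r_m² and the year screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from iristax.simulate import MorphoSimSpec, TraitSpec, simulate_morphometrics
from iristax.tables import read_trait_table, write_trait_table
from iristax.variability import (
    consistent_variability,
    kruskal_wallis,
    ks_normality,
    oneway_anova,
    trait_summary,
    variability_structure,
    year_homogeneity_screen,
)

from conftest import anova_textbook, kruskal_textbook, rm2_naive


def frame(**cols):
    n = len(next(iter(cols.values())))
    base = {"species": ["sp"] * n, "year": ["Y1"] * n,
            "individual_id": [f"i{k}" for k in range(n)]}
    return pd.DataFrame({**base, **cols})


# -- trait_summary -------------------------------------------------------

def test_constant_sample_summary():
    s = trait_summary([10, 10, 10])
    assert (s.mean, s.sd, s.cv_pct) == (10, 0, 0)


def test_hand_arithmetic_case():
    s = trait_summary([8, 10, 12])
    assert s.mean == pytest.approx(10)
    assert s.sd == pytest.approx(2)
    assert s.sem == pytest.approx(2 / np.sqrt(3))
    assert s.cv_pct == pytest.approx(20)


@given(st.floats(min_value=0.01, max_value=1e4))
@settings(max_examples=30)
def test_cv_scale_invariant_under_multiplication(factor):
    base = np.array([3.0, 4.0, 5.5, 6.25])
    assert trait_summary(base * factor).cv_pct == pytest.approx(
        trait_summary(base).cv_pct, rel=1e-9
    )


def test_summary_errors():
    with pytest.raises(ValueError):
        trait_summary([5.0])
    with pytest.raises(ValueError):
        trait_summary([-3.0, 1.0])  # mean <= 0: CV undefined


# -- normality -----------------------------------------------------------

def test_exact_normal_quantiles_pass():
    q = stats.norm.ppf((np.arange(1, 21) - 0.5) / 20)
    d, p, ok = ks_normality(q, alpha=0.05)
    assert d < 0.1
    assert ok


def test_two_point_mass_fails():
    values = np.array([0.0, 100.0] * 10)
    _, p, ok = ks_normality(values, alpha=0.05)
    assert not ok
    assert p < 0.05


def test_constant_sample_errors():
    with pytest.raises(ValueError):
        ks_normality([5.0] * 10)


# -- ANOVA / Kruskal-Wallis ---------------------------------------------

def test_identical_groups_f_zero():
    f, p = oneway_anova([[1, 2, 3], [1, 2, 3]])
    assert f == 0.0


def test_anova_hand_case():
    f, _ = oneway_anova([[1, 2], [5, 6]])
    assert f == pytest.approx(32.0, abs=1e-10)


def test_anova_one_group_errors():
    with pytest.raises(ValueError):
        oneway_anova([[1, 2, 3]])


def test_kruskal_hand_case():
    h, _ = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
    assert h == pytest.approx(kruskal_textbook([[1, 2, 3], [4, 5, 6]]), abs=1e-12)
    assert h == pytest.approx(3.857142857, abs=1e-6)


def test_kruskal_identical_observations_h_zero():
    h, p = kruskal_wallis([[2, 2], [2, 2]])
    assert (h, p) == (0.0, 1.0)


def test_kruskal_empty_group_errors():
    with pytest.raises(ValueError):
        kruskal_wallis([[1], [2], []])


def test_statistics_match_textbook_oracles(rng):
    for _ in range(50):
        k = int(rng.integers(2, 5))
        groups = [rng.normal(rng.uniform(-1, 1), 1, rng.integers(3, 9))
                  for _ in range(k)]
        f, _ = oneway_anova(groups)
        assert f == pytest.approx(anova_textbook(groups), abs=1e-10)
        h, _ = kruskal_wallis(groups)
        assert h == pytest.approx(kruskal_textbook(groups), abs=1e-10)


# -- consistent variability ----------------------------------------------

def test_rm2_linear_pair_is_one():
    df = frame(a=[1.0, 2, 3, 4], b=[2.0, 4, 6, 8])
    assert consistent_variability(df, "sp", "a") == pytest.approx(1.0)
    assert consistent_variability(df, "sp", "b") == pytest.approx(1.0)


def test_rm2_uncorrelated_pair_is_zero():
    df = frame(a=[1.0, 2, 3], b=[2.0, 1, 2])
    assert consistent_variability(df, "sp", "a") == pytest.approx(0.0, abs=1e-12)


def test_rm2_anticorrelated_pair_is_one():
    df = frame(a=[1.0, 2, 3], b=[3.0, 2, 1])
    assert consistent_variability(df, "sp", "a") == pytest.approx(1.0)


def test_rm2_matches_naive_double_loop(rng):
    spec = MorphoSimSpec(
        traits=tuple(
            TraitSpec(f"t{i}", "taxonomic", 5.0 + i) for i in range(6)
        ),
        n_species=2, n_individuals_per_species=12, seed=3,
    )
    matrix, _ = simulate_morphometrics(spec)
    for trait in ("t0", "t3", "t5"):
        mine = consistent_variability(matrix, "sp01", trait)
        assert 0.0 <= mine <= 1.0
        assert mine == pytest.approx(rm2_naive(matrix, "sp01", trait), abs=1e-12)


def test_zero_variance_partner_excluded():
    df = frame(a=[1.0, 2, 3], b=[5.0, 5, 5], c=[1.0, 2, 3])
    # b is constant: only c counts for a
    assert consistent_variability(df, "sp", "a") == pytest.approx(1.0)
    with pytest.raises(ValueError):
        consistent_variability(frame(a=[1.0, 2, 3], b=[5.0, 5, 5]), "sp", "a")


# -- variability structure ----------------------------------------------

def test_profile_one_row_per_trait_and_scale_free():
    df = frame(a=[1.0, 2, 3, 4], b=[4.0, 3, 5, 6], c=[2.0, 2, 3, 1])
    prof = variability_structure(df, "sp")
    assert list(prof.table["trait"]) == ["a", "b", "c"]
    scaled = df.copy()
    scaled["a"] = scaled["a"] * 250.0  # unit change mm -> something else
    prof2 = variability_structure(scaled, "sp")
    assert prof2.table["cv_pct"].to_numpy() == pytest.approx(
        prof.table["cv_pct"].to_numpy()
    )
    assert prof2.table["rm2"].to_numpy() == pytest.approx(
        prof.table["rm2"].to_numpy()
    )


# -- year screen ---------------------------------------------------------

def null_matrix(seed, n_traits=6):
    spec = MorphoSimSpec(
        traits=tuple(TraitSpec(f"t{i}", "taxonomic", 5.0) for i in range(n_traits)),
        n_species=3, n_individuals_per_species=24, n_years=3, seed=seed,
    )
    return simulate_morphometrics(spec)[0]


def test_null_year_effect_mostly_pooled():
    pooled = total = 0
    for seed in range(8):
        rep = year_homogeneity_screen(null_matrix(seed), alpha=0.05)
        pooled += len(rep.pooled_traits())
        total += len(rep.table)
    assert pooled / total > 0.85


def test_planted_year_shift_is_flagged():
    spec = MorphoSimSpec(
        traits=tuple(TraitSpec(f"t{i}", "taxonomic", 5.0) for i in range(4)),
        n_species=3, n_individuals_per_species=24, n_years=2,
        year_shifts=(("t0", 5.0),), seed=2,
    )
    matrix, _ = simulate_morphometrics(spec)
    rep = year_homogeneity_screen(matrix, alpha=0.05)
    assert "t0" in rep.flagged_traits()
    assert set(rep.flagged_traits()) <= {"t0", "t1", "t2", "t3"}


def test_single_year_trivially_pooled(caplog):
    df = frame(a=[1.0, 2, 3], b=[2.0, 3, 4])
    rep = year_homogeneity_screen(df, alpha=0.05)
    assert rep.pooled_traits() == ["a", "b"]


# -- table I/O -----------------------------------------------------------

def test_trait_table_round_trip(tmp_path):
    df = frame(a=[1.5, 2.25, 3.0], b=[4.0, 5.5, 6.125])
    path = tmp_path / "traits.tsv"
    write_trait_table(df, path)
    back = read_trait_table(path)
    pd.testing.assert_frame_equal(back, df)


def test_comma_decimals_rejected(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("species\tyear\tindividual_id\ta\nsp\tY1\ti1\t3,5\nsp\tY1\ti2\t4,5\n")
    with pytest.raises(ValueError, match="comma"):
        read_trait_table(path)
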