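"""Stage 1: per-species trait statistics and the variability structure.

Following Rostova's approach, every trait of a species is placed in a
plane whose axes are its *total* variability — the coefficient of
variation CV% = 100·SD/mean — and its *consistent* (coordinated)
variability r_m², the mean of squared Pearson correlations of the trait
with every other trait across individuals of that species.  Stable,
weakly coordinated traits (low CV, low r_m²) are candidate taxonomic
indicators; the classification itself lives in :mod:`iristax.indicators`.

Before pooling years, a homogeneity screen compares year groups per
trait: one-way ANOVA when every year group passes a Lilliefors-type
Kolmogorov-Smirnov normality check at level alpha, the Kruskal-Wallis
rank test otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .tables import META_COLUMNS

log = logging.getLogger(__name__)

__all__ = [
    "TraitSummary",
    "HomogeneityReport",
    "VariabilityProfile",
    "trait_summary",
    "ks_normality",
    "oneway_anova",
    "kruskal_wallis",
    "year_homogeneity_screen",
    "consistent_variability",
    "variability_structure",
    "trait_columns",
]

MIN_COMPLETE_PAIRS = 3  # a correlation needs at least 3 complete records


def trait_columns(matrix: pd.DataFrame) -> list[str]:
    return [c for c in matrix.columns if c not in META_COLUMNS]


@dataclass(frozen=True)
class TraitSummary:
    """Mean, sample SD (n-1), SEM and CV% of one trait sample."""

    mean: float
    sd: float
    sem: float
    cv_pct: float
    n: int


def trait_summary(values) -> TraitSummary:
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise ValueError("trait summary needs at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite trait values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if mean <= 0:
        raise ValueError("CV undefined: mean must be positive")
    return TraitSummary(
        mean=mean,
        sd=sd,
        sem=sd / np.sqrt(x.size),
        cv_pct=100.0 * sd / mean,
        n=int(x.size),
    )


def ks_normality(values, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Kolmogorov-Smirnov normality check with fitted parameters.

    The null distribution accounts for estimating mean and SD from the
    sample (Lilliefors correction); the naive KS p-value would be
    anticonservative here.  Returns (D, p, passed at alpha).
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 4:
        raise ValueError("normality test needs at least 4 values")
    if x.std(ddof=1) == 0:
        raise ValueError("degenerate sample: zero variance")
    d, p = lilliefors(x, dist="norm", pvalmethod="table")
    return float(d), float(p), bool(p >= alpha)


def oneway_anova(groups) -> tuple[float, float]:
    """Classic one-way ANOVA F and its p-value."""
    cleaned = [np.asarray(g, dtype=float) for g in groups]
    if len(cleaned) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(g.size < 2 for g in cleaned):
        raise ValueError("each ANOVA group needs at least 2 values")
    if sum(g.size for g in cleaned) - len(cleaned) < 1:
        raise ValueError("no error degrees of freedom")
    allv = np.concatenate(cleaned)
    if np.ptp(allv) == 0:
        return 0.0, 1.0  # zero between- and within-variance
    f, p = stats.f_oneway(*cleaned)
    if np.isnan(f):
        return 0.0, 1.0
    return float(f), float(p)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p-value."""
    cleaned = [np.asarray(g, dtype=float) for g in groups]
    if len(cleaned) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    if any(g.size < 1 for g in cleaned):
        raise ValueError("empty group")
    if sum(g.size for g in cleaned) < 3:
        raise ValueError("needs at least 3 observations in total")
    allv = np.concatenate(cleaned)
    if np.ptp(allv) == 0:
        return 0.0, 1.0  # tie-correction denominator vanishes
    h, p = stats.kruskal(*cleaned)
    return float(h), float(p)


@dataclass
class HomogeneityReport:
    """Per-trait between-year comparison and the pooling decision."""

    alpha: float
    table: pd.DataFrame  # trait, normality_ok, test_used, statistic, p_value, pooled

    def pooled_traits(self) -> list[str]:
        return list(self.table.loc[self.table["pooled"], "trait"])

    def flagged_traits(self) -> list[str]:
        return list(self.table.loc[~self.table["pooled"], "trait"])


def year_homogeneity_screen(matrix: pd.DataFrame, alpha: float = 0.05) -> HomogeneityReport:
    """Compare year groups per trait; route ANOVA vs Kruskal-Wallis.

    Individuals are pooled across species within each year group; under
    a zero year effect, years are exchangeable, so the routed test holds
    its level regardless of the species mixture.  A trait is pooled
    when its between-year p-value is >= alpha.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    years = sorted(matrix["year"].unique())
    rows = []
    if len(years) < 2:
        log.info("single year present; all traits trivially pooled")
        for trait in trait_columns(matrix):
            rows.append(
                dict(trait=trait, normality_ok=True, test_used="none",
                     statistic=np.nan, p_value=1.0, pooled=True)
            )
        return HomogeneityReport(alpha=alpha, table=pd.DataFrame(rows))
    for trait in trait_columns(matrix):
        groups = [
            matrix.loc[matrix["year"] == y, trait].dropna().to_numpy()
            for y in years
        ]
        normal = True
        for g in groups:
            try:
                _, _, ok = ks_normality(g, alpha)
            except ValueError:
                ok = False
            normal = normal and ok
        if normal:
            statistic, p = oneway_anova(groups)
            test = "anova"
        else:
            statistic, p = kruskal_wallis(groups)
            test = "kruskal_wallis"
        rows.append(
            dict(trait=trait, normality_ok=normal, test_used=test,
                 statistic=statistic, p_value=p, pooled=bool(p >= alpha))
        )
    return HomogeneityReport(alpha=alpha, table=pd.DataFrame(rows))


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float | None:
    """Pairwise-complete Pearson r; None when undefined."""
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < MIN_COMPLETE_PAIRS:
        return None
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return None
    return float(np.corrcoef(xs, ys)[0, 1])


def consistent_variability(matrix: pd.DataFrame, species: str, trait: str) -> float:
    """r_m² of a trait within a species: mean squared correlation.

    Pearson correlations are computed across individuals of the species
    with every other trait (pairwise-complete); zero-variance partners
    are excluded.  Raises when no partner pair is computable.
    """
    sub = matrix.loc[matrix["species"] == species]
    if sub.empty:
        raise ValueError(f"species {species!r} not in matrix")
    others = [t for t in trait_columns(matrix) if t != trait]
    if not others:
        raise ValueError("need at least 2 traits for consistent variability")
    x = sub[trait].to_numpy(dtype=float)
    r2 = []
    for other in others:
        r = _pearson_r(x, sub[other].to_numpy(dtype=float))
        if r is not None:
            r2.append(r * r)
    if not r2:
        raise ValueError(
            f"no computable correlation partner for {trait!r} in {species!r}"
        )
    return float(np.mean(r2))


@dataclass
class VariabilityProfile:
    """Per-trait (CV%, r_m²) coordinates for one species."""

    species: str
    table: pd.DataFrame  # trait, n, mean, sd, sem, cv_pct, rm2


def variability_structure(matrix: pd.DataFrame, species: str) -> VariabilityProfile:
    """The variability-structure coordinates of every trait of a species."""
    sub = matrix.loc[matrix["species"] == species]
    if len(sub) < 3:
        raise ValueError(f"species {species!r} needs at least 3 individuals")
    rows = []
    for trait in trait_columns(matrix):
        summ = trait_summary(sub[trait])
        rm2 = consistent_variability(matrix, species, trait)
        rows.append(
            dict(trait=trait, n=summ.n, mean=summ.mean, sd=summ.sd,
                 sem=summ.sem, cv_pct=summ.cv_pct, rm2=rm2)
        )
    return VariabilityProfile(species=species, table=pd.DataFrame(rows))
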