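"""Stage 2: indicator classification from the variability structure.

A trait's position in the (CV%, r_m²) plane determines its indicator
role:

====================  ==========  ===========
class                 total CV    r_m²
====================  ==========  ===========
taxonomic (genetic)   low         low
biological            low         high
systemic              high        high
ecological            high        low
====================  ==========  ===========

"Low" means at or below the split (boundary ties go to the low side).
The default splits are fixed at CV = 6.0 % and r_m² = 0.08, the upper
edges of the reported range for taxonomic indicators in Iris; a
per-species median rule is available as an alternative.  Note that the
median rule can never label more than about half the traits taxonomic,
so it is unsuitable when most measured traits are expected to be
diagnostic — hence fixed splits as the default.

Cross-species selection keeps traits classified taxonomic in a majority
(default) or in all species, ordered by how deep in the low/low corner
they sit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variability import VariabilityProfile

__all__ = [
    "IndicatorThresholds",
    "IndicatorClassification",
    "classify_trait_indicators",
    "select_taxonomic_traits",
    "three_group_view",
]

CLASS_ORDER = ("taxonomic", "biological", "systemic", "ecological")


@dataclass(frozen=True)
class IndicatorThresholds:
    """Splits of the variability plane, fixed or per-species medians."""

    cv_split: float = 6.0
    rm2_split: float = 0.08
    rule: str = "fixed"  # "fixed" | "median"

    def __post_init__(self) -> None:
        if self.rule not in ("fixed", "median"):
            raise ValueError("rule must be 'fixed' or 'median'")
        if self.cv_split <= 0 or self.rm2_split <= 0:
            raise ValueError("splits must be strictly positive")


@dataclass
class IndicatorClassification:
    """Classes of every trait of one species, plus the splits used."""

    species: str
    table: pd.DataFrame  # trait, cv_pct, rm2, indicator_class
    cv_split: float
    rm2_split: float

    def classes(self) -> dict[str, str]:
        return dict(zip(self.table["trait"], self.table["indicator_class"]))


def _classify(cv: float, rm2: float, cv_split: float, rm2_split: float) -> str:
    low_cv = cv <= cv_split
    low_rm2 = rm2 <= rm2_split
    if low_cv and low_rm2:
        return "taxonomic"
    if low_cv:
        return "biological"
    if low_rm2:
        return "ecological"
    return "systemic"


def classify_trait_indicators(
    profile: VariabilityProfile,
    thresholds: IndicatorThresholds = IndicatorThresholds(),
) -> IndicatorClassification:
    """Assign one of the four indicator classes to every trait."""
    tab = profile.table
    if tab.empty:
        raise ValueError("empty variability profile")
    if thresholds.rule == "median":
        cv_split = float(np.median(tab["cv_pct"]))
        rm2_split = float(np.median(tab["rm2"]))
        if tab["cv_pct"].nunique() == 1 and tab["rm2"].nunique() == 1:
            raise ValueError(
                "median rule degenerate: all traits share one (CV, rm2) point"
            )
    else:
        cv_split = thresholds.cv_split
        rm2_split = thresholds.rm2_split
    out = tab[["trait", "cv_pct", "rm2"]].copy()
    out["indicator_class"] = [
        _classify(cv, rm2, cv_split, rm2_split)
        for cv, rm2 in zip(out["cv_pct"], out["rm2"])
    ]
    return IndicatorClassification(
        species=profile.species, table=out, cv_split=cv_split, rm2_split=rm2_split
    )


def select_taxonomic_traits(
    classifications: list[IndicatorClassification],
    rule: str = "majority",
) -> list[str]:
    """Cross-species taxonomic indicator set.

    ``majority`` keeps traits taxonomic in more than half the species,
    ``unanimous`` in all of them.  Output is ordered by the trait's
    mean (across species) of its average CV- and r_m²-rank, ascending —
    the deepest low/low-corner traits first.
    """
    if rule not in ("majority", "unanimous"):
        raise ValueError("rule must be 'majority' or 'unanimous'")
    if not classifications:
        raise ValueError("need at least one classified species")
    counts: dict[str, int] = {}
    ranks: dict[str, list[float]] = {}
    for cls in classifications:
        tab = cls.table
        cv_rank = tab["cv_pct"].rank(method="average")
        rm2_rank = tab["rm2"].rank(method="average")
        for trait, c, rc, rr in zip(
            tab["trait"], tab["indicator_class"], cv_rank, rm2_rank
        ):
            counts[trait] = counts.get(trait, 0) + (c == "taxonomic")
            ranks.setdefault(trait, []).append(0.5 * (rc + rr))
    n_species = len(classifications)
    need = n_species if rule == "unanimous" else n_species / 2.0
    selected = [
        t for t, c in counts.items()
        if (c == n_species if rule == "unanimous" else c > need)
    ]
    if not selected:
        raise ValueError(
            "no trait qualifies as a cross-species taxonomic indicator; "
            "consider relaxing the thresholds or the selection rule"
        )
    return sorted(selected, key=lambda t: (float(np.mean(ranks[t])), t))


def three_group_view(classification: IndicatorClassification) -> pd.DataFrame:
    """Reporting option merging ecological into the systemic group.

    Mirrors presentations using three groups — taxonomic (genetic),
    biological and ecological-biological — while the four-class
    assignment stays the computed record.
    """
    mapping = {
        "taxonomic": "taxonomic",
        "biological": "biological",
        "systemic": "ecological_biological",
        "ecological": "ecological_biological",
    }
    out = classification.table.copy()
    out["indicator_group"] = out["indicator_class"].map(mapping)
    return out
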