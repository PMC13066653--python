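"""Stage orchestration: simulate/read inputs, run both tracks, report.

A single master seed drives every stochastic step through fixed
offsets (morphometric draw: seed, sequence evolution: seed+1,
bootstrap resampling: seed+2), so identical configuration plus seed
reproduces byte-identical output bundles.  The manifest records the
package version, a hash of the canonical configuration and every
numeric default in force.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .concordance import concordance_report
from .indicators import (
    IndicatorThresholds,
    classify_trait_indicators,
    select_taxonomic_traits,
)
from .molphylo import (
    Alignment,
    collapse_haplotypes,
    infer_ml_tree,
    jc69_distance_matrix,
    read_alignment,
    write_alignment,
)
from .molphylo.tree import Tree
from .morphocluster import (
    cut_clusters,
    euclidean_distances,
    species_trait_table,
    suggest_k,
    ward_cluster,
)
from .simulate import default_study_spec, simulate_alignment, simulate_morphometrics
from .tables import read_trait_table, write_trait_table
from .variability import variability_structure, year_homogeneity_screen

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "write_report"]

# numeric defaults in force; all surfaced in the manifest
DEFAULTS = {
    "alpha": 0.05,
    "bootstrap": 1000,
    "cv_split_pct": 6.0,
    "rm2_split": 0.08,
    "branch_length_bounds": [1e-8, 10.0],
    "branch_opt_lnl_tol": 1e-4,
    "nni_min_gain": 1e-6,
    "distance_metric": "euclidean",
    "gaps_treated_as": "missing",
}

_KNOWN_KEYS = {
    "trait_table", "alignment", "simulate", "alpha", "indicator_rule",
    "cv_split", "rm2_split", "selection_rule", "standardize", "k_morpho",
    "bootstrap", "seed", "outdir", "on_year_flag",
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything one run needs; unknown configuration keys are errors."""

    outdir: str
    seed: int
    trait_table: str | None = None
    alignment: str | None = None
    simulate: bool = False
    alpha: float = 0.05
    indicator_rule: str = "fixed"
    cv_split: float = 6.0
    rm2_split: float = 0.08
    selection_rule: str = "majority"
    standardize: bool = True
    k_morpho: int | str = "auto"
    bootstrap: int = 1000
    on_year_flag: str = "drop"  # "drop" | "fail"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(
                f"alpha must lie strictly between 0 and 1, got {self.alpha}: "
                "at the boundary every pooling decision degenerates"
            )
        if self.on_year_flag not in ("drop", "fail"):
            raise ValueError("on_year_flag must be 'drop' or 'fail'")
        if self.bootstrap < 0:
            raise ValueError("bootstrap must be >= 0")
        if isinstance(self.k_morpho, str) and self.k_morpho != "auto":
            raise ValueError("k_morpho must be an integer or 'auto'")
        if not self.simulate and self.trait_table is None and self.alignment is None:
            raise ValueError("no input: set simulate or give trait_table/alignment")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        raw.update(overrides)
        return cls(**raw)

    def canonical(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Stage outputs of one run; all tables also land in the outdir."""

    config: PipelineConfig
    homogeneity: object = None
    profiles: list = field(default_factory=list)
    classifications: list = field(default_factory=list)
    selected_traits: list[str] = field(default_factory=list)
    dendrogram: object = None
    partition: dict[str, int] = field(default_factory=dict)
    k_used: int | None = None
    ml_tree: Tree | None = None
    haplotypes: dict[str, object] = field(default_factory=dict)
    concordance: object = None
    notes: list[str] = field(default_factory=list)


def species_representative_tree(tree: Tree, aln: Alignment) -> Tree:
    """Molecular tree reduced to one accession per species, renamed.

    The first accession of each species (alignment order) represents
    it, so morphological partitions keyed by species name can be
    compared with the accession-level tree.
    """
    reps: dict[str, str] = {}
    for acc, sp in zip(aln.ids, aln.species):
        reps.setdefault(sp, acc)
    pruned = tree.prune_to(set(reps.values()))
    back = {acc: sp for sp, acc in reps.items()}
    for node in pruned.nodes():
        if pruned.labels[node] is not None:
            pruned.labels[node] = back[pruned.labels[node]]
    return pruned


def _stage(name: str, outdir: Path):
    class _Ctx:
        def __enter__(self):
            log.info("stage %s", name)

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                (outdir / f"FAILED_{name}.txt").write_text(
                    f"stage {name} failed: {exc}\n"
                )
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(config=config)
    matrix = None
    aln = None

    with _stage("inputs", outdir):
        if config.simulate:
            morpho_spec, seq_spec = default_study_spec(seed=config.seed)
            inputs = outdir / "inputs"
            inputs.mkdir(exist_ok=True)
            matrix, morpho_truth = simulate_morphometrics(morpho_spec)
            write_trait_table(matrix, inputs / "trait_matrix.tsv")
            aln, seq_truth = simulate_alignment(seq_spec)
            write_alignment(aln, inputs / "alignment.fasta")
            (inputs / "species_tree.nwk").write_text(seq_spec.species_tree + "\n")
            pd.DataFrame(
                sorted(morpho_truth.trait_classes.items()),
                columns=["trait", "planted_class"],
            ).to_csv(inputs / "truth_traits.tsv", sep="\t", index=False)
            pd.DataFrame(
                sorted(morpho_truth.species_clusters.items()),
                columns=["species", "cluster"],
            ).to_csv(inputs / "truth_clusters.tsv", sep="\t", index=False)
            pd.DataFrame(
                sorted(seq_truth.haplotypes.items()),
                columns=["accession", "haplotype"],
            ).to_csv(inputs / "truth_haplotypes.tsv", sep="\t", index=False)
        else:
            if config.trait_table:
                matrix = read_trait_table(config.trait_table)
            if config.alignment:
                aln = read_alignment(config.alignment)

    if matrix is not None:
        with _stage("year_homogeneity", outdir):
            report = year_homogeneity_screen(matrix, alpha=config.alpha)
            result.homogeneity = report
            report.table.to_csv(outdir / "homogeneity.tsv", sep="\t", index=False)
            flagged = report.flagged_traits()
            if flagged and config.on_year_flag == "fail":
                raise ValueError(f"between-year differences for traits {flagged}")
            if flagged:
                result.notes.append(
                    f"traits dropped by year screen: {', '.join(flagged)}"
                )
                matrix = matrix.drop(columns=flagged)

        with _stage("variability_structure", outdir):
            species = sorted(matrix["species"].unique())
            result.profiles = [variability_structure(matrix, sp) for sp in species]
            combined = pd.concat(
                [p.table.assign(species=p.species) for p in result.profiles]
            )
            cols = ["species"] + [c for c in combined.columns if c != "species"]
            combined[cols].to_csv(
                outdir / "variability_structure.tsv", sep="\t", index=False
            )

        with _stage("indicator_classification", outdir):
            thresholds = IndicatorThresholds(
                cv_split=config.cv_split,
                rm2_split=config.rm2_split,
                rule=config.indicator_rule,
            )
            result.classifications = [
                classify_trait_indicators(p, thresholds) for p in result.profiles
            ]
            combined = pd.concat(
                [c.table.assign(species=c.species) for c in result.classifications]
            )
            cols = ["species"] + [c for c in combined.columns if c != "species"]
            combined[cols].to_csv(
                outdir / "indicator_classification.tsv", sep="\t", index=False
            )
            result.selected_traits = select_taxonomic_traits(
                result.classifications, rule=config.selection_rule
            )
            (outdir / "selected_traits.txt").write_text(
                "\n".join(result.selected_traits) + "\n"
            )

        with _stage("ward_clustering", outdir):
            table = species_trait_table(
                matrix, result.selected_traits, standardize=config.standardize
            )
            table.table.to_csv(outdir / "species_means.tsv", sep="\t")
            dend = ward_cluster(euclidean_distances(table))
            result.dendrogram = dend
            k = suggest_k(dend) if config.k_morpho == "auto" else int(config.k_morpho)
            result.k_used = k
            result.partition = cut_clusters(dend, k)
            (outdir / "morpho_dendrogram.nwk").write_text(dend.to_newick() + "\n")
            pd.DataFrame(
                sorted(result.partition.items()), columns=["species", "cluster_id"]
            ).to_csv(outdir / "morpho_partition.tsv", sep="\t", index=False)

    if aln is not None:
        with _stage("molecular_inference", outdir):
            dm = jc69_distance_matrix(aln)
            pd.DataFrame(dm.matrix, index=dm.labels, columns=dm.labels).to_csv(
                outdir / "jc_distances.tsv", sep="\t"
            )
            result.ml_tree = infer_ml_tree(
                aln, bootstrap=config.bootstrap, seed=config.seed + 2
            )
            (outdir / "ml_tree.nwk").write_text(
                result.ml_tree.to_newick(include_supports=True) + "\n"
            )
            rows = []
            for sp in dict.fromkeys(aln.species):
                if len(aln.records_for_species(sp)) < 2:
                    continue
                table = collapse_haplotypes(aln, scope=sp)
                result.haplotypes[sp] = table
                for hap, members in table.haplotypes.items():
                    rows.append(
                        dict(species=sp, haplotype=hap,
                             n_accessions=len(members),
                             accessions=",".join(members))
                    )
            pd.DataFrame(
                rows, columns=["species", "haplotype", "n_accessions", "accessions"]
            ).to_csv(outdir / "haplotypes.tsv", sep="\t", index=False)

    if matrix is not None and aln is not None:
        with _stage("concordance", outdir):
            sp_tree = species_representative_tree(result.ml_tree, aln)
            morpho_tree = result.dendrogram.to_tree()
            result.concordance = concordance_report(
                result.partition, morpho_tree, sp_tree
            )
            rep = result.concordance
            rows = [
                dict(cluster_id=cid,
                     members=",".join(sorted(
                         sp for sp, c in result.partition.items() if c == cid
                     )),
                     evaluable=cid in rep.monophyly,
                     monophyletic=rep.monophyly.get(cid, ""))
                for cid in sorted(set(result.partition.values()))
            ]
            tab = pd.DataFrame(rows)
            tab["score"] = rep.score
            tab["rf"] = rep.rf
            tab["normalized_rf"] = rep.normalized_rf
            tab.to_csv(outdir / "concordance.tsv", sep="\t", index=False)
    elif matrix is not None:
        result.notes.append("no alignment given: molecular track and concordance skipped")
        log.info("concordance skipped: no alignment")

    with _stage("report", outdir):
        manifest = {
            "software": "iristax",
            "version": __version__,
            "seed": config.seed,
            "config": json.loads(config.canonical()),
            "config_hash": config.config_hash(),
            "defaults": DEFAULTS,
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, sort_keys=True, indent=2) + "\n"
        )
        (outdir / "report.txt").write_text(write_report(result))
    return result


def _fmt_block(title: str, body: str) -> str:
    return f"## {title}\n{body.rstrip()}\n\n"


def write_report(result: PipelineResult) -> str:
    """Plain-text summary with all seven stage sections."""
    cfg = result.config
    out = [f"# iristax run report (seed={cfg.seed}, config={cfg.config_hash()})\n\n"]
    out.append(_fmt_block(
        "1. Configuration",
        "\n".join(f"{k} = {v}" for k, v in sorted(
            dataclasses.asdict(cfg).items()
        )) + "\n" + "\n".join(f"default {k} = {v}" for k, v in DEFAULTS.items()),
    ))
    if result.homogeneity is not None:
        out.append(_fmt_block(
            "2. Year homogeneity screen",
            result.homogeneity.table.to_string(index=False),
        ))
    else:
        out.append(_fmt_block("2. Year homogeneity screen", "not run"))
    if result.classifications:
        counts = {}
        for c in result.classifications:
            for cls in c.table["indicator_class"]:
                counts[cls] = counts.get(cls, 0) + 1
        body = "\n".join(
            f"{cls}: {n} species x trait assignments"
            for cls, n in sorted(counts.items())
        )
        out.append(_fmt_block("3. Indicator classes", body))
    else:
        out.append(_fmt_block("3. Indicator classes", "not run"))
    out.append(_fmt_block(
        "4. Selected taxonomic indicators",
        "\n".join(result.selected_traits) if result.selected_traits else "not run",
    ))
    if result.dendrogram is not None:
        body = (
            f"k = {result.k_used}\n"
            + "\n".join(
                f"cluster {cid}: "
                + ", ".join(sorted(s for s, c in result.partition.items() if c == cid))
                for cid in sorted(set(result.partition.values()))
            )
            + "\nnewick: " + result.dendrogram.to_newick()
        )
        out.append(_fmt_block("5. Morphological clustering (Ward)", body))
    else:
        out.append(_fmt_block("5. Morphological clustering (Ward)", "not run"))
    if result.ml_tree is not None:
        hap_lines = []
        for sp, table in result.haplotypes.items():
            diffs = ", ".join(
                f"{a}-{b}: {d}" for (a, b), d in sorted(table.differences.items())
            )
            hap_lines.append(
                f"{sp}: {table.n_haplotypes} haplotype(s)"
                + (f" (pairwise diffs {diffs})" if diffs else "")
            )
        body = (
            "ML tree (JC69, NNI search; supports = bootstrap %):\n"
            + result.ml_tree.to_newick(include_supports=True)
            + ("\n" + "\n".join(hap_lines) if hap_lines else "")
        )
        out.append(_fmt_block("6. Molecular phylogenetics", body))
    else:
        out.append(_fmt_block("6. Molecular phylogenetics", "not run"))
    if result.concordance is not None:
        rep = result.concordance
        body = (
            f"score = {rep.score:.3f} "
            f"({sum(rep.monophyly.values())}/{len(rep.monophyly)} evaluable clusters monophyletic)\n"
            f"singleton clusters excluded: {rep.singletons or 'none'}\n"
            f"RF = {rep.rf}, normalized RF = "
            + (f"{rep.normalized_rf:.3f}" if rep.normalized_rf is not None else "n/a")
            + "\n" + "\n".join(rep.notes)
        )
        out.append(_fmt_block("7. Morphological-molecular concordance", body))
    else:
        out.append(_fmt_block("7. Morphological-molecular concordance", "not run"))
    if result.notes:
        out.append(_fmt_block("Notes", "\n".join(result.notes)))
    return "".join(out)
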