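# Methods

This note documents the models, conventions and design choices behind
`iristax`, in the order the pipeline runs them. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Synthetic study design

The generator emulates a two-track taxonomic study of eleven *Iris*
species: 25 individuals per species measured for 14 morphometric traits
over three seasons, plus a chloroplast-spacer alignment with a known
species tree.

**Morphometrics.** Within a species, individuals are drawn from a
multivariate normal. Per trait, the mean and SD are chosen so the
realized coefficient of variation matches a target CV% (sampled values
below a small positive epsilon, 10⁻³ of the baseline mean, are clipped
with a logged warning — measurements are positive). Correlation
structure is planted through blocks: two traits in one block correlate
at √(rᵢ·rⱼ), the factor-model value, which keeps the matrix positive
semi-definite by construction (blocks are still validated and a
non-PSD block is a hard error). Ten traits are planted *taxonomic*
(CV targets 2–4.5 %, inside the 0.8–6.0 % range reported for such
indicators in *Iris*; no correlation block), one *biological*
(low CV, in a correlated vegetative block at r = 0.8), two *systemic*
(high CV, same block) and one *ecological* (high CV, uncorrelated).
Taxonomic traits carry species-specific mean shifts encoding a planted
5-group structure (the molecular clades): each group g gets an offset
`d_sep · SD · z(g,trait)` with z ~ N(0,1), each species within a group
a smaller `d_within · SD · z(species,trait)`. Defaults `d_sep = 3.0`
and `d_within = 0.5` are free parameters of the emulation, chosen as a
clear but not degenerate between-group separation (three within-species
SDs is the conventional "strong effect" scale in morphometrics); no
published effect sizes exist to calibrate against. The year effect is
zero by default — mirroring the screened study design — and an optional
per-trait year shift (in SD units per year step) exists to exercise the
screen's power.

**Sequences.** Sites evolve independently under JC69 along the species
tree: with e = exp(−4t/3), a site keeps the parent state with
probability e + (1−e)/4, otherwise takes one of the four bases
uniformly; the root sequence is uniform over {A,C,G,T}. The packaged
tree places the 11 species in five clades with within-group tip
branches of 0.003–0.005 and group stems of 0.018–0.025
substitutions/site — realistic magnitudes for noncoding cpDNA spacers
at the congeneric scale, chosen once (no published branch lengths to
match). Defaults: 1000 sites, two accessions per species, one private
substitution per extra accession placed at uniformly chosen distinct
sites (the emulated study reports only counts of differing
nucleotides). Ground truth (trait classes, species groups, accession →
haplotype) is recorded at generation time; haplotype truth is read off
the generated sequences themselves, so coincidental identity of two
variants is recorded as one haplotype.

What the generator does **not** emulate: measurement error structure,
missing data patterns, trait non-normality (skew, counts), indels and
alignment uncertainty, rate heterogeneity across sites, and
chloroplast introgression. Passing recovery tests therefore shows the
pipeline is correct under its own model assumptions, not that real
*Iris* data are this clean.

## Variability structure and the year screen

- Summary statistics are the sample mean, SD (n−1), SEM = SD/√n and
  CV% = 100·SD/mean (defined only for positive means).
- r²ₘ of a trait within a species is the mean of squared Pearson
  correlations with every other trait, pairwise-complete, computed
  across the individuals of that species only; partners with zero
  variance are excluded, and a trait with no computable partner is an
  error rather than a silent zero. A Spearman variant was considered
  and rejected: the method as usually stated squares the product-moment
  correlation coefficient.
- Both CV and r²ₘ are invariant under positive rescaling of units
  (CV is not shift-invariant; only multiplicative changes are safe).
- The year screen tests each trait across year groups with individuals
  pooled over species. Normality within each year group is checked with
  the Kolmogorov–Smirnov statistic against a normal with estimated
  parameters using the Lilliefors null (the naive KS p-value is
  anticonservative when mean and SD come from the sample); all groups
  normal → one-way ANOVA, otherwise Kruskal–Wallis with tie
  correction. Degenerate inputs are defined rather than crashing:
  identical groups give F = 0 (or H = 0 when the tie-correction
  denominator vanishes). Pooling across species makes year groups
  exchangeable under a zero year effect, so the routed test holds its
  level even though the pooled distribution is a species mixture.
  α defaults to 0.05. Flagged traits are dropped (default) or abort the
  run, by configuration; α is restricted to the open interval (0, 1)
  because at either boundary the pooling decision degenerates.

## Indicator classification and selection

The four classes partition the (CV, r²ₘ) plane: taxonomic = low/low,
biological = low CV/high r²ₘ, systemic = high/high, ecological = high
CV/low r²ₘ. Boundary ties go to the low side (deterministic and
documented). Default splits are **fixed** at CV = 6.0 % and r²ₘ = 0.08,
the upper edges of the range reported for taxonomic indicators in this
genus. A per-species **median** rule is provided, but it is not the
default: a median split can never place more than about half the traits
on the low/low side, which is structurally wrong whenever most measured
traits are expected to be diagnostic (10 of 14 here). A reporting
option merges ecological and systemic into one "ecological-biological"
group for the common three-group presentation.

Cross-species selection keeps traits classified taxonomic in a strict
majority of species (default) or in all species; whether "common to
the analyzed taxa" means predominance or unanimity is not decidable
from the motivating description, so both rules exist. The output is
ordered by each trait's mean (over species) average of its CV-rank and
r²ₘ-rank — ranks, not raw sums, because percent and squared-correlation
scales are not commensurable.

## Ward clustering

Species are represented by per-trait means of the selected indicators;
columns are z-scored by default (traits mix millimetres and
centimetres; Ward is scale-sensitive) and the metric is Euclidean —
Ward's natural metric; the motivating description states neither, so
both are explicit, toggleable decisions. Agglomeration minimizes the
increase in total within-cluster sum of squares (ESS); the reported
height is √(2·ΔESS), the metric-scale "Ward.D2" convention under which
two singletons at Euclidean distance d merge at height d. This is
exactly scipy's `linkage(..., method="ward")`, which the module wraps;
its merge sequence is verified in the tests against a brute-force
greedy minimum-variance oracle. Ward is reducible, so heights are
nondecreasing (asserted). k is a user parameter; the default cuts at
the largest relative gap between successive merge heights, and the
choice is logged.

## Molecular phylogenetics

- **Distances.** p = mismatches over sites where both sequences are
  determined (gaps and N excluded pairwise); d = −(3/4)·ln(1 − 4p/3).
  p ≥ 3/4 is a saturation error, never a clamped value.
- **Likelihood.** Felsenstein pruning under JC69 with stationary
  frequencies 1/4; gaps/N contribute all-ones partials; site patterns
  are compressed with multiplicities. The JC structure is used
  analytically: P(t)·v = e·v + ((1−e)/4)·Σv with e = exp(−4t/3), and
  for any edge the per-pattern likelihood is *linear* in e, so the
  per-branch optimization is a safeguarded Newton iteration on a
  concave one-dimensional objective — exact to the bounds, with no
  generic line search. Branch lengths live in [10⁻⁸, 10]
  substitutions/site; sweeps stop when a full pass gains < 10⁻⁴ lnL.
  The transition-probability interface is isolated so another
  reversible model could slot in, but only JC69 is implemented (the
  model the motivating analysis selected).
- **Search.** Neighbor joining (standard Q criterion; negative branch
  estimates clamped to zero with the deficit logged; exact on additive
  matrices) gives the start tree. NNI hill climbing evaluates both
  rearrangements at every internal edge, scoring each candidate by
  re-optimizing the five branches around the edge against the fixed
  flanking subtree partials (exact for the local problem), applies the
  single best move if it improves lnL by > 10⁻⁶, re-optimizes all
  branches, and repeats to convergence. Move enumeration order is
  fixed, so the search is deterministic.
- **Bootstrap.** Sites resampled with replacement; the full
  NJ → branch-opt → NNI pipeline runs per replicate; supports are
  mapped onto the internal edges of the full-data best tree (not a
  consensus), as supports are usually displayed. The conventional
  B = 1000 is the pipeline default; tests and the acceptance script
  use B = 100, which already separates supported from unsupported
  edges at the simulated divergences.
- **Haplotypes.** Sequences identical over mutually determined sites
  share a haplotype (wildcard mode; strict literal identity is a
  switch). Grouping is greedy first-seen and deterministic; an
  ambiguous sequence (compatible with several haplotypes) joins the
  first and the ambiguity is logged. Difference counts compare
  representatives over determined sites.

## Concordance

Monophyly on an unrooted tree is defined through bipartitions — a
cluster is a clade iff its taxon set or the complement is a split —
avoiding any arbitrary rooting. Clusters with fewer than two taxa
shared with the tree are vacuous and excluded from the score's
denominator (they are listed separately). The score is this package's
operationalization of a qualitative "clusters coincide" claim and is
labeled as such in its outputs; Robinson–Foulds distance (symmetric
split difference, normalized by 2(n−3)) between the morphological
dendrogram and the molecular tree on shared taxa is reported alongside
as the stricter, full-topology comparison. For the species-level
comparison the accession tree is pruned to one representative
accession per species (the first in alignment order) — intra-species
sampling is an explicit non-target of the cluster comparison.

## Pipeline

One master seed derives all per-stage streams by fixed offsets;
identical configuration plus seed yields byte-identical output bundles
(no timestamps in any output). Unknown configuration keys are errors.
Stage failures abort with the stage name and leave a `FAILED_<stage>`
marker next to any partial outputs. The manifest repeats every numeric
default listed above verbatim.

## Problem sizes in tests and the acceptance script

Recovery properties are checked at the packaged study size (11 species
× 25 individuals × 14 traits; 22 accessions × 1000 sites) over 25–50
seeded replicates, with B = 100 bootstrap replicates where supports are
involved; oracle agreement (pruning vs state enumeration, NJ on
additive matrices, NNI vs exhaustive quartet ML, Ward vs greedy ESS,
statistics vs textbook formulas) is checked on 100–200 random small
instances. These sizes were chosen so the full suite completes in
minutes on a single core while keeping every estimate's Monte-Carlo
error far below the asserted margins.

## Known limitations

- JC69 only; no rate heterogeneity, no model selection.
- NNI hill climbing can in principle stop in a local optimum on large
  trees; at the study's size the quartet oracle and split-recovery
  tests bound this risk empirically, not analytically.
- Gaps are missing data, never characters; indel-coded signal is
  ignored.
- The median threshold rule is structurally unable to declare most
  traits taxonomic (see above); use fixed splits when that is the
  expectation.
- The concordance score ignores branch lengths and supports; a cluster
  that is monophyletic with 51 % bootstrap counts as concordant.
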