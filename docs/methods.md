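# Methods

## Count model and differential expression

Counts are modelled negative-binomially with the mean–dispersion
parameterization Var = μ + φμ²; φ = 0 is the exact Poisson limit. Library
sizes enter through CPM normalization, optionally after TMM composition
factors (trimmed, precision-weighted mean of log-ratios against a reference
sample, factors rescaled to geometric mean 1; trims 30% on log-ratios, 5% on
abundance). Genes are tested only when CPM ≥ 1 in *every* replicate of both
arms (`Thresholds.cpm_min`).

The two-group test is the conditional NB exact test: replicate counts are
rescaled to a common effective library size (geometric mean of effective
sizes) and summed per arm; conditional on the total t, the arm-1 sum follows
a beta-binomial-type law with shape parameters n₁/φ and n₂/φ (binomial in
the Poisson limit). The two-sided p-value sums the probability of every
split whose point probability does not exceed the observed one; ties are
resolved with a 1e-10 relative tolerance. A `mid_p` variant (half weight on
equally extreme splits) exists because the reported p-value of a discrete
test is intentionally conservative — calibration diagnostics (e.g. the KS
uniformity check in the tests) should use mid-p, decision rules the
conservative default.

log₂FC = log₂((CPM̄_treat + c)/(CPM̄_ctrl + c)) with prior count c = 0.5 CPM,
so fold changes are always finite. DEG calls use |log₂FC| ≥ 1 (inclusive)
and BH FDR < 0.05 (strict), per the study's thresholds.

### Dispersion

Two estimators are provided. `estimate_dispersion` is the documented
method-of-moments estimator: per gene and arm φ̂_g = max(0, (s² − m)/m²) on
library-normalized counts, pooled by residual df, with a trimmed-mean common
value and fixed-weight shrinkage (w = 0.7 on the common value).
`common_dispersion_cml` maximizes the conditional (negative-multinomial)
log-likelihood of the replicate counts given their arm sums — the classical
companion of the conditional exact test. `run_de` uses the CML value as the
common dispersion because the moment estimator's trimmed mean is biased
slightly downward at 3 residual df per arm, and with ~2,000 genes per
experiment even a few-percent variance underestimate multiplies the far-tail
false-positive rate several-fold. Per-gene dispersions are the shrunken
moment estimates **floored at the common value**: with so few degrees of
freedom, below-common per-gene estimates are noise and only generate false
positives, while above-common estimates capture genuine extra variance
(e.g. genes riding a latent factor).

## Co-expression networks

Input is log₂(RPKM + 1) (log₂(CPM + 1) when gene lengths are unavailable,
flagged with a warning) of genes with ≥ 10 raw reads in ≥ 80% of samples.
When samples pool several experiments, each gene is centered within each
experiment first (`center_within_groups`): this is the standard batch
adjustment, and it separates the two planted structures — mean differences
between experiments (differential expression) and within-experiment
covariation (co-expression) — so the network reflects only the latter.

The network is signed, a_ij = ((1 + cor)/2)^β, with Pearson correlation and
β = 12 by default (the conventional signed-network power; the soft-threshold
chooser picks the smallest power whose connectivity distribution fits a
negative-slope power law at R² ≥ 0.8, falling back to 12). Topological
overlap and its dissimilarity follow the standard definition with unit
diagonal.

Modules come from an average-linkage tree cut. The driver default cut height
is 0.98 rather than the detector's 0.995 signature default: with a static
cut, the background topological overlap that any module induces on
non-member genes sits just under 0.995 at typical sample counts, and
average-linkage chaining through those weakly attached genes can glue
distinct modules together; 0.98 leaves margin on both sides, and any
over-splitting it causes is repaired by the eigengene merge step (modules
whose eigengene dissimilarity is below 0.25 are merged iteratively).
Clusters under 30 genes are unassigned. After merging, unassigned genes
correlating ≥ 0.5 with some module eigengene are assigned to their best
module (the usual kME membership rescue). Detection is fully deterministic;
labels M1, M2, … are ordered by size, ties by lowest gene index.

The module eigengene is the first principal component of the standardized
member submatrix, unit norm, oriented to correlate positively with the
module mean.

### Module preservation

`module_preservation` computes, per module: density (mean within-module
adjacency in the test network), the correlation of intramodular
connectivities between reference and test, and the correlation of
gene–eigengene correlations (kME) between reference and test. A null of
`n_perm` random equal-size gene sets yields Z = (obs − mean)/sd per
statistic; Zconnectivity is the median of the two connectivity Zs and
Zsummary = (Zdensity + Zconnectivity)/2. This is a deliberately reduced
composite compared to the full seven-statistic WGCNA summary — the package
relies only on its bound behaviour (strongly planted modules score ≫ 10,
random sets ≈ 0), which the tests check directly. A zero permutation sd is
reported as an infinite Z with a flag rather than an error.

## Enrichment

ORA is a one-sided hypergeometric tail with BH correction across terms
(module enrichment at FDR < 0.01). Pathway dysregulation ranks each
experiment's genes by log₂FC (ties by p, then gene id), scores each pathway
with the unweighted KS running sum (+1/|hits| at members, −1/(N−|hits|)
elsewhere; ES = extremum), obtains a two-sided permutation p with a +1
pseudo-count, and aggregates per pathway: ES_agg is the signed fraction of
experiments sharing the majority ES sign — with the *total* experiment count
in the denominator, so non-evaluable experiments dilute the score — and the
combined p is Fisher's method, BH-corrected across pathways (cut 0.01).
Exact ties between directions are broken toward the direction with the
smaller Fisher-combined evidence.

## Candidate cascade

Concordance: occurrence = number of death experiments calling the gene;
concordant ⇔ all calls share one direction (single-experiment DEGs are
trivially concordant, matching the stratified report where the
occurrence-1 DEG and concordant counts coincide). Module/annotation filter:
gene in a death-enriched module ∧ no apoptosis/autophagy keyword in any of
its term names (case-insensitive substrings "apopto"/"autophag") ∧ not in
the cancer census ∧ occurrence ≥ 1. Stress filter: exclusive (never a
stress DEG), opposite (every stress call inverted), else dropped. Ortholog
concordance: the single best ortholog must be a yeast DEG of the same sign
in ≥ 1 condition and (strict default) of the opposite sign in none; the
loose variant requiring only one same-sign call is exposed by flag. The
cascade asserts subset monotonicity (conserved ⊆ stress-specific ⊆
candidates ⊆ module-selected ⊆ DEG universe) on every run.

Disease prediction is direct-neighbor voting: per gene/disease pair, the
hypergeometric tail of disease-annotated direct neighbors (edges above a
weight threshold) against the network-wide annotation rate, BH across
pairs; significant unannotated pairs are "predicted", annotated genes are
"known". This deliberately replaces Bayesian network propagation with a
defined, exactly testable statistic.

## Synthetic data

The generator emulates the structure of a 9 cell-death + 27 stress
experiment compendium with treatment/control arms (default 4 replicates per
arm, 2,000–5,000 genes at desk scale). Per-gene baseline log₂ CPM is drawn
N(5, 1.5²) (one fixed stream shared by all experiments); log₂ mean =
baseline + module latent factor + planted log₂FC (treatment arm only);
counts are gamma-Poisson draws against log-normal library sizes. Every
generator is deterministic given the configuration seed, with separate
streams for baselines, loadings, factors and counts (so a zero-loading
module leaves counts byte-identical).

Latent-factor modules add loading × factor on the log scale. Two
normalizations keep co-expression orthogonal to differential expression:
factors are centered within the active arm of each experiment, and each
gene's factor contribution is made mean-neutral in linear space (2^x is
convex, so the raw contribution would otherwise inflate the active-arm mean
and bias fold changes of down-regulated module genes toward zero). Modules
are disjoint by construction; treatment-only modules add nothing to
controls, death-scoped modules nothing to stress experiments.

The annotation catalog contains apoptosis-/autophagy-named terms whose
membership over-samples the planted death modules at a configurable odds
ratio (odds ratio 1 = null), plus neutral background terms; planted
conserved genes are excluded from death-keyword terms by default because
the cascade, by design, nominates genes *not* already death-annotated. The
decoy cancer census is always disjoint from the conserved set. The ortholog
generator maps every conserved gene to a yeast gene with same-sign DEG
calls in ≥ 1 of 3 time points, plus a configurable fraction of other genes
with absent or opposite-sign calls. The network generator plants
disease-annotated neighborhoods (default 8 annotated of ≥ 10 neighbors over
a 5% background rate) on the designated disease genes.

`planted_recovery_config` defines the clean end-to-end recovery scenario:
two 100-gene treatment-only death modules — one up-regulated
(apoptosis-enriched), one down-regulated (autophagy-enriched) — with half
of the 32 conserved genes in each, planted at |log₂FC| = 2 in five of nine
death experiments (remaining module genes in two), φ = 0.1, 4 replicates,
factor sd 0.8 and loadings in (0.85, 1.0) so that within-module correlation
is ≈ 0.65–0.75, and module baselines floored at log₂ CPM 6.5 so
down-regulated members survive the co-expression input filter. Stress
experiments are generated under the global null in this scenario: its
purpose is to measure cascade recovery without confounding, and at 4
replicates even a per-gene-experiment false-call rate of ~10⁻⁴ across
32 genes × 27 stress experiments would contaminate exact-recovery estimates
with events unrelated to cascade correctness. The stress filter's opposite
and dropped branches are exercised by dedicated constructed tests instead.

### What the generator does not emulate

Gene-length and GC biases, sample-level batch effects within an experiment,
correlated library composition shifts, multi-factor designs, unbalanced
arms, and annotation incompleteness. Passing tests therefore demonstrate
correctness of the statistical machinery and the cascade logic under the
stated model, not robustness to the full messiness of public RNA-seq
compendia.

## Numerical choices and degenerate inputs

Exact-test tie tolerance 1e-10 relative; split tables evaluated in chunks of
≤ 4e6 cells so memory stays flat; totals of zero give p = 1. BH is the
standard step-up (via statsmodels), rejecting NaN inputs. Zero-variance
genes are rejected by the network stage (they must be filtered upstream);
empty modules, empty backgrounds, terms without partial overlap, and
missing genes in the network are explicit errors or flagged skips as
documented per function. Readers validate rather than coerce: ragged rows,
duplicate gene ids, non-integer counts, unknown conditions and unknown
config keys are errors; missing best-ortholog flags default to best with a
warning; self-loop network edges are dropped with a warning.

## Problem sizes used by the test suite

Unit tests run at 100–600 genes; the null-calibration check uses one
5,000-gene experiment; the preservation scenario uses two 2,000-gene,
40-sample datasets with 200 permutations; the end-to-end recovery check
runs the full 9 + 27 experiment study at 2,000 genes for 20 replicate
seeds. These sizes keep the whole suite at a few minutes on one CPU while
preserving the structure of the full design.

## Known limitations

- The exact test assumes a common dispersion per gene across arms and
  equalized libraries after pseudo-count rescaling; strongly unequal
  library sizes make the rescaling-and-rounding approximation coarser.
- The static tree cut plus merge is simpler than dynamic hybrid cutting;
  very close module pairs or nested modules may merge or over-split, and
  background attachment depends on network density (hence the kME rescue).
- The Zsummary composite is a 3-statistic reduction of the full WGCNA
  permutation summary; absolute values are not comparable to WGCNA's,
  only the preserved/not-preserved contrast is.
- The pathway ES aggregation reproduces the experiment-fraction pattern of
  printed enrichment scores; it is not a reimplementation of any specific
  package's internals.
- Disease prediction uses direct neighbors only; no propagation.
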