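# Methods

## Glycan representation and parsing

Free milk oligosaccharides are modeled as rooted trees of monosaccharides
(vocabulary Glc, Gal, GlcNAc, GalNAc, Fuc, Neu5Ac plus the generic classes
Hex and HexNAc used in patterns). The root is the reducing-end residue —
the Glc of the lactose core when present. Edges carry a linkage (anomeric
configuration α/β/?, child carbon, parent carbon); residues may carry
sulfate modifications as (carbon, `S`) pairs. IUPAC-condensed input is
read non-reducing → reducing, branches in parentheses binding to the
residue on their right; `Gal6S` and `Gal(6S)` sulfate spellings, Greek and
ASCII anomeric letters, and `?` wildcards are accepted.

Canonical serialization fixes branch order: at every residue the child
subtree with more residues stays on the main chain, ties broken by the
smaller parent carbon outside the parentheses (this reproduces both
printed conventions `Galβ1-4GlcNAcβ1-6(Galβ1-3)Gal…` and
`Fucα1-2(Neu5Acα2-6)Gal…`). Structure equality is tree isomorphism,
implemented as equality of canonical strings; node identifiers are a
serialization artifact. Composition-only records (e.g.
`Neu5Ac6Hex12HexNAc10`, 28 residues) are supported as structure-free
entries usable in abundance tables but rejected by the motif matcher.

## Motif matching and quantification

A motif is a pattern tree over the extended vocabulary; an occurrence is
an injective, child-to-parent-edge-preserving embedding into a structure.
Generic Hex matches {Glc, Gal, Hex}; unknown linkage components in the
*pattern* are wildcards, while unknown components in the structure match
nothing but a wildcard. In strict mode a pattern residue without
modifications only matches an unmodified residue; `ignore_modifications`
drops the check. Terminal constraints: `terminal` requires every pattern
leaf to map to a non-reducing terminal residue, `internal` requires at
least one pattern leaf on a non-terminal, `anywhere` imposes nothing.
Patterns may carry forbidden-child clauses (the i antigen requires no
β1-6 branch on its internal galactose; the Galili antigen excludes the
fucosylated B-antigen form) and variant lists (the type-2 H antigen
accepts HexNAc or Glc at the reducing position). All overlapping
occurrences count; a `presence_only` flag caps counts at 1. The matcher
is validated against a brute-force enumerator of all injective
assignments on fuzzed cases (structures ≤ 8 residues, patterns ≤ 4).

Motif quantities per sample are occurrence counts weighted by relative
abundances; the optional `size_branch` feature set appends abundance
totals in size bins (≤5, 6–12, ≥13 residues) and branch-count bins.

## Compositional preprocessing

Relative abundances carry only ratio information, so all downstream
statistics run on centered log-ratio (CLR) data. The pipeline is:
per-feature two-sided Winsorization (default fraction 0.05 per tail,
preserving within-feature order), imputation of zeros/missing values,
re-closure, then CLR. Two imputation modes: a deterministic half-minimum
per feature (the default wherever reproducibility matters) and a seeded
iterative tree-ensemble imputer in the MissForest style; both keep
imputed values inside (0, observed maximum].

The γ parameter (default 0.1) models uncertainty in the unobserved total:
after CLR, one Normal(0, γ²) draw per sample is added to all entries of
that row, a pure scale perturbation that leaves all within-sample
contrasts intact. γ = 0 recovers textbook CLR with exact zero row sums
and invariance to per-sample rescaling, and is used in every test that
asserts exact values.

Beta diversity uses Euclidean distance on CLR(γ=0) rows (the Aitchison
metric); Bray-Curtis-style alternatives are out of scope. ANOSIM is
rank-based: R = (mean between-group rank − mean within-group rank)/(M/2)
over the M = n(n−1)/2 pairwise distances, with a seeded permutation
p-value (1 + #{R* ≥ R})/(1 + permutations), default 999 permutations.
Alpha diversity offers Shannon entropy, Simpson's 1 − Σp² and observed
richness; these three are this package's choice of indices, labeled as
such. All multiple-testing correction is the two-stage (adaptive)
Benjamini-Hochberg step-up.

## Trees

Motif profiles are compared by cosine distance (1 − u·v/|u||v|) on raw
non-negative profiles — cosine needs non-negativity for the [0, 1] range;
a CLR option exists. Presence/absence trees use cosine on 0/1 terminal-
motif vectors (Jaccard behind a flag). UPGMA is average linkage with
cluster-size weighting; heights use the d/2 convention so cophenetic
distances equal merge distances, making ultrametric inputs reconstruct
exactly. Entities are processed in sorted-label order so ties resolve
deterministically. Newick branch lengths are height differences; children
print in order of their smallest descendant label.

## Lactation dynamics

Samples are Ward-clustered on Euclidean distances of CLR rows and cut
into k flat clusters (k = 4, the number of distinct sampling days; days
17/18/19 of the design are coded as day 18). Agreement with timepoints is
scored by the adjusted Rand index and arithmetic-mean-normalized mutual
information. Glycan-row clustering runs on the transposed matrix, with
optional row z-scoring.

Cluster trajectories report, per (cluster, day), the summed abundance of
the cluster's glycans per sample averaged over individuals with a
t-interval; summing clusters at a day recovers the total (100 for
percentage input). Motif differences across groups use one-way ANOVA with
Tukey HSD post-hocs on significant motifs and two-stage BH across motifs.
Time-series fits are degree-1 polynomials of CLR-scale motif quantity on
day, individuals pooled (no random effects by design); β is the
least-squares slope per day and p the regression ANOVA p-value.

The sulfation-branching test stratifies structures by residue count
(controlling for length), computes within each stratum the extension rate
(fraction of residues carrying a child) separately for GlcNAc6S and
unmodified GlcNAc, and applies a two-sided Wilcoxon signed-rank test to
the paired per-stratum differences; at least 5 informative strata are
required, and the direction is the sign of the median difference.
Size-stratum pairing is this package's reading of "controlled for
length"; the pairing unit is swappable.

## Cross-omics

Cross-correlation computes Spearman ρ for every (motif, metabolite) pair
on CLR data — correlation of log-ratio-transformed compositions is the
standard guard against compositional artifacts — with two-tailed t-tests
on ρ (n − 2 df) and a two-stage BH mask at q < 0.05. Regularized partial
correlation regresses each member of a pair on all remaining features
with ridge penalty (default 0.1 × feature count) and reports the Spearman
ρ of the residual vectors; as the penalty → ∞ this converges to the
marginal Spearman ρ. Modality informativeness Ward-clusters each modality
(and their unscaled concatenation) into k clusters and scores ARI/NMI
against timepoints, optionally after projection onto leading principal
components (an integer count or "auto" = 80 % cumulative variance). PC1
linkage runs column-centered, unscaled PCA per modality and reports PC1
variance shares and the Pearson r of the PC1 scores, orienting each PC1
to correlate positively with day when days are supplied.

## Synthetic-data generator

The generator emulates the study design — 5 individuals × 4 timepoints
(days 2, 7, 13, 18), 20 samples — with known ground truth.

**Structures** grow from lactose by a probabilistic grammar: terminal
galactoses extend with a type-2 LacNAc unit (GlcNAcβ1-3 + Galβ1-4,
probability 0.5 per site), eligible internal galactoses branch with
GlcNAcβ1-6 + Galβ1-4 (0.25), new GlcNAc residues are 6-O-sulfated (0.15)
and capped with Gal (or GalNAc, giving LacdiNAc, 0.1); decorations add
Fucα1-2 on terminal Gal (0.3), Fucα1-3 on GlcNAc (0.2) and Neu5Ac α2-3 or
α2-6 caps (0.15 each). `max_size` (default 14) bounds the backbone.
Separate cap probabilities for sulfated vs unmodified GlcNAc let the
sulfation-branching effect be planted explicitly; they are equal (1.0) by
default. Every output parses, round-trips and is accepted by the motif
engine.

**Cohorts**: expected abundance of glycan g in sample (individual i, day
d) is base_g × multiplier(cluster_g, d) × lognormal(σ = 0.2) individual
effect, with temporal multipliers Early = (1, 0, 0, 0), Stable =
(1, 1, 1, 1), Late = (0, 0.5, 1, 1.5) and Sporadic = Bernoulli(0.3)
presence per timepoint (forced present somewhere, since an all-zero
feature is unmeasurable). Shapes are qualitative reading of the temporal
cluster patterns; magnitudes are free choices recorded in the ground
truth. Observed rows are Dirichlet draws (concentration 200) around the
expected composition, expressed as percentages; exact zeros stay zero.
"Low noise" in recovery tests means σ = 0.05 and concentration 1000.

**Metabolomes** default to 5× the glycome's feature count. A latent day
factor (standardized day) drives bystander metabolites through log-scale
loadings drawn Normal(0, 1) and re-centered to sum exactly to zero — the
balancing makes direct links survive CLR closure undistorted, so a
noiseless planted link has Spearman ρ = 1 after CLR. Planted direct links
set a metabolite's log-value to the CLR value of a partner glycan chosen
among glycans present in every sample (variance-ranked): a direct
metabolic coupling to a mostly-absent glycan is not representable.
Individual effects (0.3 × noise) and measurement noise scale together.

## What the tests show — and what they don't

The generator produces compositional tables with planted cluster,
trend and link structure, but it does not emulate real-data features such
as batch effects, censored/limit-of-detection missingness (zeros here are
structural, not detection failures), heavy-tailed abundance errors,
metabolite-metabolite reaction networks, or realistic motif frequency
spectra of seal milk. Recovery results therefore demonstrate correctness
of the estimators under the stated model, not field performance.

Known limitations: partial-correlation ranking of planted direct pairs is
reliable when bystanders are unrelated noise (the construction used in
the recovery suite), but with a strong shared latent factor at n = 20
samples, latent-driven bystander pairs can out-rank a weak direct link —
conditioning on ~20 features with ridge shrinkage only partially removes
a common factor. Time-series fits pool individuals (no mixed effects);
ANOSIM assumes exchangeable samples under the null, ignoring repeated
measures of the same individuals; the Wilcoxon size-stratum pairing
weighs all strata equally regardless of how many residues they contain.

## Problem sizes and determinism

Default analyses run on 20-sample × 60-glycan cohorts; calibration suites
use 100–500 replicates (ANOSIM type-I at 199 permutations, FDR at
100–200 simulations, slope recovery at 200 replicates), chosen as the
smallest sizes at which binomial confidence intervals are informative.
Every stochastic step takes an explicit seed; the pipeline derives
per-stage seeds from one master seed via a CRC-based mix, so identical
seeds give byte-identical outputs.
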