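# glycolac

Longitudinal milk-glycomics analysis for free milk oligosaccharides (MOs),
built around the kind of study design used for wild-mammal lactation
cohorts: a handful of individuals, each sampled at a few lactation
timepoints, with relative-abundance glycomics and (optionally) a paired
metabolome from the same samples.

It is a Python library for glycomics/compositional-data analysts who need
to go from IUPAC-condensed structure strings and samples × glycans
percentage tables to motif-level statistics:

* **Glycan structures** — parse and canonically re-serialize
  IUPAC-condensed strings (`Fucα1-2Gal6Sβ1-4Glc`) into rooted
  monosaccharide trees; compositions (`Neu5Ac6Hex12HexNAc10`), sizes,
  branch points, terminal residues.
* **Motifs** — terminal-constrained subtree matching against a built-in
  library of milk epitopes (Lewis X/Y, H/B/Galili antigens, I/i antigens,
  LacdiNAc, proximal/distal type-2 sialyl-H, keratan-sulfate-like units,
  …); abundance-weighted motif quantities
  `m_k(s) = Σ_g c_{gk} · x_{gs}` (occurrence count × relative abundance).
* **Compositional statistics** — Winsorize → impute → centered log-ratio
  transform `clr(x) = log x − mean(log x)` with an optional scale
  perturbation γ; Shannon/Simpson/richness alpha diversity; Aitchison
  beta diversity with ANOSIM; Mann-Whitney screens; two-stage
  Benjamini-Hochberg FDR everywhere.
* **Glyco-phylogenetics** — cosine distances of motif profiles (or
  presence/absence of terminal motifs), UPGMA dendrograms, newick export.
* **Lactation dynamics** — Ward clustering of CLR rows scored by ARI/NMI
  against timepoints, Early/Stable/Late glycan-cluster trajectories,
  per-motif one-way ANOVA with Tukey HSD, degree-1 time-series fits
  (slope β per day), and a Wilcoxon signed-rank test of whether GlcNAc
  6-O-sulfation suppresses chain extension, controlled for structure size.
* **Cross-omics** — Spearman cross-correlation of CLR glycome and
  metabolome with t-test significance and FDR masking, regularized
  (ridge-residual) partial correlations, per-modality clustering
  informativeness with optional PCA denoising, and PC1 linkage between
  modalities.
* **Synthetic cohorts** — a seeded generator (5 individuals × 4
  timepoints by default) producing structures from a lactose-core
  poly-LacNAc grammar, compositional abundance tables with planted
  temporal clusters, and paired metabolomes with planted direct links —
  every statistic above can be scored against recorded ground truth.

## Worked example

`examples/lactation_dynamics.py` simulates a low-noise cohort and recovers
its temporal structure:

```text
cohort: 20 samples × 60 glycans
timepoint recovery: ARI=1.000  NMI=1.000  (1 = perfect)
Early    total abundance over days 2/7/13/18: [34.3, 0.0, 0.0, 0.0]
Stable   total abundance over days 2/7/13/18: [63.5, 84.4, 81.4, 75.8]
Late     total abundance over days 2/7/13/18: [0.0, 7.8, 14.4, 20.4]
steepest motif trend: Neu5Ac(a2-6)Gal  beta=+0.030/day  q=0.00019
```

20 samples is the 5 × 4 study manifest; ARI/NMI of 1 mean Ward clustering
of the CLR matrix at k=4 reproduces the four lactation timepoints exactly;
the Early cluster is present only on day 2 and the Late cluster rises
through lactation, as planted; the motif time-series fit reports the
steepest CLR-scale slope per day with its two-stage-BH q-value.

The other scripts in `examples/` each demonstrate one capability
(`parse_structures`, `motif_quantification`, `glyco_tree`, `cross_omics`,
`sulfation_branching`, `full_pipeline`). A thin `glyco` command-line
wrapper exposes the same stages (`glyco parse`, `glyco simulate-cohort`,
`glyco cluster`, `glyco run`, …).

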