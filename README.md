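# coexatlas

Tools for building a cross-study gene expression atlas from public bulk
RNA-seq runs, and for mining it with coexpression networks. The package
implements the full meta-analytic pipeline used for livestock expression
atlases: harvest and gate heterogeneous archive metadata, build a merged
reference transcriptome, quantify every library the same way, reject
badly prepared libraries, average biological replicates, and cluster the
resulting genes-by-samples matrix into coexpression modules that follow the
guilt-by-association principle.

It is aimed at researchers assembling tissue atlases for species where
hundreds of unrelated public RNA-seq submissions exist but no curated
expression resource does.

## What it computes

**Library selection.** Study-level summaries are filtered by data type and
taxonomy; run-level RunInfo records pass only if they are paired-end
Illumina transcriptomic RNA-seq (cDNA or rRNA-depletion selection) with
average read length ≥ 100 bp and ≥ 10⁷ read pairs. Free-text metadata is
harmonized over observed key variants (`tissue`, `tissue_type`,
`organism part`, …); runs without any tissue/cell-type label are dropped.

**Reference construction.** Protein-coding cDNAs from an Ensembl-style
release are merged with RefSeq-style mRNAs trimmed to their longest ORF
(ATG → in-frame stop, stop included, forward strand); RefSeq records
cross-referenced to Ensembl or sequence-identical to an Ensembl entry are
excluded. A second pass can drop transcripts whose compendium-wide median
TPM is < 1.

**Quantification.** Each library is downsampled (without replacement,
seeded) to a common depth several times. Read pairs are pseudo-aligned to
the reference by intersecting the transcript hit-sets of their 31-mers, and
equivalence-class counts are resolved by an EM in which class counts are
apportioned ∝ θ_t/ℓ_t with ℓ_t = max(ℓ − μ_frag + 1, 1). Abundances are
reported as TPM (Σ TPM = 10⁶), summed to gene level, and the library's
expression is the per-gene median across replicates.

**Library QC.** For each library the package fits the slope of
log₁₀ (#genes with TPM ≥ t) against log₁₀ t. A well-formed bulk library
follows Zipf's law, slope ≈ −1; libraries deviating by more than 20%
(|slope + 1| > 0.2) fail. Sample sex is inferred from eight Y-chromosome
markers (EIF1AY, EIF2S3Y, DDX3Y, KDM5D, TXLNGY, USP9Y, UTY, ZFY).

**Networks.** Libraries are averaged by (BioProject, tissue, breed, sex);
genes expressed ≥ 10 TPM in at least one sample enter the all-vs-all
Pearson matrix; edges are r ≥ threshold, and clusters come from a
from-scratch Markov clustering (MCL) implementation (expansion/inflation on
the column-stochastic adjacency matrix; inflation 2.2 for a many-tissue
atlas, 1.7 for single-tissue compendia).

A synthetic-data generator (`coexatlas.synth`) produces every input the
pipeline reads — transcriptomes with planted ORFs, Zipf expression with
planted tissue modules and sex-linked Y genes, paired FASTQ, and messy
metadata — with full ground truth, so recovery is testable end to end.

## Worked example

`examples/05_coexpression_clusters.py` simulates a 500-gene, 40-library
atlas with five planted 40-gene tissue modules, averages it, and clusters
the r ≥ 0.70 gene graph at inflation 2.2:

```
40 libraries -> 26 atlas samples
  r  nodes  edges
0.5    500  39560
0.7    500  14571
0.9    238   3205
r >= 0.70: 500 nodes, 14571 edges, 7 clusters (sizes [292, 40, 40, 40, 40, 40] ...)
adjusted Rand index vs planted modules: 1.00
cluster 1 (n=292): highest mean expression in tissue_06
cluster 2 (n=40): highest mean expression in tissue_01
cluster 3 (n=40): highest mean expression in tissue_02
```

Each planted module is recovered as exactly one 40-gene cluster (adjusted
Rand index 1.0 over module genes), and each cluster's mean profile peaks in
the tissue that drove it. The other examples walk through library
selection, reference merging, quantification and QC/sex inference the same
way.

A thin CLI mirrors the library (`coexatlas harvest`, `build-ref`,
`quantify`, `qc`, `aggregate`, `sex`, `network`, `simulate`); run
`coexatlas --help` for options.

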