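# Methods

This note documents the models and procedures implemented in `coexatlas`,
the parameters that matter, and the design choices taken where the
procedure was genuinely open.

## Library selection

Study-level records are admitted when their data type contains
"transcriptome or gene expression" (case-insensitive substring — archive
submitters case species and type strings inconsistently, so exact matching
loses records) and their taxonomy id belongs to the configured set; the
default set covers *Sus scrofa*, *S. s. domesticus* and eleven recognized
subspecies taxa.

Run-level gating requires, in order: all technical fields present
(`missing_field` otherwise), platform ILLUMINA, source TRANSCRIPTOMIC,
strategy RNA-seq (both `RNA-Seq` and `RNAseq` spellings, hyphen- and
case-insensitive), layout PAIRED, selection cDNA or Inverse rRNA,
`avgLength ≥ 100` bp and `spots ≥ 10⁷`. Each rejected run carries the
first failing reason, so the gate report partitions the input and the
rejection log is auditable. The depth threshold is exposed as `min_spots`
and interpreted as a read count, matching the archive's `spots` field.

Descriptor extraction walks ordered key-variant lists (tissue →
tissue type → tissue_type → organism part → organism_part, else cell
type/cell_type; breed → breed name, else strain; sex/Sex/gender; age →
developmental stage variants). Exact key matches take precedence; a
relaxed pass treats case and space/underscore as interchangeable over the
same spellings. Sex values normalize as {m, male} → male, {f, female} →
female, anything else → unknown. A record with no tissue or cell-type
value is rejected rather than stored, since the atlas groups columns by
tissue. No per-study manual key mapping is attempted.

## Reference transcriptome

The Ensembl-style cDNA FASTA is parsed with Biopython; only records whose
header biotype token is `protein_coding` are kept (the transcript biotype
is preferred; the gene biotype is the fallback). RefSeq-style mRNAs are
trimmed to their longest open reading frame before merging because mRNAs
carry UTRs that could encapsulate an Ensembl CDS.

ORF definition: forward strand only (inputs are sense-strand cDNA), ATG
through the first in-frame stop, stop codon included, coordinates 0-based
half-open. The longest ORF wins; ties break to the 5'-most start. Codons
containing N never act as starts or stops. A record with no ORF passes
through untrimmed with a warning. The implementation is linear per frame;
the test suite checks it against a deliberately naive exhaustive
enumerator.

Merging admits a RefSeq record only when it has no Ensembl transcript
cross-reference and neither its trimmed nor its original sequence exactly
equals any Ensembl sequence. Both pre- and post-trim sequences are
compared because the order of trimming versus deduplication is otherwise
ambiguous; the union is the conservative choice. Substring containment
(an Ensembl CDS inside a RefSeq mRNA that trims to something different) is
deliberately not tested — only exact identity. Gene namespaces of the two
sources are kept disjoint, so merged transcript and gene counts are
additive; no cross-source symbol reconciliation is done.

Second-pass reduction removes transcripts whose compendium-wide median TPM
falls below a threshold (default 1; the boundary value 1.0 is retained),
dropping genes that lose all transcripts.

## Quantification

The read model is the standard pseudo-alignment one: a fragment from
transcript *t* arrives at rate θ_t/ℓ_eff(t) with
ℓ_eff(t) = max(ℓ_t − μ_frag + 1, 1). The mean fragment length μ_frag is a
fixed parameter (default 200 bp) rather than being estimated from the
data; this is an acknowledged approximation — full-scale quantifiers fit a
fragment-length distribution, and externally produced abundance tables in
the standard TSV dialect can be ingested instead when that matters.

- **Downsampling** draws exactly *n* distinct pairs uniformly without
  replacement (numpy Generator), preserving input order. Replicate *i*
  uses seed `master + i` so a single master seed reproduces a library
  byte-for-byte; a `random_seeds` option draws replicate seeds at run time
  for pipelines that prefer it. Default protocol: depth 10⁷, five
  replicates, per-gene median.
- **Indexing** maps every k-mer (default k = 31, odd, ≥ 11; N-containing
  k-mers excluded) to the set of transcripts containing it.
- **Pseudo-alignment**: per mate, the intersection of hit-sets of its
  indexed k-mers (unindexed k-mers impose no constraint; a mate with no
  indexed k-mer imposes none at all); per pair, the intersection of mate
  sets; empty → unassigned.
- **EM**: class counts are apportioned within each class ∝ θ_t/ℓ_eff(t);
  θ starts uniform and iterates until max |Δθ| < 1e-8 or 1,000 rounds.
  Estimated counts sum to the assigned pair count; TPM is
  10⁶·(c_t/ℓ_t)/Σ(c_u/ℓ_u), zero-safe for empty libraries.
- **Gene level**: transcript TPM summed per gene (total conserved), then
  the element-wise median across replicates (even counts: mean of the
  central pair). Gene-level summation happens per replicate before the
  median; the reverse order differs only slightly and this one keeps each
  replicate a complete, auditable quantification.

## Library QC (Zipf statistic)

For each library the QC statistic is the ordinary least-squares slope of
log₁₀ (#genes with TPM ≥ t) on log₁₀ t over the distinct positive TPM
values — the reverse cumulative (CCDF) curve. For ideal Zipf data
(TPM ∝ 1/rank) the slope is exactly −1; a 1/rank² law gives −1/2. The
rank-abundance fit (log TPM vs log rank) is available behind a `method`
switch and agrees at −1 on ideal data. A library passes when the exponent
is finite and |slope + 1| ≤ 0.2 (deviation measured additively on the
exponent scale; the gate fails only for deviation strictly greater than
20% of the optimum's magnitude). Fits with fewer than 100 positive genes
or degenerate support return NaN and fail.

## Averaging, filtering and sex inference

Libraries are averaged by (BioProject, tissue, breed, sex) with tissue
labels normalized (lowercase, trimmed, whitespace collapsed — no ontology
mapping); output columns are arithmetic means in first-appearance order,
so group sizes weight back to the original per-gene means exactly. The
expression filter keeps genes at TPM ≥ threshold (inclusive) in at least
one column — 10 TPM for the cross-tissue atlas preset, 5 TPM for the
single-tissue presets.

Sex is called from the eight-gene Y-marker panel: male when ≥ 3 panel
genes present in the matrix reach 1 TPM, female when all present panel
genes are below 1 TPM, unknown otherwise. The ≥ 3-gene/1-TPM thresholds
are this package's operational choice for robustness against single-gene
noise; metadata-recorded sex (including mixed/pooled annotations) is never
overwritten — inference fills "unknown" only.

## Correlation graphs and MCL

Pearson correlation is computed on untransformed TPM (a log2(x+1) flag
exists for practitioners who expect it), in row blocks to bound memory for
~26k-gene matrices; zero-variance entities are excluded with a warning,
and at least three observations are required. Edges use the inclusive
rule r ≥ t with t ∈ (0, 1] — negative correlations never form edges — and
nodes are the entities with degree ≥ 1, which is what published graph
tools report and what makes node counts shrink as t rises. The threshold
scan tabulates (nodes, edges) over a grid to support choosing the largest
node count with the fewest edges.

MCL follows the canonical algorithm: self-loops with weight equal to the
node's maximum incident edge weight, column normalization, then repeated
expansion (matrix square) and inflation (element-wise power, column
renormalization) with per-column pruning of entries < 1e-5, until the
matrix changes by < 1e-6 or 200 iterations (non-convergence is flagged,
not fatal). A column pruned to zero keeps its strongest attractor.
Clusters are read from attractor systems (attractor rows sharing nodes are
unioned); a node claimed by several systems goes to the larger cluster.
Clusters are numbered 1-based in strictly size-descending order, ties by
smallest member id — published cluster numberings are tool-internal and
not exactly reproducible, so this deterministic ordering is documented
instead. Only inflation is a scientific parameter (2.2 main atlas, 1.7
tissue-specific presets); the other knobs are exposed but default to the
canonical values.

## Synthetic data: what it emulates and what it does not

The generator emulates the features the pipeline's decisions depend on:
Zipf-distributed baseline abundances (exponent `zipf_scale`, default 1,
over a seeded random rank permutation), five planted 40-gene modules
elevated 20-fold in their host tissue, per-value lognormal noise
(σ = 0.3), Y-panel genes at 50 TPM in males and exactly 0 in females, a
10% fraction of corrupted libraries (uniform: all genes equal, giving a
degenerate unfittable CCDF; spike: one gene takes 99% of the mass), and
metadata messiness (dropped sex keys, tissue typos, single-end layouts)
drawn from the observed key-variant spellings. The default design is
12 tissues × 4 libraries over 2 BioProjects and 2,000 genes — large enough
that module recovery, QC sensitivity/specificity and sex calling are
non-trivial, small enough for routine test runs.

It does not emulate: splicing or sequence evolution, GC/positional bias,
sequencing errors (off by default), batch effects beyond BioProject
labels, or partial overlap between modules. Passing recovery tests
therefore shows the pipeline's logic is correct under its own model
assumptions, not that real archives are this clean; the metadata gate and
QC rule remain exactly as specified either way.

Read simulation draws fragments ∝ TPM × effective length with truncated
normal fragment lengths (mean 200, sd 20, bounded by read length and
transcript length); mates are the fragment ends, mate 2
reverse-complemented, and read ids carry the transcript of origin so
quantifier error can be separated from multinomial sampling noise.

## Numerical and testing notes

- TPM vectors sum to 10⁶ within 1e-3 whenever any read is assigned; the
  all-zero case returns zeros rather than dividing by zero.
- Quantifier recovery is asserted two ways: Spearman ≥ 0.95 against the
  generating abundances on 100,000 pairs, and ≤ 10% relative error
  against the *realized* fragment counts for transcripts with ≥ 50%
  unique k-mers — the realized baseline isolates assignment/EM error from
  sampling noise, which at finite depth dominates for rare transcripts.
- The downsampler's unbiasedness check uses 2,000 seeded draws of 100 from
  1,000 pairs so that the ±0.03 acceptance band sits at ≈ 4.5σ per pair;
  at materially fewer draws a correct sampler would fail such a band by
  chance alone.
- Problem sizes in the test suite (500–2,000 genes, ≤ 100k read pairs,
  ≤ 96 libraries) are the package's chosen routine-verification scale;
  every procedure is size-agnostic and the network code is blocked for
  full-atlas matrices.
- Full-scale reproductions (the published 206-sample network statistics
  and pinned-release reference counts) are implemented
  (`network.reproduce_atlas_statistics`, `reference.parse_ensembl_cdna` /
  `merge_refseq`) and run whenever the corresponding large inputs are
  supplied locally under `data/`; the files themselves are too large to
  distribute with the package.

## Known limitations

- Fixed mean fragment length instead of an estimated distribution.
- Exact-sequence deduplication only when merging annotation sources; no
  containment test, no cross-source gene unification.
- No bias correction, bootstrap, single-end mode, or strand-specific
  handling in the quantifier.
- Tissue labels are normalized typographically, not ontologically; typos
  in source metadata propagate into distinct atlas groups.
- MCL is dense-matrix; graphs far beyond ~20k nodes would need a sparse
  implementation.
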