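"""Build a merged reference transcriptome from two annotation sources.

Parses a small Ensembl-style cDNA set (protein-coding only), trims
RefSeq-style mRNAs to their longest ORF, and merges the novel ones in.
"""

import io

from coexatlas import (
    Transcriptome,
    longest_orf,
    merge_refseq,
    parse_ensembl_cdna,
    parse_refseq_mrna,
    trim_to_orf,
)

ENSEMBL = """\
>ENST0001 gene:ENSG0001 gene_biotype:protein_coding transcript_biotype:protein_coding
ATGGCCGGCTAA
>ENST0002 gene:ENSG0001 gene_biotype:protein_coding transcript_biotype:protein_coding
ATGGCCTAA
>ENST0003 gene:ENSG0002 gene_biotype:lncRNA transcript_biotype:lncRNA
ATGCATGCATGC
"""

# NM_0001 duplicates ENST0002 once its UTRs are trimmed; NM_0002 is novel.
REFSEQ = """\
>NM_0001 mRNA with UTRs around a known CDS
GGGATGGCCTAACCC
>NM_0002 a transcript Ensembl does not annotate
TTATGAAACCCGGGTAATT
"""

ensembl = parse_ensembl_cdna(io.StringIO(ENSEMBL))
print(f"Ensembl parse: {ensembl.n_transcripts} protein-coding transcripts, "
      f"{ensembl.n_genes} genes (lncRNA excluded)")

refseq = parse_refseq_mrna(io.StringIO(REFSEQ))
orf = longest_orf("GGGATGGCCTAACCC")
print(f"longest ORF of NM_0001: [{orf.start}, {orf.end}) -> "
      f"{'GGGATGGCCTAACCC'[orf.start:orf.end]}")

trimmed = Transcriptome([trim_to_orf(r) for r in refseq.records])
merged = merge_refseq(ensembl, trimmed)
print(f"merged reference: {merged.n_transcripts} transcripts, "
      f"{merged.n_genes} genes")
# Only NM_0002 is admitted: the trimmed NM_0001 equals ENST0002 exactly, so
# the merged counts are Ensembl's plus one transcript and one gene.
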