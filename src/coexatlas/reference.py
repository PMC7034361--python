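"""Merged reference transcriptome construction.

The quantification index is built from two annotation sources: an
Ensembl-style cDNA FASTA restricted to protein-coding transcripts, and a
RefSeq-style mRNA FASTA whose records are trimmed to their longest open
reading frame (RefSeq mRNAs carry UTRs and could otherwise encapsulate an
Ensembl CDS). RefSeq records already cross-referenced to Ensembl ids, or
whose sequence is already present in the Ensembl set, are excluded. After a
first quantification pass, transcripts never detected across the sample
compendium can be dropped to form a leaner second-pass reference.

Coordinates are 0-based half-open throughout. Gene namespaces of the two
sources are kept disjoint; no cross-source gene reconciliation is
attempted, so merged gene counts are additive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class TranscriptRecord:
    """A single transcript sequence with its gene assignment and provenance."""

    transcript_id: str
    gene_id: str
    source: str  # "ensembl" or "refseq"
    biotype: str = ""
    sequence: str = ""
    ensembl_xref: str | None = None
    untrimmed_sequence: str | None = None  # original mRNA, kept through ORF trimming

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.transcript_id}: empty sequence")
        if not self.gene_id:
            raise ValueError(f"{self.transcript_id}: empty gene_id")


@dataclass
class Transcriptome:
    """An ordered set of transcripts plus the induced gene-to-transcript map."""

    records: list[TranscriptRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.transcript_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate transcript_id in Transcriptome")

    @property
    def gene_map(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for r in self.records:
            out.setdefault(r.gene_id, set()).add(r.transcript_id)
        return out

    @property
    def n_transcripts(self) -> int:
        return len(self.records)

    @property
    def n_genes(self) -> int:
        return len({r.gene_id for r in self.records})

    def gene_of(self) -> dict[str, str]:
        """Transcript-to-gene mapping."""
        return {r.transcript_id: r.gene_id for r in self.records}

    def lengths(self) -> dict[str, int]:
        return {r.transcript_id: len(r.sequence) for r in self.records}

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(f">{r.transcript_id} gene:{r.gene_id} source:{r.source}\n")
                seq = r.sequence
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")

    def write_gene_map(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\ttranscript_id\tsource\n")
            for r in self.records:
                fh.write(f"{r.gene_id}\t{r.transcript_id}\t{r.source}\n")


@dataclass(frozen=True)
class OrfInterval:
    """A 0-based half-open ORF interval; the stop codon is included."""

    start: int
    end: int
    has_stop: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("invalid ORF interval")
        if self.has_stop and (self.end - self.start) % 3:
            raise ValueError("stopped ORF length must be a multiple of 3")


def _header_fields(description: str) -> dict[str, str]:
    """Parse ``key:value`` tokens from an Ensembl-style FASTA description."""
    out: dict[str, str] = {}
    for token in description.split():
        if ":" in token:
            key, _, value = token.partition(":")
            out.setdefault(key, value)
    return out


def parse_ensembl_cdna(fasta: str | Path | IO[str]) -> Transcriptome:
    """Parse an Ensembl-dialect cDNA FASTA, keeping protein-coding transcripts.

    Headers must carry ``gene:<id>`` and a ``transcript_biotype:`` (or
    ``gene_biotype:``) token; records missing either are skipped with a
    warning. Version suffixes on gene ids are removed; sequences are
    uppercased.
    """
    records: list[TranscriptRecord] = []
    for rec in SeqIO.parse(fasta, "fasta"):
        fields = _header_fields(rec.description)
        gene = fields.get("gene", "")
        biotype = fields.get("transcript_biotype") or fields.get("gene_biotype") or ""
        if not gene or not biotype:
            logger.warning("skipping %s: header lacks gene id or biotype", rec.id)
            continue
        if biotype != "protein_coding":
            continue
        records.append(TranscriptRecord(
            transcript_id=rec.id,
            gene_id=gene.split(".")[0],
            source="ensembl",
            biotype=biotype,
            sequence=str(rec.seq).upper(),
        ))
    return Transcriptome(records)


def parse_refseq_mrna(
    fasta: str | Path | IO[str],
    xref: Mapping[str, str] | None = None,
    gene_map: Mapping[str, str] | None = None,
) -> Transcriptome:
    """Parse a RefSeq-dialect mRNA FASTA (accession-first headers).

    *xref* maps RefSeq transcript accessions to Ensembl transcript ids where
    such an assignment exists; *gene_map* maps accessions to gene ids. An
    accession with no gene mapping is treated as its own single-transcript
    gene.
    """
    xref = dict(xref or {})
    gene_map = dict(gene_map or {})
    records = []
    for rec in SeqIO.parse(fasta, "fasta"):
        acc = rec.id
        records.append(TranscriptRecord(
            transcript_id=acc,
            gene_id=gene_map.get(acc, acc),
            source="refseq",
            biotype="mRNA",
            sequence=str(rec.seq).upper(),
            ensembl_xref=xref.get(acc),
        ))
    return Transcriptome(records)


def read_xref_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping RefSeq accession to Ensembl transcript id."""
    out: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()  # column names, ignored
        del header
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0] and parts[1]:
                out[parts[0]] = parts[1]
    return out


def longest_orf(sequence: str) -> OrfInterval | None:
    """Longest forward-strand ORF: ATG through an in-frame stop, inclusive.

    Ties go to the 5'-most start. Codons containing N never act as starts or
    stops. Returns ``None`` when no ATG-initiated, stop-terminated frame
    exists.
    """
    seq = sequence.upper()
    n = len(seq)
    best: tuple[int, int] | None = None  # (length, -start) maximized
    best_iv: OrfInterval | None = None
    for frame in range(3):
        stops = [i for i in range(frame, n - 2, 3) if seq[i:i + 3] in STOP_CODONS]
        starts = [i for i in range(frame, n - 2, 3) if seq[i:i + 3] == "ATG"]
        si = 0
        for start in starts:
            while si < len(stops) and stops[si] < start:
                si += 1
            # all stops before this start are also before later starts in
            # this frame, so si only moves forward
            j = si
            if j >= len(stops):
                continue
            end = stops[j] + 3
            length = end - start
            key = (length, -start)
            if best is None or key > best:
                best = key
                best_iv = OrfInterval(start=start, end=end, has_stop=True)
    return best_iv


def trim_to_orf(record: TranscriptRecord) -> TranscriptRecord:
    """Replace an mRNA's sequence with its longest ORF, dropping the UTRs.

    Records without any ORF are returned unmodified (with a warning) so that
    downstream deduplication still sees them. The pre-trim sequence is
    retained on the record for sequence-identity checks at merge time.
    """
    iv = longest_orf(record.sequence)
    if iv is None:
        logger.warning("%s: no ORF found, sequence left untrimmed",
                       record.transcript_id)
        return replace(record, untrimmed_sequence=record.sequence)
    return replace(
        record,
        sequence=record.sequence[iv.start:iv.end].upper(),
        untrimmed_sequence=record.sequence,
    )


def merge_refseq(ensembl: Transcriptome, refseq: Transcriptome) -> Transcriptome:
    """Merge trimmed RefSeq records into the Ensembl set.

    A RefSeq record is admitted only if it carries no Ensembl cross-reference
    and neither its trimmed nor its pre-trim sequence equals any Ensembl
    sequence (exact uppercase string identity; the conservative union of
    both comparisons). Ensembl records pass through unchanged; RefSeq ids
    colliding with Ensembl ids are renamed with a ``_refseq`` suffix.
    """
    ensembl_seqs = {r.sequence for r in ensembl.records}
    ensembl_ids = {r.transcript_id for r in ensembl.records}
    merged = list(ensembl.records)
    for rec in refseq.records:
        if rec.ensembl_xref:
            continue
        if rec.sequence in ensembl_seqs:
            continue
        if rec.untrimmed_sequence and rec.untrimmed_sequence in ensembl_seqs:
            continue
        if rec.transcript_id in ensembl_ids:
            new_id = rec.transcript_id + "_refseq"
            logger.warning("transcript id collision: %s renamed to %s",
                           rec.transcript_id, new_id)
            rec = replace(rec, transcript_id=new_id)
        merged.append(rec)
    return Transcriptome(merged)


def drop_undetected(
    transcriptome: Transcriptome,
    median_tpm_per_transcript: Mapping[str, float],
    threshold: float = 1.0,
) -> tuple[Transcriptome, int]:
    """Second-pass index reduction: drop transcripts with median TPM < threshold.

    Transcripts absent from the median table count as undetected (median 0).
    Genes whose transcripts are all removed disappear from the gene map.
    Returns the reduced transcriptome and the number of transcripts removed.
    """
    kept = [r for r in transcriptome.records
            if median_tpm_per_transcript.get(r.transcript_id, 0.0) >= threshold]
    removed = len(transcriptome.records) - len(kept)
    return Transcriptome(kept), removed


def brute_force_longest_orf(sequence: str) -> OrfInterval | None:
    """Reference ORF finder by exhaustive enumeration of every ATG...stop pair.

    Deliberately naive (checks every start position independently); used as
    the oracle for :func:`longest_orf` in the test suite.
    """
    seq = sequence.upper()
    n = len(seq)
    candidates: list[tuple[int, int, int]] = []  # (length, -start, start)
    for start in range(n - 2):
        if seq[start:start + 3] != "ATG":
            continue
        for j in range(start + 3, n - 2, 3):
            if seq[j:j + 3] in STOP_CODONS:
                candidates.append((j + 3 - start, -start, start))
                break
    if not candidates:
        return None
    length, neg_start, start = max(candidates)
    del neg_start
    return OrfInterval(start=start, end=start + length, has_stop=True)
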