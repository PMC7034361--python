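"""Lightweight pseudo-alignment quantification of paired-end reads.

Expression is estimated per library by (i) exact seeded downsampling of the
read pairs to a common depth, (ii) pseudo-alignment of each pair to the set
of reference transcripts sharing all of its indexed k-mers, (iii) an
equivalence-class EM that apportions each class count among its member
transcripts in proportion to abundance over effective length, and (iv)
normalization to transcripts per million (TPM). Transcript TPM is summed to
gene level, and a library's expression is the per-gene median over several
downsampled replicates.

The model is the standard one for pseudo-alignment quantifiers: reads are
assumed to derive from transcript *t* at rate theta_t / l_eff(t), where
l_eff(t) = max(l_t - mu_frag + 1, 1) for a fixed mean fragment length
mu_frag. Fragment-length estimation, bias correction and bootstrap
resampling are out of scope; an external quantifier's abundance tables can
be ingested instead via :func:`read_abundance_tsv`.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .reference import Transcriptome

logger = logging.getLogger(__name__)

DEFAULT_K = 31
DEFAULT_FRAGMENT_LENGTH = 200.0


class InsufficientDepthError(ValueError):
    """Raised when a library is shallower than the requested downsample depth."""


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


@dataclass
class KmerIndex:
    """Map from each k-mer of the reference to the transcripts containing it."""

    k: int
    table: dict[str, frozenset[str]]
    transcript_lengths: dict[str, int]


@dataclass
class EquivalenceClassCounts:
    """Read-pair counts per compatibility class (sorted transcript-id tuple)."""

    classes: dict[tuple[str, ...], int] = field(default_factory=dict)
    unassigned: int = 0

    @property
    def assigned(self) -> int:
        return sum(self.classes.values())


@dataclass
class AbundanceTable:
    """Per-transcript estimated counts, effective lengths and TPM.

    ``table`` is indexed by transcript_id with columns
    (length, eff_length, est_counts, tpm) — the standard abundance-table
    dialect, so it round-trips through TSV against external quantifiers.
    """

    table: pd.DataFrame
    mean_fragment_length: float = DEFAULT_FRAGMENT_LENGTH

    def tpm(self) -> pd.Series:
        return self.table["tpm"]


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_paired_fastq(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    """Load a pair of (optionally gzipped) FASTQ files into memory."""
    pairs = []
    with _open_maybe_gzip(path1) as f1, _open_maybe_gzip(path2) as f2:
        for (t1, s1, q1), (t2, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2), strict=True
        ):
            rid = t1.split()[0].removesuffix("/1")
            rid2 = t2.split()[0].removesuffix("/2")
            if rid != rid2:
                raise ValueError(f"mate id mismatch: {rid} vs {rid2}")
            pairs.append(ReadPair(rid, s1, q1, s2, q2))
    return pairs


def write_paired_fastq(
    pairs: Sequence[ReadPair], path1: str | Path, path2: str | Path
) -> None:
    """Write read pairs as two gzipped FASTQ files."""
    with gzip.open(path1, "wt") as f1, gzip.open(path2, "wt") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{p.qual2}\n")


def downsample(
    pairs: Sequence[ReadPair], n: int = 10_000_000, seed: int = 0
) -> list[ReadPair]:
    """Sample exactly *n* distinct pairs uniformly without replacement.

    The original relative order is preserved and the draw is a deterministic
    function of *seed*. Libraries shallower than *n* raise
    :class:`InsufficientDepthError` — the metadata gate should have excluded
    them.
    """
    depth = len(pairs)
    if depth < n:
        raise InsufficientDepthError(
            f"insufficient_depth: {depth} pairs < requested {n}"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(depth, size=n, replace=False))
    return [pairs[i] for i in idx]


def build_index(transcriptome: Transcriptome, k: int = DEFAULT_K) -> KmerIndex:
    """Index every k-mer of every transcript (k odd, >= 11; N-containing k-mers skipped)."""
    if not transcriptome.records:
        raise ValueError("cannot index an empty transcriptome")
    if k < 11 or k % 2 == 0:
        raise ValueError("k must be odd and >= 11")
    table: dict[str, set[str]] = {}
    for rec in transcriptome.records:
        seq = rec.sequence
        if len(seq) < k:
            logger.warning("%s shorter than k=%d, contributes no k-mers",
                           rec.transcript_id, k)
            continue
        tid = rec.transcript_id
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if "N" in kmer:
                continue
            table.setdefault(kmer, set()).add(tid)
    frozen = {kmer: frozenset(tids) for kmer, tids in table.items()}
    return KmerIndex(k=k, table=frozen, transcript_lengths=transcriptome.lengths())


def _mate_compatibility(seq: str, index: KmerIndex) -> frozenset[str] | None:
    """Intersection of hit sets over the mate's indexed k-mers; None if no k-mer is indexed."""
    k = index.k
    table = index.table
    result: set[str] | None = None
    for i in range(len(seq) - k + 1):
        hits = table.get(seq[i:i + k])
        if hits is None:
            continue
        if result is None:
            result = set(hits)
        else:
            result &= hits
            if not result:
                return frozenset()
    return frozenset(result) if result is not None else None


def pseudoalign(pair: ReadPair, index: KmerIndex) -> frozenset[str] | None:
    """Compatibility set of a read pair, or None when unassigned.

    Each mate's set is the intersection of the hit sets of its k-mers,
    ignoring k-mers absent from the index; a mate with no indexed k-mer
    imposes no constraint. The pair's set is the intersection of the mates'.
    """
    s1 = _mate_compatibility(pair.seq1.upper(), index)
    s2 = _mate_compatibility(pair.seq2.upper(), index)
    if s1 is None and s2 is None:
        return None
    if s1 is None:
        final = s2
    elif s2 is None:
        final = s1
    else:
        final = s1 & s2
    return final if final else None


def count_classes(
    pairs: Iterable[ReadPair], index: KmerIndex
) -> EquivalenceClassCounts:
    """Pseudo-align a set of pairs and tally equivalence-class counts."""
    eq = EquivalenceClassCounts()
    classes = eq.classes
    for pair in pairs:
        hit = pseudoalign(pair, index)
        if hit is None:
            eq.unassigned += 1
        else:
            key = tuple(sorted(hit))
            classes[key] = classes.get(key, 0) + 1
    return eq


def effective_lengths(
    lengths: Mapping[str, int],
    mean_fragment_length: float = DEFAULT_FRAGMENT_LENGTH,
) -> dict[str, float]:
    """l_eff = max(l - mu_frag + 1, 1)."""
    return {t: max(l - mean_fragment_length + 1.0, 1.0)
            for t, l in lengths.items()}


def tpm(est_counts: np.ndarray, eff_lengths: np.ndarray) -> np.ndarray:
    """Transcripts per million from counts and effective lengths.

    rate_t = counts_t / l_eff(t); tpm_t = 1e6 * rate_t / sum(rate). An
    all-zero count vector maps to all-zero TPM.
    """
    est_counts = np.asarray(est_counts, dtype=float)
    eff_lengths = np.asarray(eff_lengths, dtype=float)
    rate = est_counts / eff_lengths
    total = rate.sum()
    if total <= 0:
        return np.zeros_like(rate)
    return 1e6 * rate / total


def em_abundance(
    eq: EquivalenceClassCounts,
    eff_lengths: Mapping[str, float],
    lengths: Mapping[str, int] | None = None,
    mean_fragment_length: float = DEFAULT_FRAGMENT_LENGTH,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> AbundanceTable:
    """Equivalence-class EM for transcript abundances.

    Each class count is apportioned among its member transcripts in
    proportion to theta_t / l_eff(t); abundances start uniform and iterate
    until the largest abundance change falls below *tol* (or *max_iter*).
    Transcripts in *eff_lengths* but in no class receive zero counts. With
    no assigned reads the table is all zeros.
    """
    tids = sorted(eff_lengths)
    t_index = {t: i for i, t in enumerate(tids)}
    n_t = len(tids)
    lens = np.array([(lengths or {}).get(t, 0) for t in tids], dtype=float)
    eff = np.array([max(eff_lengths[t], 1.0) for t in tids], dtype=float)

    class_items = [(np.array([t_index[t] for t in members], dtype=np.intp), cnt)
                   for members, cnt in eq.classes.items() if cnt > 0]
    total = float(sum(cnt for _, cnt in class_items))
    if not class_items or total == 0:
        zero = np.zeros(n_t)
        table = pd.DataFrame(
            {"length": lens, "eff_length": eff, "est_counts": zero, "tpm": zero},
            index=pd.Index(tids, name="target_id"),
        )
        return AbundanceTable(table, mean_fragment_length)

    # flat layout for vectorized E-steps
    flat = np.concatenate([m for m, _ in class_items])
    sizes = np.array([len(m) for m, _ in class_items])
    counts = np.array([c for _, c in class_items], dtype=float)
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])

    theta = np.full(n_t, 1.0 / n_t)
    for _ in range(max_iter):
        w = theta / eff
        class_sums = np.add.reduceat(w[flat], offsets)
        share = w[flat] / np.repeat(class_sums, sizes) * np.repeat(counts, sizes)
        alpha = np.bincount(flat, weights=share, minlength=n_t)
        theta_new = alpha / total
        if np.max(np.abs(theta_new - theta)) < tol:
            theta = theta_new
            break
        theta = theta_new

    w = theta / eff
    class_sums = np.add.reduceat(w[flat], offsets)
    share = w[flat] / np.repeat(class_sums, sizes) * np.repeat(counts, sizes)
    est_counts = np.bincount(flat, weights=share, minlength=n_t)
    table = pd.DataFrame(
        {"length": lens, "eff_length": eff, "est_counts": est_counts,
         "tpm": tpm(est_counts, eff)},
        index=pd.Index(tids, name="target_id"),
    )
    return AbundanceTable(table, mean_fragment_length)


def gene_tpm(
    transcript_tpm: pd.Series, gene_of: Mapping[str, str]
) -> pd.Series:
    """Sum transcript TPM to gene level; totals are preserved exactly.

    Every transcript must map to a gene; an orphan raises ``ValueError``.
    """
    missing = [t for t in transcript_tpm.index if t not in gene_of]
    if missing:
        raise ValueError(f"transcripts without gene assignment: {missing[:5]}")
    genes = transcript_tpm.index.map(gene_of)
    out = transcript_tpm.groupby(genes).sum()
    out.index.name = "gene_id"
    return out


def median_of_replicates(replicates: Sequence[pd.Series]) -> pd.Series:
    """Element-wise median across replicate gene vectors (even count: mean of central pair)."""
    if not replicates:
        raise ValueError("no replicates supplied")
    df = pd.concat(replicates, axis=1)
    if df.isna().any().any():
        raise ValueError("replicates cover different gene sets")
    return df.median(axis=1)


def quantify_library(
    transcriptome: Transcriptome,
    pairs: Sequence[ReadPair],
    n: int = 10_000_000,
    replicates: int = 5,
    seed: int = 0,
    k: int = DEFAULT_K,
    mean_fragment_length: float = DEFAULT_FRAGMENT_LENGTH,
    random_seeds: bool = False,
    index: KmerIndex | None = None,
) -> tuple[pd.Series, list[AbundanceTable]]:
    """Full per-library quantification: downsample, pseudo-align, EM, median.

    Replicate *i* uses seed ``seed + i`` so a master seed reproduces the
    whole library byte-for-byte; with ``random_seeds=True`` replicate seeds
    are themselves drawn at run time (seeded only by the master seed),
    mimicking pipelines that assign downsampling seeds randomly.

    Returns the per-gene median TPM across replicates and the replicate
    abundance tables.
    """
    if index is None:
        index = build_index(transcriptome, k=k)
    eff = effective_lengths(index.transcript_lengths, mean_fragment_length)
    gene_of = transcriptome.gene_of()
    if random_seeds:
        seeds = list(np.random.default_rng(seed).integers(0, 2**31 - 1, replicates))
    else:
        seeds = [seed + i for i in range(replicates)]
    gene_vectors = []
    tables = []
    for rep_seed in seeds:
        sub = downsample(pairs, n=n, seed=int(rep_seed))
        eq = count_classes(sub, index)
        tab = em_abundance(eq, eff, lengths=index.transcript_lengths,
                           mean_fragment_length=mean_fragment_length)
        tables.append(tab)
        gene_vectors.append(gene_tpm(tab.tpm(), gene_of))
    return median_of_replicates(gene_vectors), tables


def write_abundance_tsv(table: AbundanceTable, path: str | Path) -> None:
    df = table.table.reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_abundance_tsv(path: str | Path) -> AbundanceTable:
    """Ingest an abundance TSV in the standard (target_id, length, eff_length,
    est_counts, tpm) dialect, e.g. from a full-scale external quantifier."""
    df = pd.read_csv(path, sep="\t").set_index("target_id")
    required = {"length", "eff_length", "est_counts", "tpm"}
    if not required.issubset(df.columns):
        raise ValueError(f"abundance table missing columns {required - set(df.columns)}")
    return AbundanceTable(df[["length", "eff_length", "est_counts", "tpm"]])
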