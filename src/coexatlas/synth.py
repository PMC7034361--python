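"""Synthetic atlas generator with known ground truth.

Emulates the statistical structure the pipeline assumes in real compendia:
Zipf-distributed baseline gene abundances, tissue-specific planted
coexpression modules driven by shared tissue identity, Y-chromosome marker
expression in males only, a configurable fraction of QC-failing libraries,
and messy run metadata with variant key spellings, typos and missing
fields. Every output is a deterministic function of (design, seed), and the
generator emits exactly the file formats the rest of the pipeline reads, so
recovery of the planted truth can be tested end to end.

It does not emulate sequence evolution, splicing, GC or positional bias, or
batch effects beyond BioProject labels; read simulation is error-free by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .metadata import SEX_KEYS, TISSUE_KEYS, BREED_KEYS, AGE_KEYS
from .qc import Y_PANEL
from .quantify import ReadPair, effective_lengths
from .reference import Transcriptome, TranscriptRecord

BASES = np.array(list("ACGT"))
STOP_SET = {"TAA", "TAG", "TGA"}
BREEDS = ("Duroc", "Landrace", "Large White", "Pietrain", "Berkshire", "Meishan")


@dataclass(frozen=True)
class AtlasDesign:
    """Study design of a synthetic atlas.

    Defaults give 12 tissues x 4 libraries spread over 2 BioProjects
    (96 libraries), 2,000 genes with five 40-gene modules elevated 20-fold
    in their host tissue, multiplicative lognormal noise (sigma 0.3), and
    10% corrupted (QC-failing) libraries — compact enough for routine test
    runs while preserving the structure the pipeline must recover.
    """

    n_tissues: int = 12
    libraries_per_tissue: int = 4
    n_bioprojects: int = 2
    n_genes: int = 2000
    module_spec: tuple[tuple[str, int, float], ...] = tuple(
        (f"tissue_{i:02d}", 40, 20.0) for i in range(1, 6)
    )
    zipf_scale: float = 1.0  # exponent of the 1/rank^s baseline
    noise_sigma: float = 0.3
    sex_ratio: float = 0.5
    y_panel_tpm: float = 50.0
    corrupt_fraction: float = 0.1
    corrupt_mode: str = "uniform"  # or "spike"
    messiness: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_tissues, self.libraries_per_tissue,
               self.n_bioprojects, self.n_genes) < 1:
            raise ValueError("all design counts must be >= 1")
        if sum(size for _, size, _ in self.module_spec) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        for frac in (self.sex_ratio, self.corrupt_fraction, self.messiness):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.corrupt_mode not in ("uniform", "spike"):
            raise ValueError("corrupt_mode must be 'uniform' or 'spike'")

    @property
    def n_samples(self) -> int:
        return self.n_tissues * self.libraries_per_tissue

    @property
    def tissues(self) -> list[str]:
        return [f"tissue_{i:02d}" for i in range(1, self.n_tissues + 1)]


@dataclass
class GroundTruth:
    """The generator's hidden state: what a perfect pipeline should recover."""

    true_tpm: ExpressionMatrix
    module_membership: dict[str, str]  # gene -> module label
    sex_assignment: dict[str, str]  # sample -> male/female
    qc_flags: dict[str, str]  # sample -> clean/corrupted


def _random_orf_codons(rng: np.random.Generator, n_codons: int) -> str:
    """Random codons avoiding in-frame stops."""
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(BASES, size=3))
        if c not in STOP_SET and c != "ATG":
            codons.append(c)
    return "".join(codons)


def _random_utr(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def simulate_transcriptome(
    n_genes: int,
    transcripts_per_gene_range: tuple[int, int] = (1, 1),
    seed: int = 0,
) -> Transcriptome:
    """Random transcripts of 600-3,000 nt, each with a planted ORF >= 300 nt.

    Each sequence is UTR + ATG + stop-free codons + stop + UTR, so the ORF
    trimmer always finds an ORF. The last eight genes are named after the
    Y-chromosome marker panel so sex-linked expression can be simulated.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = transcripts_per_gene_range
    gene_ids = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    if n_genes >= len(Y_PANEL):
        gene_ids[-len(Y_PANEL):] = list(Y_PANEL)
    records = []
    for gid in gene_ids:
        n_tx = int(rng.integers(lo, hi + 1))
        for t in range(1, n_tx + 1):
            total = int(rng.integers(600, 3001))
            orf_codons = int(rng.integers(100, max(100, (total - 60) // 3) + 1))
            orf_len = 3 * orf_codons + 6  # ATG + body + stop
            orf_len = min(orf_len, total - 20)
            body = (orf_len - 6) // 3
            utr5 = int(rng.integers(5, total - (3 * body + 6) - 5 + 1))
            utr3 = total - utr5 - (3 * body + 6)
            seq = (_random_utr(rng, utr5) + "ATG" + _random_orf_codons(rng, body)
                   + "TAA" + _random_utr(rng, utr3))
            records.append(TranscriptRecord(
                transcript_id=f"{gid}.t{t}", gene_id=gid,
                source="ensembl", biotype="protein_coding", sequence=seq,
            ))
    return Transcriptome(records)


def simulate_expression(design: AtlasDesign) -> GroundTruth:
    """Draw the ground-truth TPM matrix and sample annotations for a design.

    Baseline abundance of gene g is proportional to 1/rank^zipf_scale over a
    seeded random rank permutation. Module genes are multiplied by their
    fold-elevation in samples of the host tissue; every value then receives
    lognormal noise exp(sigma*N(0,1)). Y-panel genes express at y_panel_tpm
    (before noise) in males and exactly zero in females. A corrupt_fraction
    of samples is replaced per corrupt_mode (uniform: all genes equal;
    spike: one gene takes 99% of the mass, the rest share the remainder
    equally). Columns are renormalized to sum to 1e6.
    """
    rng = np.random.default_rng(design.seed)
    genes = [f"G{i:05d}" for i in range(1, design.n_genes + 1)]
    if design.n_genes >= len(Y_PANEL):
        genes[-len(Y_PANEL):] = list(Y_PANEL)
    y_idx = [i for i, g in enumerate(genes) if g in Y_PANEL]

    # Zipf baseline over a random rank assignment (Y genes handled separately)
    ranks = rng.permutation(design.n_genes) + 1
    base = 1.0 / ranks.astype(float) ** design.zipf_scale
    base *= 1e6 / base.sum()
    base[y_idx] = 0.0

    # planted modules: contiguous blocks of non-Y genes, assigned per spec
    module_membership: dict[str, str] = {}
    module_rows: dict[str, np.ndarray] = {}
    cursor = 0
    non_y = [i for i, g in enumerate(genes) if g not in Y_PANEL]
    for label, size, fold in design.module_spec:
        idx = np.array(non_y[cursor:cursor + size])
        cursor += size
        module_rows[label] = idx
        for i in idx:
            module_membership[genes[i]] = label
    folds = {label: fold for label, _, fold in design.module_spec}

    samples: list[str] = []
    descriptors: dict[str, dict[str, str]] = {}
    sex_assignment: dict[str, str] = {}
    cols: dict[str, np.ndarray] = {}
    run = 0
    for t_i, tissue in enumerate(design.tissues):
        for lib in range(design.libraries_per_tissue):
            run += 1
            sid = f"RUN{run:06d}"
            bioproject = f"PRJS{(lib % design.n_bioprojects) + 1:05d}"
            sex = "male" if rng.random() < design.sex_ratio else "female"
            breed = BREEDS[t_i % len(BREEDS)]
            col = base.copy()
            for label, idx in module_rows.items():
                if label == tissue:
                    col[idx] = col[idx] * folds[label]
            if sex == "male":
                col[y_idx] = design.y_panel_tpm
            col *= np.exp(design.noise_sigma * rng.standard_normal(col.size))
            if sex == "female":
                col[y_idx] = 0.0
            col *= 1e6 / col.sum()
            samples.append(sid)
            sex_assignment[sid] = sex
            descriptors[sid] = {"bioproject": bioproject, "tissue": tissue,
                                "breed": breed, "sex": sex}
            cols[sid] = col

    qc_flags = {sid: "clean" for sid in samples}
    n_corrupt = int(round(design.corrupt_fraction * len(samples)))
    for sid in rng.choice(samples, size=n_corrupt, replace=False):
        sid = str(sid)
        qc_flags[sid] = "corrupted"
        if design.corrupt_mode == "uniform":
            cols[sid] = np.full(design.n_genes, 1e6 / design.n_genes)
        else:  # spike
            col = np.full(design.n_genes, 0.01 * 1e6 / (design.n_genes - 1))
            col[int(rng.integers(design.n_genes))] = 0.99e6
            col *= 1e6 / col.sum()
            cols[sid] = col

    values = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    samples_df = pd.DataFrame.from_dict(descriptors, orient="index")
    matrix = ExpressionMatrix(values, samples_df)
    return GroundTruth(true_tpm=matrix, module_membership=module_membership,
                       sex_assignment=sex_assignment, qc_flags=qc_flags)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def simulate_reads(
    transcript_tpm: Mapping[str, float],
    transcriptome: Transcriptome,
    n_pairs: int,
    read_len: int = 100,
    frag_mean: float = 200.0,
    frag_sd: float = 20.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[ReadPair]:
    """Simulate error-free (by default) paired reads from true abundances.

    Fragments are drawn per transcript with probability proportional to
    TPM x effective length; fragment lengths are normal (truncated to
    [read_len, transcript length]); mate 1 is the fragment's 5' end, mate 2
    the reverse complement of its 3' end. Substitution errors are applied
    per base at *error_rate*.
    """
    if frag_mean < read_len:
        raise ValueError("frag_mean must be >= read_len")
    rng = np.random.default_rng(seed)
    recs = [r for r in transcriptome.records
            if transcript_tpm.get(r.transcript_id, 0.0) > 0]
    eff = effective_lengths({r.transcript_id: len(r.sequence) for r in recs},
                            frag_mean)
    weights = np.array([transcript_tpm[r.transcript_id] * eff[r.transcript_id]
                        for r in recs], dtype=float)
    if not recs or weights.sum() <= 0:
        raise ValueError("no expressed transcripts to simulate from")
    probs = weights / weights.sum()
    choice = rng.choice(len(recs), size=n_pairs, p=probs)
    frags = rng.normal(frag_mean, frag_sd, size=n_pairs)
    starts_u = rng.random(n_pairs)
    pairs = []
    qual = "I" * read_len
    for i in range(n_pairs):
        rec = recs[choice[i]]
        seq = rec.sequence
        flen = int(round(frags[i]))
        flen = max(read_len, min(flen, len(seq)))
        start = int(starts_u[i] * (len(seq) - flen + 1))
        frag = seq[start:start + flen]
        s1 = frag[:read_len]
        s2 = _revcomp(frag[-read_len:])
        if error_rate > 0:
            s1 = _mutate(s1, error_rate, rng)
            s2 = _mutate(s2, error_rate, rng)
        # read ids carry the transcript of origin, simulator-style
        pairs.append(ReadPair(f"read{i + 1}:{rec.transcript_id}", s1, qual, s2, qual))
    return pairs


def origin_counts(pairs: Sequence[ReadPair]) -> dict[str, int]:
    """Realized fragments per transcript, recovered from simulated read ids."""
    out: dict[str, int] = {}
    for p in pairs:
        tid = p.read_id.rsplit(":", 1)[1]
        out[tid] = out.get(tid, 0) + 1
    return out


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    for i in np.flatnonzero(rng.random(len(chars)) < rate):
        chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
    return "".join(chars)


@dataclass
class SyntheticMetadata:
    """RunInfo + key-value metadata with a record of every injected defect."""

    runinfo: pd.DataFrame
    metadata: pd.DataFrame  # columns run_accession, key, value
    truth: pd.DataFrame  # per-run ground truth + injected defect
    injected: dict[str, int] = field(default_factory=dict)


def simulate_metadata(design: AtlasDesign, truth: GroundTruth) -> SyntheticMetadata:
    """Emit RunInfo and key-value metadata tables for a simulated atlas.

    Every run is written with gate-passing technical fields and with
    tissue/sex/breed keys drawn from the observed spelling variants. With
    probability ``design.messiness`` a record receives one defect: its sex
    key is dropped, its tissue value is typo'd, or its layout is flipped to
    SINGLE (which the technical gate must reject). A ground-truth sidecar
    records the defect (if any) per run.
    """
    rng = np.random.default_rng(design.seed + 104729)
    matrix = truth.true_tpm
    runinfo_rows = []
    meta_rows = []
    truth_rows = []
    injected = {"drop_sex": 0, "typo_tissue": 0, "single_layout": 0}
    for sid in matrix.sample_ids:
        desc = matrix.samples.loc[sid]
        defect = ""
        if rng.random() < design.messiness:
            defect = str(rng.choice(["drop_sex", "typo_tissue", "single_layout"]))
            injected[defect] += 1
        layout = "SINGLE" if defect == "single_layout" else "PAIRED"
        runinfo_rows.append({
            "Run": sid, "Sample": sid.replace("RUN", "SAMN"),
            "BioProject": desc["bioproject"], "Platform": "ILLUMINA",
            "LibrarySource": "TRANSCRIPTOMIC", "LibraryStrategy": "RNA-Seq",
            "LibraryLayout": layout, "LibrarySelection": "cDNA",
            "avgLength": 200, "spots": 20_000_000,
        })
        tissue_value = str(desc["tissue"])
        if defect == "typo_tissue":
            i = int(rng.integers(len(tissue_value)))
            tissue_value = tissue_value[:i] + str(rng.choice(BASES)).lower() + tissue_value[i + 1:]
        tissue_key = str(rng.choice(TISSUE_KEYS))
        meta_rows.append((sid, tissue_key, tissue_value))
        if defect != "drop_sex":
            meta_rows.append((sid, str(rng.choice(SEX_KEYS)), str(desc["sex"])))
        meta_rows.append((sid, str(rng.choice(BREED_KEYS)), str(desc["breed"])))
        meta_rows.append((sid, str(rng.choice(AGE_KEYS)),
                          f"{int(rng.integers(4, 105))} weeks"))
        truth_rows.append({
            "run_accession": sid, "tissue": desc["tissue"],
            "breed": desc["breed"], "sex": truth.sex_assignment[sid],
            "bioproject": desc["bioproject"], "qc_flag": truth.qc_flags[sid],
            "defect": defect,
        })
    return SyntheticMetadata(
        runinfo=pd.DataFrame(runinfo_rows),
        metadata=pd.DataFrame(meta_rows, columns=["run_accession", "key", "value"]),
        truth=pd.DataFrame(truth_rows),
        injected=injected,
    )


def write_atlas_inputs(
    design: AtlasDesign,
    truth: GroundTruth,
    meta: SyntheticMetadata,
    out_dir: str | Path,
) -> None:
    """Write the generated tables in exactly the formats the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta.runinfo.to_csv(out / "runinfo.csv", index=False)
    meta.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
    meta.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    truth.true_tpm.write(out / "true_tpm.tsv", out / "samples.tsv")
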