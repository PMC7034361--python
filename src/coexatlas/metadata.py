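"""Selection and harmonization of public sequencing-run metadata.

Candidate libraries for an expression atlas are drawn from study-level
(BioProject) summaries and run-level ("RunInfo") tables. Runs are admitted
only when their technical fields match the atlas design — paired-end
Illumina poly(A)+/rRNA-depleted RNA-seq of sufficient length and depth —
and when their free-text sample metadata yields, at minimum, a tissue or
cell-type label. Key names in public metadata are inconsistent ("tissue",
"tissue_type", "organism part", ...), so descriptor extraction walks an
ordered list of observed spellings.

Everything here reads local files only; fetching from live archives is out
of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: NCBI taxonomy ids for Sus scrofa, S. s. domesticus and 11 recognized
#: subspecies; the default gate for study-level selection.
PIG_TAXONOMY_IDS: frozenset[int] = frozenset(
    {9823, 9825, 291050, 309913, 309914, 375578, 310260,
     310261, 375579, 415978, 490583, 1170810, 2485929}
)

#: Study-level data type admitted to the atlas (substring, case-insensitive).
TRANSCRIPTOME_DATA_TYPE = "transcriptome or gene expression"

#: Columns a RunInfo table must provide.
RUNINFO_COLUMNS = (
    "Run", "Sample", "BioProject", "Platform", "LibrarySource",
    "LibraryStrategy", "LibraryLayout", "LibrarySelection",
    "avgLength", "spots",
)

# Ordered key variants observed in public sample metadata. First non-empty
# hit wins; within each group an exact match is preferred over a
# case/underscore-insensitive one.
TISSUE_KEYS = ("tissue", "tissue type", "tissue_type",
               "organism part", "organism_part")
CELL_KEYS = ("cell type", "cell_type")
BREED_KEYS = ("breed", "breed name")
STRAIN_KEYS = ("strain",)
SEX_KEYS = ("sex", "Sex", "gender")
AGE_KEYS = ("age", "developmental stage", "developmental_stage",
            "stage", "Stage")


@dataclass(frozen=True)
class LibraryRecord:
    """One sequencing run as described by a RunInfo row plus its metadata."""

    run_accession: str
    sample_accession: str = ""
    bioproject: str = ""
    platform: str = ""
    library_source: str = ""
    library_strategy: str = ""
    library_layout: str = ""
    library_selection: str = ""
    avg_length: float = 0.0
    spots: int = 0
    metadata: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.run_accession:
            raise ValueError("run_accession must be non-empty")
        if self.avg_length < 0 or self.spots < 0:
            raise ValueError("avg_length and spots must be non-negative")


@dataclass(frozen=True)
class SampleDescriptor:
    """Harmonized sample annotation: tissue is mandatory, the rest optional."""

    tissue: str
    breed: str = "unknown"
    sex: str = "unknown"  # one of {male, female, unknown}
    age: str = "unknown"

    def __post_init__(self) -> None:
        if not self.tissue:
            raise ValueError("tissue must be non-empty")
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"invalid sex value: {self.sex!r}")


@dataclass
class GateReport:
    """Partition of gated runs into kept accessions and (accession, reason) rejections."""

    kept: list[str] = field(default_factory=list)
    rejected: list[tuple[str, str]] = field(default_factory=list)

    def reasons(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, reason in self.rejected:
            out[reason] = out.get(reason, 0) + 1
        return out


def _find_column(df: pd.DataFrame, tokens: Sequence[str]) -> str | None:
    """Locate a column whose normalized name contains every token."""
    for col in df.columns:
        name = str(col).lower().replace("_", " ").replace("-", " ")
        if all(tok in name for tok in tokens):
            return col
    return None


def parse_bioproject_summary(
    summary: pd.DataFrame,
    taxonomy_ids: Iterable[int] = PIG_TAXONOMY_IDS,
    data_type: str = TRANSCRIPTOME_DATA_TYPE,
) -> list[str]:
    """Select BioProject accessions by data type and taxonomy id.

    A row is admitted when its data-type field contains *data_type*
    (case-insensitive substring — species names in the source file are too
    inconsistently cased for exact matching) and its taxonomy id is in
    *taxonomy_ids*. Returns unique accessions in input order; malformed rows
    are skipped with a warning.
    """
    taxonomy_ids = {int(t) for t in taxonomy_ids}
    acc_col = _find_column(summary, ["accession"]) or _find_column(summary, ["project"])
    type_col = _find_column(summary, ["data", "type"])
    tax_col = _find_column(summary, ["tax"]) or _find_column(summary, ["organism", "id"])
    if acc_col is None or type_col is None or tax_col is None:
        raise ValueError(
            "summary table needs accession, data-type and taxonomy-id columns"
        )
    needle = data_type.lower()
    out: list[str] = []
    seen: set[str] = set()
    for _, row in summary.iterrows():
        try:
            dtype = str(row[type_col]).lower()
            taxid = int(row[tax_col])
            acc = str(row[acc_col])
        except (ValueError, TypeError):
            logger.warning("skipping malformed BioProject summary row: %r", dict(row))
            continue
        if needle in dtype and taxid in taxonomy_ids and acc not in seen:
            seen.add(acc)
            out.append(acc)
    return out


def read_runinfo(path: str | Path) -> list[LibraryRecord]:
    """Read a RunInfo-style CSV into :class:`LibraryRecord` objects."""
    return records_from_runinfo(pd.read_csv(path, dtype=str))


def records_from_runinfo(df: pd.DataFrame) -> list[LibraryRecord]:
    """Convert a RunInfo-style table into :class:`LibraryRecord` objects.

    Missing fields become empty strings / zeros so the gate can reject them
    with reason ``missing_field`` rather than aborting the whole table.
    """
    df = df.fillna("").astype(str)
    records = []
    for _, row in df.iterrows():
        run = str(row.get("Run", "")).strip()
        if not run:
            logger.warning("RunInfo row without Run accession skipped")
            continue
        try:
            avg_length = float(row.get("avgLength", "") or 0)
        except ValueError:
            avg_length = 0.0
        try:
            spots = int(float(row.get("spots", "") or 0))
        except ValueError:
            spots = 0
        records.append(LibraryRecord(
            run_accession=run,
            sample_accession=str(row.get("Sample", "")),
            bioproject=str(row.get("BioProject", "")),
            platform=str(row.get("Platform", "")),
            library_source=str(row.get("LibrarySource", "")),
            library_strategy=str(row.get("LibraryStrategy", "")),
            library_layout=str(row.get("LibraryLayout", "")),
            library_selection=str(row.get("LibrarySelection", "")),
            avg_length=avg_length,
            spots=spots,
        ))
    return records


def _squash(value: str) -> str:
    return value.strip().lower().replace("-", "").replace("_", "").replace(" ", "")


def _first_failure(
    rec: LibraryRecord, min_avg_length: float, min_spots: int
) -> str | None:
    """Reason code for the first failing gate, or None if the run passes."""
    required = (rec.platform, rec.library_source, rec.library_strategy,
                rec.library_layout, rec.library_selection)
    if any(not f for f in required):
        return "missing_field"
    if rec.platform.strip().upper() != "ILLUMINA":
        return "platform"
    if rec.library_source.strip().upper() != "TRANSCRIPTOMIC":
        return "source"
    # SRA writes "RNA-Seq"; some summaries write "RNAseq".
    if _squash(rec.library_strategy) != "rnaseq":
        return "strategy"
    if rec.library_layout.strip().upper() != "PAIRED":
        return "layout"
    if _squash(rec.library_selection) not in ("cdna", "inverserrna"):
        return "selection"
    if rec.avg_length < min_avg_length:
        return "avg_length"
    if rec.spots < min_spots:
        return "spots"
    return None


def gate_runinfo(
    records: Sequence[LibraryRecord],
    min_avg_length: float = 100.0,
    min_spots: int = 10_000_000,
) -> GateReport:
    """Apply the technical inclusion gate to a set of runs.

    Kept runs are paired-end Illumina transcriptomic RNA-seq with cDNA or
    rRNA-depletion selection, average read length >= *min_avg_length* bp and
    >= *min_spots* read pairs. Each rejection carries the first failing
    reason code; the kept/rejected lists partition the input.
    """
    report = GateReport()
    for rec in records:
        reason = _first_failure(rec, min_avg_length, min_spots)
        if reason is None:
            report.kept.append(rec.run_accession)
        else:
            report.rejected.append((rec.run_accession, reason))
    return report


def _lookup(metadata: Sequence[tuple[str, str]], keys: Sequence[str]) -> str:
    """First non-empty value for a key list: exact match beats relaxed match.

    Relaxed matching is case-insensitive with spaces and underscores
    interchangeable, over the same spellings.
    """
    for key in keys:
        for k, v in metadata:
            if k == key and v.strip():
                return v.strip()
    wanted = {_relax(key) for key in keys}
    for k, v in metadata:
        if _relax(k) in wanted and v.strip():
            return v.strip()
    return ""


def _relax(key: str) -> str:
    return key.strip().lower().replace("_", " ")


def normalize_sex(value: str) -> str:
    v = value.strip().lower()
    if v in ("m", "male"):
        return "male"
    if v in ("f", "female"):
        return "female"
    return "unknown"


def extract_descriptor(
    metadata: Sequence[tuple[str, str]],
) -> SampleDescriptor | None:
    """Harmonize free-text metadata into a :class:`SampleDescriptor`.

    Tissue comes from the tissue-key variants, else the cell-type variants;
    a sample with neither is unusable for an atlas and returns ``None``.
    Breed falls back to strain; sex values are normalized to
    male/female/unknown.
    """
    tissue = _lookup(metadata, TISSUE_KEYS) or _lookup(metadata, CELL_KEYS)
    if not tissue:
        return None
    breed = _lookup(metadata, BREED_KEYS) or _lookup(metadata, STRAIN_KEYS) or "unknown"
    sex_raw = _lookup(metadata, SEX_KEYS)
    age = _lookup(metadata, AGE_KEYS) or "unknown"
    return SampleDescriptor(
        tissue=tissue,
        breed=breed,
        sex=normalize_sex(sex_raw) if sex_raw else "unknown",
        age=age,
    )


def read_metadata_table(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    """Read a flattened (run_accession, key, value) TSV into per-run key-value lists."""
    df = pd.read_csv(path, sep="\t", dtype=str,
                     names=["run_accession", "key", "value"], header=0).fillna("")
    out: dict[str, list[tuple[str, str]]] = {}
    for run, key, value in df.itertuples(index=False):
        out.setdefault(run, []).append((key, value))
    return out


def harvest(
    records: Sequence[LibraryRecord],
    metadata: Mapping[str, Sequence[tuple[str, str]]],
    min_avg_length: float = 100.0,
    min_spots: int = 10_000_000,
) -> tuple[dict[str, SampleDescriptor], GateReport]:
    """Full selection step: technical gate, then descriptor extraction.

    Runs passing the technical gate but lacking a tissue/cell-type key are
    moved to the rejection list with reason ``no_tissue``. Returns the
    descriptors of the surviving runs and the combined gate report.
    """
    report = gate_runinfo(records, min_avg_length, min_spots)
    descriptors: dict[str, SampleDescriptor] = {}
    still_kept: list[str] = []
    for run in report.kept:
        desc = extract_descriptor(list(metadata.get(run, [])))
        if desc is None:
            report.rejected.append((run, "no_tissue"))
        else:
            descriptors[run] = desc
            still_kept.append(run)
    report.kept = still_kept
    return descriptors, report


def write_harvest(
    descriptors: Mapping[str, SampleDescriptor],
    report: GateReport,
    out_dir: str | Path,
) -> None:
    """Write the kept-library descriptor TSV and the rejection log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kept = pd.DataFrame(
        [(run, d.tissue, d.breed, d.sex, d.age)
         for run, d in descriptors.items()],
        columns=["run_accession", "tissue", "breed", "sex", "age"],
    )
    kept.to_csv(out / "kept_libraries.tsv", sep="\t", index=False)
    rej = pd.DataFrame(report.rejected, columns=["run_accession", "reason"])
    rej.to_csv(out / "rejected_libraries.tsv", sep="\t", index=False)
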