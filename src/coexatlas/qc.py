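"""Library quality control, group averaging and sex inference.

A well-prepared bulk RNA-seq library has a heavy-tailed abundance
distribution: a minority of genes produce the majority of reads, to a good
approximation following Zipf's law (abundance inversely proportional to
rank). The QC statistic is the slope of the log-log reverse cumulative
curve — the number of genes expressed at or above each TPM level against
that level — which is -1 for ideal Zipf data. Libraries whose fitted
exponent deviates from -1 by more than 20% (|slope + 1| > 0.2), or cannot
be fitted at all, are excluded.

After QC, libraries are averaged by (BioProject, tissue, breed, sex) so
each atlas column represents the biological replicates of one tissue from
one study, sex and breed. Sample sex missing from metadata is inferred from
a panel of Y-chromosome genes that are robustly expressed in males and
undetectable in females.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import DESCRIPTOR_COLUMNS, ExpressionMatrix, normalize_tissue

#: Y-chromosome male-marker panel (gene symbols).
Y_PANEL = ("EIF1AY", "EIF2S3Y", "DDX3Y", "KDM5D", "TXLNGY", "USP9Y", "UTY", "ZFY")

ZIPF_OPTIMUM = -1.0
ZIPF_MAX_DEVIATION = 0.2
MIN_POSITIVE_GENES = 100


@dataclass(frozen=True)
class ZipfQCResult:
    sample_id: str
    exponent: float
    deviation: float
    passed: bool


@dataclass(frozen=True)
class SexCall:
    sample_id: str
    call: str  # male / female / unknown
    panel_detected: int


def zipf_exponent(gene_tpm: np.ndarray | pd.Series, method: str = "ccdf") -> float:
    """Fitted power-law exponent of a library's abundance distribution.

    ``method="ccdf"`` (default): ordinary least-squares slope of
    log10(#genes with TPM >= t) on log10(t) over the distinct positive TPM
    values t — the reverse cumulative curve. ``method="rank"``: slope of
    log10(TPM) on log10(rank), the rank-abundance alternative. Both equal
    -1 for ideal Zipf data.

    Returns NaN when fewer than 100 genes are positive or the fit is
    degenerate (zero variance); NaN fails the QC gate downstream.
    """
    tpm = np.asarray(gene_tpm, dtype=float)
    pos = np.sort(tpm[tpm > 0])
    if pos.size < MIN_POSITIVE_GENES:
        return float("nan")
    if method == "ccdf":
        t = np.unique(pos)
        # genes with TPM >= t, via position of t in the sorted vector
        n_ge = pos.size - np.searchsorted(pos, t, side="left")
        x = np.log10(t)
        y = np.log10(n_ge)
    elif method == "rank":
        ranks = np.arange(1, pos.size + 1)
        x = np.log10(ranks)
        y = np.log10(pos[::-1])
    else:
        raise ValueError(f"unknown method {method!r}")
    if np.ptp(x) == 0:
        return float("nan")
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)


def qc_gate(exponent: float, sample_id: str = "") -> ZipfQCResult:
    """Pass iff the exponent is finite and within 20% of the Zipf optimum -1."""
    deviation = abs(exponent - ZIPF_OPTIMUM)
    passed = bool(np.isfinite(exponent) and deviation <= ZIPF_MAX_DEVIATION)
    return ZipfQCResult(sample_id=sample_id, exponent=float(exponent),
                        deviation=float(deviation), passed=passed)


def qc_matrix(matrix: ExpressionMatrix, method: str = "ccdf") -> pd.DataFrame:
    """Per-sample Zipf QC report: (sample_id, exponent, deviation, passed)."""
    rows = []
    for sid in matrix.sample_ids:
        res = qc_gate(zipf_exponent(matrix.values[sid], method=method), sid)
        rows.append((res.sample_id, res.exponent, res.deviation, res.passed))
    return pd.DataFrame(rows, columns=["sample_id", "exponent", "deviation", "passed"])


def expression_filter(
    matrix: ExpressionMatrix, min_tpm: float, min_samples: int = 1
) -> ExpressionMatrix:
    """Keep genes with TPM >= min_tpm in at least min_samples columns (inclusive)."""
    if min_tpm <= 0:
        raise ValueError("min_tpm must be positive")
    mask = (matrix.values >= min_tpm).sum(axis=1) >= min_samples
    return ExpressionMatrix(matrix.values.loc[mask], matrix.samples.copy())


def aggregate(
    matrix: ExpressionMatrix,
    group_key: Sequence[str] = DESCRIPTOR_COLUMNS,
) -> ExpressionMatrix:
    """Average columns by (BioProject, tissue, breed, sex).

    Tissue labels are normalized (lowercase, trimmed, whitespace collapsed)
    before grouping. Each output column is the arithmetic mean of its member
    libraries, labelled by the joined key; column order follows first
    appearance of each key in the input.
    """
    desc = matrix.samples.copy()
    if "tissue" in desc.columns:
        desc["tissue"] = desc["tissue"].map(normalize_tissue)
    keys = [tuple(desc.loc[sid, k] for k in group_key) for sid in matrix.sample_ids]
    order: list[tuple] = []
    members: dict[tuple, list[str]] = {}
    for sid, key in zip(matrix.sample_ids, keys):
        if key not in members:
            members[key] = []
            order.append(key)
        members[key].append(sid)
    columns = {}
    descriptors = {}
    for key in order:
        sid_group = members[key]
        label = "|".join(str(p) for p in key)
        columns[label] = matrix.values[sid_group].mean(axis=1)
        descriptors[label] = dict(zip(group_key, (str(p) for p in key)))
    return ExpressionMatrix.from_columns(columns, descriptors)


def infer_sex(
    matrix: ExpressionMatrix,
    y_panel: Sequence[str] = Y_PANEL,
    min_genes: int = 3,
    min_tpm: float = 1.0,
) -> list[SexCall]:
    """Call sample sex from Y-chromosome marker expression.

    A sample is called male when at least *min_genes* of the panel genes
    present in the matrix reach *min_tpm*; female when every present panel
    gene is below *min_tpm*; otherwise unknown. Raises when no panel gene is
    in the matrix.
    """
    present = [g for g in y_panel if g in matrix.values.index]
    if not present:
        raise ValueError("no Y-panel gene present in the matrix")
    sub = matrix.values.loc[present]
    calls = []
    for sid in matrix.sample_ids:
        detected = int((sub[sid] >= min_tpm).sum())
        if detected >= min_genes:
            call = "male"
        elif detected == 0:
            call = "female"
        else:
            call = "unknown"
        calls.append(SexCall(sample_id=sid, call=call, panel_detected=detected))
    return calls


def fill_unknown_sex(
    matrix: ExpressionMatrix, calls: Sequence[SexCall]
) -> ExpressionMatrix:
    """Fill in inferred sex where metadata says unknown.

    Metadata-recorded sex (including mixed/pooled annotations) is never
    overwritten; inference only replaces "unknown".
    """
    samples = matrix.samples.copy()
    by_id = {c.sample_id: c.call for c in calls}
    for sid in samples.index:
        if samples.loc[sid, "sex"] in ("unknown", "", None):
            samples.loc[sid, "sex"] = by_id.get(sid, "unknown")
    return ExpressionMatrix(matrix.values.copy(), samples)
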