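"""Genes-by-samples TPM matrices with per-sample descriptors.

The atlas object is a non-negative TPM matrix whose columns carry a sample
descriptor (BioProject, tissue, breed, sex). It serializes as a plain TSV
matrix plus a sidecar descriptor TSV so external tools can consume it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DESCRIPTOR_COLUMNS = ("bioproject", "tissue", "breed", "sex")


def normalize_tissue(label: str) -> str:
    """Lowercase, trim, and collapse internal whitespace (no ontology mapping)."""
    return " ".join(str(label).strip().lower().split())


@dataclass
class ExpressionMatrix:
    """TPM values (genes x samples) plus per-sample descriptors.

    ``values``: DataFrame indexed by gene_id, columns are sample_ids.
    ``samples``: DataFrame indexed by sample_id with columns
    (bioproject, tissue, breed, sex), aligned with ``values.columns``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.samples is None:
            self.samples = pd.DataFrame(
                {c: "unknown" for c in DESCRIPTOR_COLUMNS},
                index=self.values.columns,
            )
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene_ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample_ids")
        if not self.values.columns.equals(self.samples.index):
            self.samples = self.samples.reindex(self.values.columns)
            if self.samples.isna().any().any():
                raise ValueError("samples table does not cover all matrix columns")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.samples.copy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(self.values[ids], self.samples.loc[ids])

    def write(self, matrix_path: str | Path, samples_path: str | Path) -> None:
        self.values.rename_axis("gene_id").to_csv(matrix_path, sep="\t")
        self.samples.rename_axis("sample_id").to_csv(samples_path, sep="\t")

    @classmethod
    def read(
        cls, matrix_path: str | Path, samples_path: str | Path | None = None
    ) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        samples = None
        if samples_path is not None:
            samples = pd.read_csv(samples_path, sep="\t", index_col=0, dtype=str)
        return cls(values, samples)

    @classmethod
    def from_columns(
        cls,
        columns: Mapping[str, pd.Series],
        descriptors: Mapping[str, Mapping[str, str]] | None = None,
    ) -> "ExpressionMatrix":
        """Assemble from per-sample gene vectors and optional descriptor dicts."""
        values = pd.DataFrame(dict(columns))
        samples = None
        if descriptors is not None:
            samples = pd.DataFrame.from_dict(dict(descriptors), orient="index")
            for col in DESCRIPTOR_COLUMNS:
                if col not in samples.columns:
                    samples[col] = "unknown"
            samples = samples[list(DESCRIPTOR_COLUMNS)]
        return cls(values, samples)
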