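import numpy as np
import pytest

from coexatlas import AtlasDesign, LibraryRecord, simulate_expression


def make_record(**overrides) -> LibraryRecord:
    """A gate-passing library record; override fields to trigger rejections."""
    base = dict(
        run_accession="SRR0000001",
        sample_accession="SAMN0000001",
        bioproject="PRJNA00001",
        platform="ILLUMINA",
        library_source="TRANSCRIPTOMIC",
        library_strategy="RNA-Seq",
        library_layout="PAIRED",
        library_selection="cDNA",
        avg_length=150.0,
        spots=20_000_000,
    )
    base.update(overrides)
    return LibraryRecord(**base)


@pytest.fixture(scope="session")
def default_truth():
    """Ground truth for the default synthetic design (fixed seed)."""
    return simulate_expression(AtlasDesign(seed=42))


@pytest.fixture(scope="session")
def recovery_truth():
    """A 500-gene, 40-sample, uncorrupted design for module-recovery tests."""
    design = AtlasDesign(n_genes=500, n_tissues=8, libraries_per_tissue=5,
                         corrupt_fraction=0.0, seed=3)
    return simulate_expression(design)


def zipf_vector(n: int = 10_000, exponent: float = 1.0) -> np.ndarray:
    """Ideal rank-law TPM vector: TPM_r proportional to 1/r**exponent, summing to 1e6."""
    ranks = np.arange(1, n + 1, dtype=float)
    v = ranks ** -exponent
    return 1e6 * v / v.sum()
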