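import numpy as np
import pandas as pd
import pytest

from lncscape.gene_model import GeneRecord
from lncscape.synthetic_data import CohortConfig, generate_annotation, generate_cohort, generate_peaks


def random_genes(rng, n=10, chroms=("c1", "c2"), span=20_000, lnc_fraction=0.5):
    """Random small gene set for oracle tests (may overlap heavily)."""
    genes = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span))
        exons = []
        pos = start
        for _ in range(int(rng.integers(1, 4))):
            length = int(rng.integers(50, 300))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(20, 400))
        biotype = "lincRNA" if rng.random() < lnc_fraction else "protein_coding"
        genes.append(
            GeneRecord(f"G{i:03d}", f"G{i:03d}", biotype, chrom,
                       "+" if rng.random() < 0.5 else "-", exons)
        )
    return genes


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort, generated once per test session."""
    cfg = CohortConfig(seed=11)
    genes, ann = generate_annotation(cfg)
    counts, clinical, truth = generate_cohort(cfg, genes, ann)
    return cfg, genes, ann, counts, clinical, truth


@pytest.fixture(scope="session")
def default_peaks(default_cohort):
    cfg, genes, ann, counts, clinical, truth = default_cohort
    peaks, status = generate_peaks(cfg, genes, truth)
    return peaks, status


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
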