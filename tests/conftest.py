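import numpy as np
import pytest

from exlnc.genome_io import (BIOTYPE_CODING, BIOTYPE_LNCRNA, GeneModel,
                             GenomicInterval, Peak)
from exlnc.synthetic_data import SynthConfig, generate_dataset


def make_gene(gene_id, chrom, start, end, strand="+", biotype=BIOTYPE_LNCRNA):
    return GeneModel(gene_id, biotype, GenomicInterval(chrom, start, end,
                                                       strand))


def make_peak(peak_id, chrom, start, end, summit=None):
    return Peak(peak_id, GenomicInterval(chrom, start, end),
                (start + end) // 2 if summit is None else summit)


@pytest.fixture(scope="session")
def small_dataset():
    """One seeded synthetic cohort shared across read-only tests."""
    cfg = SynthConfig(n_lnc=60, n_coding=120, n_peaks=300, n_tissues=2,
                      seed=42)
    return generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
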