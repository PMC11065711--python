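import numpy as np
import pytest
from hypothesis import settings

from popne.io import GenotypeDataset, VariantRecord

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_dataset(calls, positions=None, chrom="1", alleles=("A", "G")):
    """Build a GenotypeDataset from a samples x variants dosage list."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if positions is None:
        positions = [1000 * (j + 1) for j in range(m)]
    chroms = [chrom] * m if isinstance(chrom, str) else chrom
    variants = [VariantRecord(chroms[j], f"snp{j + 1}", int(positions[j]), alleles)
                for j in range(m)]
    return GenotypeDataset(variants=variants,
                           samples=[f"s{i + 1}" for i in range(n)],
                           calls=calls)


@pytest.fixture
def toy_dataset():
    """3 samples x 2 SNPs, no missing data."""
    return make_dataset([[0, 1], [1, 2], [2, 0]])


@pytest.fixture
def rng():
    return np.random.default_rng(20250917)
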