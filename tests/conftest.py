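import numpy as np
import pytest

from epiensemble.data import SNP, GenotypeMatrix, PhenotypeLabels


def make_matrix(values, kinds=None, ids=None, missing=None):
    values = np.asarray(values)
    n = values.shape[1]
    return GenotypeMatrix(
        factor_ids=ids or [f"snp{j + 1}" for j in range(n)],
        factor_kinds=kinds or [SNP] * n,
        values=values,
        missing_mask=missing,
    )


@pytest.fixture(scope="session")
def xor_dataset():
    """200 x 20 noiseless dataset whose labels are an XOR of two SNPs.

    Case if exactly one of snp6/snp13 is heterozygous; all other columns are
    independent noise, so {snp6, snp13} classifies perfectly and nothing
    else does.
    """
    rng = np.random.default_rng(42)
    values = rng.integers(0, 3, size=(200, 20)).astype(np.int16)
    a, b = values[:, 5] == 1, values[:, 12] == 1
    labels = (a ^ b).astype(np.int8)
    # guarantee both classes
    labels[0], labels[1] = 0, 1
    values[0, 5], values[0, 12] = 0, 0
    values[1, 5], values[1, 12] = 1, 0
    gm = make_matrix(values)
    return gm, PhenotypeLabels(labels), ("snp13", "snp6")


@pytest.fixture
def nine_cell_grid():
    """All 9 two-locus genotype combinations, one sample each."""
    x = np.array([[a, b] for a in range(3) for b in range(3)], dtype=np.int16)
    return x
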