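import numpy as np
import pytest

from popsep.genotypes import MISSING, GenotypeMatrix, LabelSet, SNPRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(dosages, sample_ids=None, missing=None):
    """Build a GenotypeMatrix from a plain array (helper, not a fixture)."""
    d = np.asarray(dosages, dtype=np.int8)
    m, n = d.shape
    if missing is not None:
        d = d.copy()
        for i, j in missing:
            d[i, j] = MISSING
    ids = sample_ids or [f"s{i}" for i in range(m)]
    snps = [
        SNPRecord(f"rs{j}", "1", j + 1, allele_a="A", allele_b="B") for j in range(n)
    ]
    return GenotypeMatrix(ids, snps, d)


def two_class_labels(gm, n_first):
    return LabelSet(
        {s: (0 if i < n_first else 1) for i, s in enumerate(gm.sample_ids)},
        class_names=("g0", "g1"),
    )
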