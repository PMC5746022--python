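import numpy as np
import pytest

from herdimpute.genodata import GenotypeMatrix, Site


def make_sites(n, chrom="1", start=100, step=100):
    return [Site(chrom=chrom, pos=start + i * step, ref_allele="A", alt_allele="G")
            for i in range(n)]


def make_gm(dosage, chrom="1", sample_prefix="s", breeds=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    return GenotypeMatrix(
        sample_ids=[f"{sample_prefix}{i}" for i in range(n)],
        sites=make_sites(m, chrom=chrom),
        dosage=dosage,
        breeds=breeds,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_gm(rng, n=10, m=20, missing_rate=0.0):
    d = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    if missing_rate:
        d[rng.random((n, m)) < missing_rate] = -1
    return make_gm(d)
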