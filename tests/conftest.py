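import numpy as np
import pandas as pd
import pytest

from snpepi import io as sio
from snpepi.containers import GenotypeMatrix, MarkerMap


@pytest.fixture(scope="session")
def afw_pairs():
    """The packaged 52-row significant-pair table."""
    return sio.load_afw_pairs()


@pytest.fixture(scope="session")
def subnet_a_markers():
    """Synthetic marker positions for the radial subnet's SNPs."""
    return MarkerMap(pd.read_csv(
        sio.fixture_path("subnet_a_positions.synthetic.tsv"), sep="\t",
        dtype={"chrom": str}))


def random_genotypes(rng, n, maf, three_classes=True):
    """Genotype vector under HWE; optionally resample until 3 classes."""
    q = maf
    probs = [(1 - q) ** 2, 2 * q * (1 - q), q * q]
    for _ in range(100):
        g = rng.choice(3, size=n, p=probs).astype(float)
        if not three_classes or np.unique(g).size == 3:
            return g
    raise RuntimeError("could not draw a 3-class genotype vector")


def make_matrix(codes, chrom="1", start_pos=1000, gap=10_000, ids=None):
    """Wrap a codes array in a GenotypeMatrix with a simple map."""
    codes = np.asarray(codes, dtype=float)
    m = codes.shape[1]
    markers = MarkerMap(pd.DataFrame({
        "snp": [f"s{k+1}" for k in range(m)],
        "chrom": [chrom] * m,
        "pos": [start_pos + k * gap for k in range(m)],
    }))
    return GenotypeMatrix(codes, markers, ids)
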