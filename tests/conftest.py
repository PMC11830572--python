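import numpy as np
import pandas as pd
import pytest

from portal5hmc.io import CountMatrix, GeneModel, GenomicRegion


@pytest.fixture
def toy_genes():
    """Two genes on chr1 (one per strand) and one on chr2."""
    return [
        GeneModel("chr1", 10_000, 20_000, "alpha", "+",
                  ((10_000, 11_000), (14_000, 15_000), (19_000, 20_000))),
        GeneModel("chr1", 40_000, 50_000, "beta", "-",
                  ((40_000, 42_000), (48_000, 50_000))),
        GeneModel("chr2", 5_000, 9_000, "gamma", "+", ((5_000, 9_000),)),
    ]


@pytest.fixture
def small_counts():
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.poisson(50, size=(50, 6)),
        index=pd.Index([f"hmr_{i:06d}" for i in range(50)], name="region"),
        columns=[f"PC_{i+1:03d}" for i in range(3)] + [f"MLM_{i+1:03d}" for i in range(3)],
    )
    return CountMatrix(counts, counts.sum(axis=0).astype(np.int64))


def make_region(chrom="chr1", start=0, end=100, name="r", strand="."):
    return GenomicRegion(chrom, start, end, name, 0.0, strand)
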