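import numpy as np
import pandas as pd
import pytest

from methgwas.core import GenomeLayout, GenomicInterval, MethylomeSample


@pytest.fixture
def layout():
    return GenomeLayout(("chr1", "chr2"), (1_000_000, 800_000))


@pytest.fixture
def tiny_layout():
    return GenomeLayout(("chr1",), (10_000,))


def make_sample(layout, rows, sample_id="s1", **groups):
    """rows: iterable of (chrom, pos0, n_meth, n_total)."""
    calls = pd.DataFrame(rows, columns=["chrom", "pos", "n_meth", "n_total"])
    return MethylomeSample(sample_id, calls, layout, **groups)


@pytest.fixture
def make_sample_factory():
    return make_sample


def toy_gwas(t_values, chrom="chr1", trait="t"):
    """GWAS frame with b = t, se = 1 at 0-based positions 0..n-1."""
    t = np.asarray(t_values, dtype=float)
    df = pd.DataFrame(
        {
            "trait": trait,
            "chrom": chrom,
            "pos": np.arange(len(t), dtype=np.int64),
            "b": t,
            "se": 1.0,
        }
    )
    df["t2"] = (df["b"] / df["se"]) ** 2
    return df
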