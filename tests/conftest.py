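import numpy as np
import pandas as pd
import pytest

from hexasense.core import ContactMatrix, GenomeBinning, QuantTable


@pytest.fixture
def small_binning():
    return GenomeBinning({"chr1": 1000}, 100)


@pytest.fixture
def quant_table():
    """3 proteins x 4 samples with one missing cell."""
    data = pd.DataFrame(
        {
            "c1": [2.0, 3.0, 5.0],
            "c2": [4.0, 6.0, 10.0],
            "t1": [1.0, np.nan, 5.0],
            "t2": [2.0, 3.0, 10.0],
        },
        index=["A", "B", "C"],
    )
    cond = pd.Series(
        ["control", "control", "treated", "treated"], index=data.columns
    )
    batch = pd.Series(["b1", "b2", "b1", "b2"], index=data.columns)
    return QuantTable(data, cond, batch, kind="iBAQ")


def dense_matrix(dense, chrom="chr1", res=1):
    dense = np.asarray(dense, dtype=float)
    binning = GenomeBinning({chrom: dense.shape[0] * res}, res)
    return ContactMatrix.from_dense(chrom, binning, dense)
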