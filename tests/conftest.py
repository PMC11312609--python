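import numpy as np
import pandas as pd
import pytest

from trapseq.io import GeneCountMatrix


def make_metadata(rows):
    """rows: list of (sample_id, fraction, condition, genotype)."""
    df = pd.DataFrame(rows, columns=["sample_id", "fraction", "condition", "genotype"])
    return df.set_index("sample_id")


@pytest.fixture
def small_gcm():
    """4 genes x 4 samples, ribosomal/total x LDF/contralateral, WT."""
    meta = make_metadata(
        [
            ("r_ldf", "ribosomal", "LDF", "WT"),
            ("r_con", "ribosomal", "contralateral", "WT"),
            ("t_ldf", "total", "LDF", "WT"),
            ("t_con", "total", "contralateral", "WT"),
        ]
    )
    counts = pd.DataFrame(
        [[100, 50, 80, 40], [10, 10, 10, 10], [0, 5, 3, 2], [400, 400, 100, 100]],
        index=pd.Index(["gA", "gB", "gC", "gD"], name="gene_id"),
        columns=meta.index,
    )
    lengths = pd.Series([1000, 2000, 500, 1000], index=counts.index, name="length")
    return GeneCountMatrix(counts=counts, samples=meta, gene_lengths=lengths)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
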