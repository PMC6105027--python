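import numpy as np
import pandas as pd
import pytest

from ssrkit.popgen import GenotypeTable
from ssrkit.seqio import SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def tiny_genotypes() -> GenotypeTable:
    """Three accessions x two loci, hand-written, no missing data."""
    df = pd.DataFrame(
        {
            "L1": [("150", "150"), ("150", "156"), ("156", "156")],
            "L2": [("200", "203"), ("200", "203"), ("200", "200")],
        },
        index=["x", "y", "z"],
        dtype=object,
    )
    return GenotypeTable(df)


def random_record(rng, length: int, rec_id: str = "r") -> SequenceRecord:
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return SequenceRecord(rec_id, seq)
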