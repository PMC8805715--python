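import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def chrom_sizes():
    return {"chrI": 1_000_000, "chrII": 800_000}


def make_pair(chrom1, pos1, chrom2, pos2, strand1="+", strand2="-",
              mapq1=60, mapq2=60, nm1=0, nm2=0, read_id="r"):
    return {
        "read_id": read_id,
        "chrom1": chrom1, "pos1": pos1, "strand1": strand1, "mapq1": mapq1, "nm1": nm1,
        "chrom2": chrom2, "pos2": pos2, "strand2": strand2, "mapq2": mapq2, "nm2": nm2,
    }


@pytest.fixture
def pair_factory():
    return make_pair


def pairs_frame(rows):
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
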