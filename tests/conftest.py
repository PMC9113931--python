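import numpy as np
import pytest

from ashmscan.io_core import VariantRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genome():
    """Small fixed genome with known AID contexts and a codon playground."""
    #            0         1         2         3
    #            0123456789012345678901234567890123456789
    seq = "GGGGAACTGGGGAGCAGGGGATGGAGGCGTAAGGGGGGGG"
    return {"chrT": seq}


def make_variant(pos, ref, alt, sample="S1", chrom="chrT", **kw):
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, sample_id=sample, **kw)
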