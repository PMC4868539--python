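import numpy as np
import pytest

from polfid.iomodel import AlignedRead
from polfid.simulate import SimConfig, simulate


def make_read(seq, pos=0, chrom="chr1", quals=40, cigar=None, read_id="r1",
              mapq=60, n_mismatches=0, is_reverse=False, is_duplicate=False):
    """Build an AlignedRead with uniform qualities unless given."""
    if isinstance(quals, int):
        quals = np.full(len(seq), quals, dtype=np.uint8)
    else:
        quals = np.asarray(quals, dtype=np.uint8)
    if cigar is None:
        cigar = [("M", len(seq))]
    return AlignedRead(read_id=read_id, chrom=chrom, pos=pos, cigar=cigar,
                       seq=seq, quals=quals, mapq=mapq,
                       n_mismatches=n_mismatches, is_duplicate=is_duplicate,
                       is_reverse=is_reverse)


@pytest.fixture(scope="session")
def small_sim():
    """A moderate simulation with the default error regime, shared by
    read-level tests."""
    cfg = SimConfig(seed=11, n_genes=8, coverage_target=25,
                    polymerase_error_rate=1e-4)
    return simulate(cfg)


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free simulation: reads are exact copies of the reference."""
    cfg = SimConfig(seed=12, n_genes=6, coverage_target=15,
                    polymerase_error_rate=0.0, sequencing_error_rate=0.0,
                    low_quality_fraction=0.0)
    return simulate(cfg)
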