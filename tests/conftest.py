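import numpy as np
import pytest
from hypothesis import settings

from lsimpute.model import HMMParameters

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from lsimpute.panel_io import ReferencePanel


def panel_from_haplotypes(haplotypes, chrom="20", spacing=1000):
    """Wrap a raw (H, M) allele matrix in a ReferencePanel."""
    hap = np.asarray(haplotypes, dtype=np.uint8)
    M = hap.shape[1]
    return ReferencePanel(
        chrom=chrom,
        positions=10_001 + spacing * np.arange(M, dtype=np.int64),
        ref_alleles=np.array(["A"] * M),
        alt_alleles=np.array(["C"] * M),
        haplotypes=hap,
    )


def params_for(hap, theta, epsilon):
    hap = np.asarray(hap)
    return HMMParameters(
        n_haplotypes=hap.shape[0],
        theta=np.atleast_1d(np.asarray(theta, dtype=float)),
        epsilon=np.broadcast_to(np.asarray(epsilon, dtype=float), (hap.shape[1],)).copy(),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20220)
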