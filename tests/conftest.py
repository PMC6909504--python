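import numpy as np
import pytest

from allelichrom import simulate
from allelichrom.genome import GenomicInterval, RestrictionFragmentMap


@pytest.fixture
def rng():
    return np.random.default_rng(20231207)


@pytest.fixture
def domain_spec():
    return simulate.default_domain_spec()


@pytest.fixture
def small_fragment_map():
    # 10-kb toy chromosome, irregular DpnII-like fragments
    boundaries = np.array(
        [0, 350, 900, 1300, 2100, 2550, 3300, 4100, 4600, 5500, 6200, 7000, 8100, 9000, 10_000]
    )
    return RestrictionFragmentMap("chrT", boundaries, enzyme_name="test")


@pytest.fixture
def whole_window(domain_spec):
    from allelichrom.fourc import NormalizationWindow

    return NormalizationWindow(
        GenomicInterval(domain_spec.chrom, 0, domain_spec.chrom_length)
    )
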