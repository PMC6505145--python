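import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tgarray.align import TargetRegistry, align_reads, index_targets
from tgarray.simulate import (ReadSimParams, make_locus, random_seq,
                              random_unit, simulate_reads)

settings.register_profile(
    "suite", derandomize=True, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")

UNIT_LEN = 3000
MARKER = (1000, 1720)
HOST_LEN = 30000
COPIES = 6
INVERTED = (2,)
DELETION = 686
CONT_LEN = 2000
CONT_OFFSET = 4 * UNIT_LEN


@pytest.fixture(scope="session")
def unit():
    rng = np.random.default_rng(11)
    return random_unit(rng, UNIT_LEN, marker_len=MARKER[1] - MARKER[0],
                       marker_offset=MARKER[0])


@pytest.fixture(scope="session")
def locus(unit):
    """(host, haplotype, truth) with one inversion, a deletion and a
    contaminant segment between copies 4 and 5."""
    rng = np.random.default_rng(12)
    cont = random_seq(rng, CONT_LEN)
    host, hap, truth = make_locus(
        13, HOST_LEN, unit, COPIES, INVERTED, DELETION,
        contaminant=(cont, CONT_OFFSET))
    return host, hap, truth, cont


@pytest.fixture(scope="session")
def registry(unit, locus):
    host, _, _, cont = locus
    return TargetRegistry.build(host, unit, contaminant=cont)


@pytest.fixture(scope="session")
def index(registry):
    return index_targets(registry, k=15)


@pytest.fixture(scope="session")
def clean_reads(locus):
    """Error-free reads at 10x with an N50 long enough to span landmarks."""
    _, hap, _, _ = locus
    params = ReadSimParams(coverage_target=10.0, seed=21,
                           sub_rate=0, ins_rate=0, del_rate=0,
                           length_log_mean=np.log(8000) - 0.25, length_log_sd=0.5)
    return simulate_reads([(hap, 1.0)], params)


@pytest.fixture(scope="session")
def clean_segments(clean_reads, index):
    reads, _ = clean_reads
    return align_reads(reads, index)


@pytest.fixture(scope="session")
def noisy_reads(locus):
    """Nanopore-like reads (11% total error) at 10x."""
    _, hap, _, _ = locus
    params = ReadSimParams(coverage_target=10.0, seed=22,
                           length_log_mean=np.log(8000) - 0.25, length_log_sd=0.5)
    return simulate_reads([(hap, 1.0)], params)


@pytest.fixture(scope="session")
def noisy_segments(noisy_reads, index):
    reads, _ = noisy_reads
    return align_reads(reads, index)
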