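import numpy as np
import pytest

from odnmap.config import GuideSpec, OdnSpec, SampleSpec
from odnmap.io import ReadPair
from odnmap.simulate import (add_misprime_loci, add_spontaneous_breaks,
                             plant_guide_sites, simulate_genome, simulate_reads)

B2M_PROTOSPACER = "GAGTAGCGCGAGCACAGCTA"


@pytest.fixture(scope="session")
def odn() -> OdnSpec:
    return OdnSpec()


@pytest.fixture(scope="session")
def b2m_guide() -> GuideSpec:
    return GuideSpec("B2M", B2M_PROTOSPACER, "NGG")


@pytest.fixture(scope="session")
def sample() -> SampleSpec:
    return SampleSpec("sample1", "ACGTACGT")


def make_truth(seed: int, odn: OdnSpec, guide: GuideSpec, length: int = 120_000,
               offtargets=(1, 3), n_spont: int = 10, n_misprime: int = 10,
               gene_bias: float = 0.8):
    truth = simulate_genome(length, seed=seed)
    truth = plant_guide_sites(truth, guide, list(offtargets), seed=seed + 1)
    if n_spont:
        truth = add_spontaneous_breaks(truth, n_spont, seed=seed + 2, gene_bias=gene_bias)
    if n_misprime:
        truth = add_misprime_loci(truth, odn, n_misprime, seed=seed + 3)
    return truth


def make_pairs(truth, odn, n_reads: int, seed: int, barcode: str = "ACGTACGT",
               **kwargs) -> list[ReadPair]:
    r1, r2 = simulate_reads(truth, odn, n_reads, seed=seed, barcode=barcode, **kwargs)
    return [ReadPair(a[0], a[1], a[2], b[1], b[2]) for a, b in zip(r1, r2)]


@pytest.fixture(scope="session")
def small_truth(odn, b2m_guide):
    """A modest planted dataset shared by read-level and site-level tests."""
    return make_truth(seed=11, odn=odn, guide=b2m_guide)


@pytest.fixture(scope="session")
def small_pairs(small_truth, odn):
    return make_pairs(small_truth, odn, n_reads=3000, seed=17,
                      misprime_frac=0.3, dup_rate=0.5, read_len=100)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
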