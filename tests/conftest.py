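import numpy as np
import pytest

from xlsite.records import CrossLinkSite, MappedCdna


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genome():
    """A deterministic little genome with known motif placements.

    chr1 carries a TCAT at 10, a CCAC at 20, and a TTT run at 30..32
    embedded in otherwise motif-free sequence.
    """
    seq = list("G" * 50)
    seq[10:14] = "TCAT"
    seq[20:24] = "CCAC"
    seq[30:33] = "TTT"
    return {"chr1": "".join(seq)}


def make_cdna(chrom="chr1", strand="+", start=100, end=150, barcode=None,
              deletions=()):
    return MappedCdna(chrom, strand, start, end, barcode, tuple(deletions))


def make_site(chrom="chr1", strand="+", position=100, count=1,
              source="truncation"):
    return CrossLinkSite(chrom, strand, position, count, source)


@pytest.fixture
def make_cdna_factory():
    return make_cdna


@pytest.fixture
def make_site_factory():
    return make_site
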