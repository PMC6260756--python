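import numpy as np
import pytest

from txcurate.filters import CurationConfig
from txcurate.model import GenomicInterval, Transcript
from txcurate.simulate import FixtureSpec, generate


def make_tx(tid, exons, strand="+", seqid="chr1", gene=None, biotype="other"):
    """Shorthand transcript builder from (start, end) pairs."""
    return Transcript(
        tid, gene or f"g_{tid}",
        tuple(GenomicInterval(seqid, s, e, strand) for s, e in exons),
        biotype=biotype,
    )


@pytest.fixture(scope="session")
def bundle():
    """The default synthetic catalog (seed 1), shared across tests."""
    return generate(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def cfg():
    return CurationConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
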