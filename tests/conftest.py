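import numpy as np
import pytest

from sirnakit.transcripts import Transcript


@pytest.fixture
def toy_transcript():
    """1000-nt transcript with 5'UTR [1,99], CDS [100,800], 3'UTR [801,1000]."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=1000))
    return Transcript(
        id="TX1", symbol="GENE1", sequence=seq, cds_start=100, cds_end=800,
        exon_lengths=[300, 400, 300],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
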