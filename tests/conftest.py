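import numpy as np
import pytest

import arrowguide as ag


@pytest.fixture(scope="session")
def examples():
    """The built-in EGFR L858R / KRAS G12V worked examples."""
    return ag.worked_examples()


@pytest.fixture(scope="session")
def egfr(examples):
    return examples["EGFR_L858R"]


@pytest.fixture(scope="session")
def kras(examples):
    return examples["KRAS_G12V"]


@pytest.fixture()
def rng():
    return np.random.default_rng(20_260_921)


def random_dna(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture(scope="session")
def amplicon_ref(egfr):
    """A 143-bp amplicon embedding the EGFR L858R mutant protospacer."""
    r = np.random.default_rng(1)
    left = "".join(r.choice(list("ACGT"), 60))
    right = "".join(r.choice(list("ACGT"), 60))
    seq = left + egfr.pair.mut_context + right
    sites = [
        s
        for s in ag.scan_protospacers(seq, 60 + egfr.pair.variant_offset)
        if s.protospacer == egfr.mut_guide
    ]
    return ag.AmpliconRef(seq, sites[0])
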