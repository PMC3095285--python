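import pytest

from genarch.simulate import (ESTSimParams, EvolParams, SignalFlags,
                              implant_signals, simulate_ests, simulate_family)

TREE4 = "((a:0.2,b:0.2):0.1,(c:0.2,d:0.2):0.1);"


@pytest.fixture(scope="session")
def family4():
    """Four-gene family with four ancestral introns, moderate divergence."""
    return simulate_family(EvolParams(tree=TREE4, seed=11, n_codons=200,
                                      n_ancestral_introns=4))


@pytest.fixture(scope="session")
def clean_ests(family4):
    """Error-free, fully spliced, well-covered EST set with truth table."""
    return simulate_ests(family4, ESTSimParams(seed=12, error_rate=0.0,
                                               coverage=10.0,
                                               retained_intron_prob=0.0))


@pytest.fixture(scope="session")
def implanted_family(family4):
    """family4 with a transit peptide + anchor on 'a' and a retro-copy of 'b'."""
    return implant_signals(family4, {
        "a": SignalFlags(transit_peptide=True, tm_anchor=True),
        "b": SignalFlags(retrocopy=True),
    })
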