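import numpy as np
import pytest
from hypothesis import settings

from connmap.refdata import GeneSignature, GeneUniverse, RefSet, ReferenceProfile

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def universe5():
    return GeneUniverse(("g1", "g2", "g3", "g4", "g5"))


@pytest.fixture
def profile5(universe5):
    """The worked 5-gene example: ranks g1:+5 g2:-4 g3:+3 g4:-2 g5:+1."""
    return ReferenceProfile(
        "p5", universe5, np.array([5, -4, 3, -2, 1]), drug="drugA", cell="MCF7", dose="1e-6"
    )


def make_signature(*entries, signature_id="sig"):
    return GeneSignature(signature_id, tuple(entries))


def make_profile(universe, ranks, profile_id="p", **meta):
    return ReferenceProfile(profile_id, universe, np.asarray(ranks), **meta)


@pytest.fixture
def sig_top2(universe5):
    """Perfectly matching signature for profile5: the two most extreme genes."""
    return make_signature(("g1", 1), ("g2", -1))
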