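import numpy as np
import pytest
from hypothesis import settings

from trialadapt.posterior import MatchedPair, make_sample

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_pair(rng, n_c=None, n_t=None, shift=0.2, sd=1.0):
    """A matched pair with normal outcomes, treatment shifted upward."""
    n_c = n_c if n_c is not None else int(rng.integers(3, 11))
    n_t = n_t if n_t is not None else int(rng.integers(3, 11))
    ctrl = make_sample(rng.normal(0.0, sd, n_c))
    trt = make_sample(rng.normal(shift, sd, n_t))
    return MatchedPair(response=0, control=ctrl, treatment=trt)


@pytest.fixture
def symmetric_pair(rng):
    values = rng.normal(0.0, 1.0, 8)
    return MatchedPair(response=0, control=make_sample(values), treatment=make_sample(values))
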