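import numpy as np
import pytest

from escapenet import DirectedGraph, NodeParameters


@pytest.fixture
def reference_params() -> NodeParameters:
    """The workhorse operating point: excitable, weak noise."""
    return NodeParameters(lambda_=0.9, omega=20.0, alpha=0.05)


@pytest.fixture
def complete3() -> DirectedGraph:
    return DirectedGraph.complete(3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20120106)
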