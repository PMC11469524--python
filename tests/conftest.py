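import numpy as np
import pytest

import mranet as m
from mranet.network import Condition, PerturbationDesign


@pytest.fixture
def chain_ahb():
    """A -> H -> B with A a stimulus; A and B measured, H hidden."""
    net = m.SignalingNetwork(("A", "H", "B"), (("A", "H"), ("H", "B")), {"A"})
    design = PerturbationDesign(
        (Condition("stim", frozenset({"A"}), frozenset()),),
        (("A", "A"), ("B", "B")),
    )
    return net, design


@pytest.fixture
def two_node():
    """Stimulus A -> B with r_B_A = 2 (the worked simulator example)."""
    net = m.SignalingNetwork(("A", "B"), (("A", "B"),), {"A"})
    r = np.array([[-1.0, 0.0], [2.0, -1.0]])
    return net, r


@pytest.fixture
def small_chain():
    """S -> A -> B, all downstream nodes measured and inhibitable."""
    net = m.SignalingNetwork(("S", "A", "B"), (("S", "A"), ("A", "B")), {"S"})
    design = m.systematic_design(net)
    return net, design


def quick_config(seed=0, n_starts=8):
    return m.FitConfig(n_starts=n_starts, seed=seed, sign_flip_rounds=2)
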