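import numpy as np
import pytest

from plasticlsm.network import (
    EXCITATORY,
    INHIBITORY,
    Network,
    SynapseTable,
)


def make_micro_network(weights, pre, post, exc=None):
    """A hand-built network for unit tests: explicit synapses, exc/inh types."""
    n = max(list(pre) + list(post)) + 1 if len(pre) else 2
    weights = np.asarray(weights, dtype=float)
    pre = np.asarray(pre, dtype=np.int64)
    post = np.asarray(post, dtype=np.int64)
    if exc is None:
        exc = weights >= 0
    params = [EXCITATORY] * n
    table = SynapseTable(
        pre=pre, post=post, weight=weights.copy(),
        is_excitatory=np.asarray(exc, dtype=bool),
    )
    return Network(params=params, synapses=table)


@pytest.fixture
def micro_network():
    return make_micro_network([5.0, 5.0], pre=[0, 1], post=[1, 0])
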