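import numpy as np
import pytest

from thermonet import synthgen
from thermonet.graph import TensorShape


@pytest.fixture(scope="session")
def small_sim_config():
    """Reduced-frame simulation config used across tests (fast to draw)."""
    return synthgen.SimulationConfig(
        frame_height=120, frame_width=160, noise_sd=0.1, seed=11
    )


@pytest.fixture(scope="session")
def input_299():
    return TensorShape(299, 299, 3)


def random_small_graph(rng: np.random.Generator):
    """A random valid chain-with-branches layer graph on a small input.

    Used as the shared generator for shape-inference and parameter-count
    oracle tests.
    """
    from thermonet.graph import LayerNode, NetworkGraph

    g = NetworkGraph("custom")
    prev = g.add_node(LayerNode("input", "input"))
    size = int(rng.integers(12, 25))
    n_blocks = int(rng.integers(1, 4))
    for b in range(n_blocks):
        kind = rng.choice(["conv", "maxpool", "avgpool", "branch"])
        name = f"b{b}"
        if kind == "conv":
            f = int(rng.choice([1, 3, 5]))
            stride = int(rng.choice([1, 2]))
            pad = "same" if (stride == 1 and rng.random() < 0.5) else 0
            prev = g.chain(prev, LayerNode(
                f"{name}/conv", "conv", filter_height=f, filter_width=f,
                num_filters=int(rng.integers(1, 9)), stride=stride, padding=pad))
            prev = g.chain(prev, LayerNode(f"{name}/bn", "batchnorm"))
            prev = g.chain(prev, LayerNode(f"{name}/relu", "activation"))
        elif kind in ("maxpool", "avgpool"):
            prev = g.chain(prev, LayerNode(
                f"{name}/pool", kind, filter_height=2, filter_width=2, stride=1))
        else:
            width = int(rng.integers(2, 4))
            outs = []
            for k in range(width):
                f = int(rng.choice([1, 3]))
                nid = g.chain(prev, LayerNode(
                    f"{name}/br{k}/conv", "conv", filter_height=f, filter_width=f,
                    num_filters=int(rng.integers(1, 7)), stride=1, padding="same"))
                outs.append(nid)
            cat = g.add_node(LayerNode(f"{name}/concat", "concat"))
            for o in outs:
                g.add_edge(o, cat)
            prev = cat
    prev = g.chain(prev, LayerNode("head/gap", "global_avg_pool"))
    prev = g.chain(prev, LayerNode("head/dense", "dense", num_filters=2))
    prev = g.chain(prev, LayerNode("head/softmax", "softmax"))
    g.chain(prev, LayerNode("head/cls", "classification"))
    g.validate()
    return g, TensorShape(size, size, int(rng.integers(1, 4)))
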