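"""Unit tests for the layer-graph machinery: the convolution output-size
rule, shape inference, parameter counting, FLOP estimation, freezing and
serialization."""

import numpy as np
import pytest

from thermonet.graph import (
    GeometryError,
    GraphValidationError,
    LayerNode,
    NetworkGraph,
    ShapeConflictError,
    TensorShape,
    conv_output_size,
)
from conftest import random_small_graph


def brute_force_output_size(w, f, p, s):
    """Independent oracle: enumerate valid filter placements on a padded
    1-D grid of length w + 2p, stepping by s."""
    padded = w + 2 * p
    count = 0
    pos = 0
    while pos + f <= padded:
        count += 1
        pos += s
    return count


class TestConvOutputSize:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((299, 3, 1, 1), 299),   # 'same' padding identity
            ((299, 3, 0, 2), 149),
            ((480, 7, 3, 2), 240),
            ((35, 3, 0, 2), 17),
            ((75, 3, 0, 2), 37),
        ],
    )
    def test_known_values(self, args, expected):
        with pytest.warns() if (args[0] - args[1] + 2 * args[2]) % args[3] else _noop():
            assert conv_output_size(*args) == expected

    def test_matches_placement_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            w = int(rng.integers(1, 60))
            f = int(rng.integers(1, min(w, 9) + 1))
            p = int(rng.integers(0, 4))
            s = int(rng.integers(1, 4))
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                assert conv_output_size(w, f, p, s) == brute_force_output_size(w, f, p, s)

    def test_floor_division_warns(self):
        with pytest.warns(UserWarning, match="not divisible"):
            assert conv_output_size(10, 3, 0, 2) == 4

    def test_invalid_geometry_raises(self):
        with pytest.raises(GeometryError):
            conv_output_size(2, 7, 0, 1)  # input smaller than filter
        with pytest.raises(GeometryError):
            conv_output_size(10, 3, 0, 0)  # zero stride
        with pytest.raises(GeometryError):
            conv_output_size(10.5, 3, 0, 1)  # non-integer

    def test_error_names_offending_argument(self):
        with pytest.raises(GeometryError, match="stride"):
            conv_output_size(10, 3, 0, -1)


import contextlib


@contextlib.contextmanager
def _noop():
    yield


class TestTensorShape:
    def test_rejects_nonpositive_dims(self):
        for bad in [(0, 1, 1), (1, -2, 1), (1, 1, 0)]:
            with pytest.raises(GeometryError):
                TensorShape(*bad)


def linear_chain():
    g = NetworkGraph("custom")
    p = g.add_node(LayerNode("input", "input"))
    p = g.chain(p, LayerNode("c/conv", "conv", filter_height=3, filter_width=3,
                             num_filters=32, padding="same"))
    p = g.chain(p, LayerNode("c/bn", "batchnorm"))
    p = g.chain(p, LayerNode("c/relu", "activation"))
    g.chain(p, LayerNode("cls", "classification"))
    g.validate()
    return g


class TestGraphStructure:
    def test_linear_chain_counts(self):
        g = linear_chain()
        s = g.summarize(TensorShape(8, 8, 3))
        assert s.layer_count == 5
        assert s.connection_count == 4

    def test_concat_requires_in_degree_two(self):
        g = NetworkGraph("custom")
        p = g.add_node(LayerNode("input", "input"))
        cat = g.add_node(LayerNode("cat", "concat"))
        g.add_edge(p, cat)
        g.chain(cat, LayerNode("cls", "classification"))
        with pytest.raises(GraphValidationError, match="in-degree"):
            g.validate()

    def test_cycle_detection(self):
        g = NetworkGraph("custom")
        p = g.add_node(LayerNode("input", "input"))
        a = g.chain(p, LayerNode("a", "activation"))
        b = g.chain(a, LayerNode("b", "activation"))
        g.add_edge(b, a)
        with pytest.raises(GraphValidationError):
            g.validate()

    def test_dropout_rate_presence_rule(self):
        with pytest.raises(GraphValidationError):
            LayerNode("d", "dropout")  # missing rate
        with pytest.raises(GraphValidationError):
            LayerNode("a", "activation", dropout_rate=0.5)  # rate on non-dropout


class TestShapeInference:
    def test_single_conv(self):
        g = NetworkGraph("custom")
        p = g.add_node(LayerNode("input", "input"))
        p = g.chain(p, LayerNode("c", "conv", filter_height=3, filter_width=3,
                                 num_filters=32, stride=1, padding=1))
        g.chain(p, LayerNode("cls", "classification"))
        g.validate()
        shapes = g.infer_shapes(TensorShape(299, 299, 3))
        assert shapes["c"] == TensorShape(299, 299, 32)

    def test_concat_sums_channels(self):
        g = NetworkGraph("custom")
        p = g.add_node(LayerNode("input", "input"))
        outs = [
            g.chain(p, LayerNode(f"b{i}", "conv", filter_height=1, filter_width=1,
                                 num_filters=c))
            for i, c in enumerate([128, 384, 256, 256])
        ]
        cat = g.add_node(LayerNode("cat", "concat"))
        for o in outs:
            g.add_edge(o, cat)
        g.chain(cat, LayerNode("cls", "classification"))
        g.validate()
        shapes = g.infer_shapes(TensorShape(17, 17, 64))
        assert shapes["cat"].channels == 1024

    def test_concat_spatial_mismatch_names_node(self):
        g = NetworkGraph("custom")
        p = g.add_node(LayerNode("input", "input"))
        a = g.chain(p, LayerNode("a", "conv", filter_height=1, filter_width=1,
                                 num_filters=4))
        b = g.chain(p, LayerNode("b", "maxpool", filter_height=2, filter_width=2,
                                 stride=2))
        cat = g.add_node(LayerNode("cat", "concat"))
        g.add_edge(a, cat)
        g.add_edge(b, cat)
        g.chain(cat, LayerNode("cls", "classification"))
        g.validate()
        with pytest.raises(ShapeConflictError, match="cat"):
            g.infer_shapes(TensorShape(8, 8, 2))

    def test_global_avg_pool_collapses_spatial(self):
        g = NetworkGraph("custom")
        p = g.add_node(LayerNode("input", "input"))
        p = g.chain(p, LayerNode("gap", "global_avg_pool"))
        g.chain(p, LayerNode("cls", "classification"))
        g.validate()
        assert g.infer_shapes(TensorShape(35, 35, 384))["gap"] == TensorShape(1, 1, 384)


class TestParameterCounting:
    def test_dense_with_bias(self):
        g = NetworkGraph("custom")
        p = g.add_node(LayerNode("input", "input"))
        p = g.chain(p, LayerNode("gap", "global_avg_pool"))
        p = g.chain(p, LayerNode("fc", "dense", num_filters=2))
        g.chain(p, LayerNode("cls", "classification"))
        g.validate()
        count = g.count_parameters(TensorShape(1, 1, 1536), include_batchnorm=False)
        assert count.total == 1536 * 2 + 2 == 3074

    def test_conv_no_bias(self):
        g = NetworkGraph("custom")
        p = g.add_node(LayerNode("input", "input"))
        p = g.chain(p, LayerNode("c", "conv", filter_height=3, filter_width=3,
                                 num_filters=32, padding="same"))
        g.chain(p, LayerNode("cls", "classification"))
        g.validate()
        count = g.count_parameters(TensorShape(8, 8, 3), include_bias=False)
        assert count.total == 3 * 3 * 3 * 32 == 864

    def test_matches_materialized_weights(self):
        """Materialize-and-count oracle on random graphs: the analytic sum
        must equal the summed sizes of the actually-allocated tensors."""
        from thermonet.nn import NetworkExecutor

        rng = np.random.default_rng(21)
        for _ in range(20):
            g, shape = random_small_graph(rng)
            analytic = g.count_parameters(shape, include_batchnorm=False,
                                          include_bias=False)
            ex = NetworkExecutor(g, shape, np.random.default_rng(0))
            convs_dense = sum(
                int(p["w"].size) + int(p.get("b", np.empty(0)).size)
                for nid, p in ex.params.items()
                if g.nodes[nid].kind in ("conv", "dense")
            )
            assert analytic.total == convs_dense
            # batchnorm accounting: 2C trainable + 2C running stats
            with_bn = g.count_parameters(shape, include_batchnorm=True,
                                         include_bias=False)
            bn_total = sum(
                int(p["gamma"].size + p["beta"].size) + int(
                    ex.bn_state[nid]["mean"].size + ex.bn_state[nid]["var"].size)
                for nid, p in ex.params.items()
                if g.nodes[nid].kind == "batchnorm"
            )
            assert with_bn.total == convs_dense + bn_total


class TestFlops:
    def test_unit_conv(self):
        g = NetworkGraph("custom")
        p = g.add_node(LayerNode("input", "input"))
        p = g.chain(p, LayerNode("c", "conv", filter_height=1, filter_width=1,
                                 num_filters=1))
        g.chain(p, LayerNode("cls", "classification"))
        g.validate()
        assert g.estimate_flops(TensorShape(1, 1, 1)) == 1

    def test_area_scaling(self):
        g = NetworkGraph("custom")
        p = g.add_node(LayerNode("input", "input"))
        p = g.chain(p, LayerNode("c", "conv", filter_height=3, filter_width=3,
                                 num_filters=8, padding="same"))
        g.chain(p, LayerNode("cls", "classification"))
        g.validate()
        f1 = g.estimate_flops(TensorShape(16, 16, 3))
        f2 = g.estimate_flops(TensorShape(32, 32, 3))
        assert f2 == 4 * f1


class TestFreezing:
    def test_freeze_zero_is_identity(self):
        g = linear_chain()
        g2 = g.freeze_prefix(0)
        assert g.to_json() == g2.to_json()

    def test_freeze_prefix_marks_first_convs(self):
        from thermonet.builders import build_inception_v4

        g = build_inception_v4()
        g10 = g.freeze_prefix(10)
        frozen = [nid for nid in g10.conv_ids_topological()
                  if not g10.nodes[nid].trainable]
        assert len(frozen) == 10
        assert frozen == g.conv_ids_topological()[:10]
        shape = TensorShape(299, 299, 3)
        assert (g10.count_parameters(shape).trainable
                < g.count_parameters(shape).trainable)

    def test_freeze_all_leaves_head_and_batchnorm(self):
        from thermonet.builders import build_inception_v4

        g = build_inception_v4()
        n_convs = len(g.conv_ids_topological())
        gall = g.freeze_prefix(n_convs)
        shape = TensorShape(299, 299, 3)
        shapes = g.infer_shapes(shape)
        preds = g.predecessors()
        expected = 0
        for nid, node in gall.nodes.items():
            if node.kind == "dense":
                cin = shapes[preds[nid][0]].channels
                expected += cin * node.num_filters + node.num_filters
            elif node.kind == "batchnorm":
                expected += 2 * shapes[preds[nid][0]].channels
        assert gall.count_parameters(shape).trainable == expected

    def test_freeze_out_of_range(self):
        g = linear_chain()
        with pytest.raises(ValueError):
            g.freeze_prefix(2)

    def test_freeze_stem_region(self):
        from thermonet.builders import build_inception_v4

        g = build_inception_v4().freeze_region("stem")
        assert all(not n.trainable for n in g.nodes.values()
                   if n.stage == "stem" and n.kind in ("conv", "batchnorm"))
        assert all(n.trainable for n in g.nodes.values()
                   if n.stage.startswith("inception_a") and n.kind == "conv")


class TestSerialization:
    def test_round_trip(self):
        g = linear_chain()
        g2 = NetworkGraph.from_json(g.to_json())
        assert g2.to_json() == g.to_json()
        s1 = g.summarize(TensorShape(8, 8, 3))
        s2 = g2.summarize(TensorShape(8, 8, 3))
        assert s1 == s2
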