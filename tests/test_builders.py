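"""Tests for the inception V3/V4/MV4 builders: block compositions, the
feature-preservation rule of the modified inception-B, monotone
size/compute reduction of MV4 versus V4, and shape-inference agreement
with an independent recursive evaluator."""

import json
import math

import numpy as np
import pytest

from thermonet import builders
from thermonet.builders import (
    BlockConfigError,
    HeadSpec,
    InvalidHeadError,
    MV4BlockConfig,
    build_inception_mv4,
    build_inception_v3,
    build_inception_v4,
    build_model,
    count_inception_b_blocks,
    default_v3_head,
    default_v4_head,
    make_canonical_inception_b,
    make_modified_inception_b,
)
from thermonet.graph import GeometryError, TensorShape

from conftest import random_small_graph

INPUT = TensorShape(299, 299, 3)


# ---------------------------------------------------------------------------
# independent shape oracle


def replay_shapes(graph, input_shape):
    """Brute-force per-node replay of the output-size rule, written
    independently of NetworkGraph.infer_shapes (plain recursion with
    memoization, explicit floor arithmetic)."""
    preds = {}
    for nid in graph.nodes:
        preds[nid] = []
    for a, b in graph.edges:
        preds[b].append(a)
    memo = {}

    def out_size(w, f, p, s):
        return (w - f + 2 * p) // s + 1

    def shape_of(nid):
        if nid in memo:
            return memo[nid]
        node = graph.nodes[nid]
        if node.kind == "input":
            result = input_shape.as_tuple()
        elif node.kind == "concat":
            ins = [shape_of(p) for p in preds[nid]]
            assert len({(h, w) for h, w, _ in ins}) == 1
            result = (ins[0][0], ins[0][1], sum(c for _, _, c in ins))
        else:
            h, w, c = shape_of(preds[nid][0])
            if node.kind in ("conv", "maxpool", "avgpool"):
                if node.padding == "same":
                    nh, nw = h, w
                else:
                    nh = out_size(h, node.filter_height, node.padding, node.stride)
                    nw = out_size(w, node.filter_width, node.padding, node.stride)
                nc = node.num_filters if node.kind == "conv" else c
                result = (nh, nw, nc)
            elif node.kind == "global_avg_pool":
                result = (1, 1, c)
            elif node.kind == "dense":
                result = (1, 1, node.num_filters)
            else:
                result = (h, w, c)
        memo[nid] = result
        return result

    return {nid: shape_of(nid) for nid in graph.nodes}


def assert_shapes_agree(graph, input_shape):
    inferred = graph.infer_shapes(input_shape)
    replayed = replay_shapes(graph, input_shape)
    for nid in graph.nodes:
        assert inferred[nid].as_tuple() == replayed[nid], nid


# ---------------------------------------------------------------------------
# compositions


class TestV4Composition:
    def test_block_counts(self):
        g = build_inception_v4()
        stages = {n.stage for n in g.nodes.values()}
        assert count_inception_b_blocks(g) == 7
        assert sum(1 for s in stages if s.startswith("inception_a")) == 4
        assert sum(1 for s in stages if s.startswith("inception_c")) == 3
        assert "reduction_a" in stages and "reduction_b" in stages

    def test_every_inception_b_concat_is_1024_channels(self):
        g = build_inception_v4()
        shapes = g.infer_shapes(INPUT)
        concats = [nid for nid in g.nodes
                   if nid.startswith("inception_b") and nid.endswith("concat")]
        assert len(concats) == 7
        assert all(shapes[nid].channels == 1024 for nid in concats)

    def test_head_input_is_1536_features(self):
        g = build_inception_v4()
        shapes = g.infer_shapes(INPUT)
        assert shapes["head/0_global_avg_pool"].channels == 1536

    def test_conv_bn_relu_triples(self):
        g = build_inception_v4()
        succ = g.successors()
        for nid, node in g.nodes.items():
            if node.kind == "conv":
                (bn,) = succ[nid]
                assert g.nodes[bn].kind == "batchnorm"
                (relu,) = succ[bn]
                assert g.nodes[relu].kind == "activation"

    def test_default_head_has_dropout_08(self):
        g = build_inception_v4()
        drops = [n for n in g.nodes.values() if n.kind == "dropout"]
        assert len(drops) == 1 and drops[0].dropout_rate == 0.8

    def test_too_small_input_is_invalid_geometry(self):
        with pytest.raises(GeometryError):
            build_inception_v4(TensorShape(16, 16, 3))


class TestV3Composition:
    def test_block_counts(self):
        g = build_inception_v3()
        stages = {n.stage for n in g.nodes.values()}
        assert sum(1 for s in stages if s.startswith("inception_a")) == 3
        assert count_inception_b_blocks(g) == 4
        assert sum(1 for s in stages if s.startswith("inception_c")) == 2

    def test_head_input_is_2048_features_and_no_dropout(self):
        g = build_inception_v3()
        shapes = g.infer_shapes(INPUT)
        assert shapes["head/0_global_avg_pool"].channels == 2048
        assert not any(n.kind == "dropout" for n in g.nodes.values())

    def test_shape_inference_succeeds_end_to_end(self):
        g = build_inception_v3()
        shapes = g.infer_shapes(INPUT)
        assert shapes[g.output_id].channels == 2


class TestModifiedInceptionB:
    def test_default_concat_output_is_1024(self):
        frag = make_modified_inception_b()
        shapes = frag.infer_shapes(TensorShape(17, 17, 1024))
        assert shapes[frag.output_id].channels == 1024

    def test_spatial_dims_preserved(self):
        frag = make_modified_inception_b()
        for side in (9, 17, 33):
            shapes = frag.infer_shapes(TensorShape(side, side, 512))
            assert (shapes[frag.output_id].height,
                    shapes[frag.output_id].width) == (side, side)

    def test_node_reduction_versus_canonical_is_positive_constant(self):
        mod = make_modified_inception_b()
        canon = make_canonical_inception_b()
        reduction = len(canon.nodes) - len(mod.nodes)
        assert reduction > 0
        # and the whole-network delta is 7x that per-block constant
        v4 = build_inception_v4()
        mv4 = build_inception_mv4()
        assert len(v4.nodes) - len(mv4.nodes) == 7 * reduction
        assert len(v4.edges) - len(mv4.edges) == 7 * (
            len(canon.edges) - len(mod.edges))

    def test_strict_config_rejects_non_1024_totals(self):
        with pytest.raises(BlockConfigError):
            MV4BlockConfig(parallel_branch_filters=(256, 256))

    def test_literal_text_variant_behind_flag(self):
        cfg = MV4BlockConfig.literal_text()
        assert cfg.total_output_channels == 1152
        frag = make_modified_inception_b(cfg)
        shapes = frag.infer_shapes(TensorShape(17, 17, 1024))
        assert shapes[frag.output_id].channels == 1152
        # the widened concat still feeds reduction-B legally
        g = build_inception_mv4(block_config=cfg)
        assert g.infer_shapes(INPUT)["head/0_global_avg_pool"].channels == 1536


class TestMV4Monotonicity:
    def test_all_seven_blocks_modified_and_preserving(self):
        g = build_inception_mv4()
        shapes = g.infer_shapes(INPUT)
        concats = [nid for nid in g.nodes
                   if nid.startswith("inception_b") and nid.endswith("concat")]
        assert len(concats) == 7
        assert all(shapes[nid].channels == 1024 for nid in concats)

    def test_strictly_smaller_than_v4_in_every_measure(self):
        v4 = build_inception_v4()
        mv4 = build_inception_mv4()
        s4, sm = v4.summarize(INPUT), mv4.summarize(INPUT)
        assert sm.layer_count < s4.layer_count
        assert sm.connection_count < s4.connection_count
        assert sm.parameter_count < s4.parameter_count
        assert sm.flops_estimate < s4.flops_estimate

    def test_flops_inequality_at_tiny_scale_too(self):
        shape = TensorShape(75, 75, 3)
        tv4 = build_model("tiny-v4")
        tmv4 = build_model("tiny-mv4")
        assert tmv4.estimate_flops(shape) < tv4.estimate_flops(shape)


class TestHeads:
    def test_head_requires_terminal_classification(self):
        with pytest.raises(InvalidHeadError):
            HeadSpec((("global_avg_pool",), ("dense", 2)))

    def test_binary_dense_width(self):
        for head in (default_v3_head(), default_v4_head()):
            dense = [op for op in head.ops if op[0] == "dense"]
            assert dense == [("dense", 2)]


class TestDeterminismAndOracle:
    def test_two_builds_serialize_identically(self):
        for build in (build_inception_v3, build_inception_v4, build_inception_mv4):
            assert build().to_json() == build().to_json()

    def test_serialization_round_trip_preserves_summary(self):
        g = build_inception_mv4()
        g2 = type(g).from_json(g.to_json())
        assert g.summarize(INPUT) == g2.summarize(INPUT)

    @pytest.mark.parametrize("build", [build_inception_v3, build_inception_v4,
                                       build_inception_mv4])
    def test_shape_inference_matches_independent_replay(self, build):
        assert_shapes_agree(build(), INPUT)

    def test_shape_inference_on_100_random_graphs(self):
        rng = np.random.default_rng(77)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(100):
                g, shape = random_small_graph(rng)
                assert_shapes_agree(g, shape)

    def test_tiny_variants_preserve_stage_sequence(self):
        full = build_inception_mv4()
        tiny = build_model("tiny-mv4")
        def stage_kinds(g):
            order = [g.nodes[nid].stage for nid in g.topological_order()]
            # collapse consecutive duplicates; drop the repeat index
            import re
            seq = []
            for s in order:
                s = re.sub(r"\d+$", "", s)
                if not seq or seq[-1] != s:
                    seq.append(s)
            return seq
        assert set(stage_kinds(tiny)) <= set(stage_kinds(full))
        # every stage family present
        for fam in ("stem", "inception_a", "reduction_a", "inception_b",
                    "reduction_b", "inception_c", "head"):
            assert any(s.startswith(fam) for s in stage_kinds(tiny))
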