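"""Builders for the inception V3, V4 and MV4 layer graphs.

The V4 blocks follow the canonical published inception-v4 configuration
(stem to 35x35x384, four inception-A, reduction-A, seven inception-B,
reduction-B, three inception-C, 1536 features into the head).  The V3
builder keeps that family's canonical filter geometry but the block
composition used for the thermography experiments: three inception-A,
reduction-A, four inception-B, reduction-B, two inception-C, 2048 features
into the head.

MV4 is V4 with every one of the seven inception-B blocks replaced by a
shallower multi-branch block that preserves the 1024 concatenated output
features, so reduction-B and everything downstream are geometry-compatible
unchanged.  Its default branch widths are recorded in
:class:`MV4BlockConfig`; every width in every builder is tabulated in this
one module so deviations from the canonical configuration are auditable.

``width_scale`` lets every filter count be scaled down uniformly (minimum
one filter), producing the "tiny" variants used for CPU-scale experiments;
the block topology is preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph import LayerNode, NetworkGraph, TensorShape

__all__ = [
    "HeadSpec",
    "MV4BlockConfig",
    "InvalidHeadError",
    "BlockConfigError",
    "default_v3_head",
    "default_v4_head",
    "attach_head",
    "build_inception_v3",
    "build_inception_v4",
    "build_inception_mv4",
    "make_modified_inception_b",
    "build_model",
    "MODEL_NAMES",
    "TINY_SIDE",
    "TINY_WIDTH_SCALE",
    "DEFAULT_INPUT",
    "count_inception_b_blocks",
]

DEFAULT_INPUT = TensorShape(299, 299, 3)
#: Input side, width multiplier, and inception-A/B/C block repeats of the
#: tiny-v4 / tiny-mv4 variants (the full models use 4/7/3 at width 1).
TINY_SIDE = 75
TINY_WIDTH_SCALE = 0.375
TINY_BLOCK_REPEATS = (1, 2, 1)
FULL_BLOCK_REPEATS = (4, 7, 3)

MODEL_NAMES = ("v3", "v4", "mv4", "tiny-v4", "tiny-mv4")


class InvalidHeadError(ValueError):
    """Head specification lacking a terminal classification element."""


class BlockConfigError(ValueError):
    """MV4 block configuration violating the feature-preservation rule."""


@dataclass(frozen=True)
class HeadSpec:
    """Ordered classifier head: a tuple of ops drawn from
    ``("global_avg_pool",)``, ``("dropout", rate)``, ``("dense", units)``,
    ``("softmax",)``, ``("classification",)``; the final element must be
    classification."""

    ops: tuple[tuple, ...]

    def __post_init__(self):
        if not self.ops or self.ops[-1][0] != "classification":
            raise InvalidHeadError("head must terminate in a classification element")
        allowed = {"global_avg_pool", "dropout", "dense", "softmax", "classification"}
        for op in self.ops:
            if op[0] not in allowed:
                raise InvalidHeadError(f"unknown head op {op[0]!r}")


def default_v3_head(num_classes: int = 2) -> HeadSpec:
    """Global average pooling + dense + softmax (no dropout)."""
    return HeadSpec(
        (("global_avg_pool",), ("dense", num_classes), ("softmax",), ("classification",))
    )


def default_v4_head(num_classes: int = 2, dropout_rate: float = 0.8) -> HeadSpec:
    """Global average pooling + dropout(0.8) + dense + softmax."""
    return HeadSpec(
        (
            ("global_avg_pool",),
            ("dropout", dropout_rate),
            ("dense", num_classes),
            ("softmax",),
            ("classification",),
        )
    )


@dataclass(frozen=True)
class MV4BlockConfig:
    """Branch widths of the modified inception-B block.

    Branches (all stride 1, spatial dims preserved):

    * average pool -> 1x1 conv (``avgpool_proj_filters``) -> 3x3 conv
      (``avgpool_branch_filters``) — the branch's output width is thereby
      raised from 128 to 256 features;
    * direct 1x1 conv (``direct_branch_filters``);
    * 1x1 conv (``stem_1x1_filters``) feeding two parallel
      ``parallel_filter_size`` x ``parallel_filter_size`` convs
      (``parallel_branch_filters``).

    The concatenated output width must equal 1024 — the feature-
    preservation rule that keeps the block interchangeable with the
    canonical inception-B — unless ``strict`` is disabled.
    ``literal_text()`` returns the 1152-channel variant with two parallel
    256-filter convs.
    """

    avgpool_proj_filters: int = 128
    avgpool_branch_filters: int = 256
    direct_branch_filters: int = 384
    stem_1x1_filters: int = 192
    parallel_branch_filters: tuple[int, int] = (192, 192)
    parallel_filter_size: int = 3
    strict: bool = True

    #: Output width of the canonical inception-B this block replaces.
    PRESERVED_FEATURES = 1024

    def __post_init__(self):
        widths = (
            self.avgpool_proj_filters,
            self.avgpool_branch_filters,
            self.direct_branch_filters,
            self.stem_1x1_filters,
            *self.parallel_branch_filters,
        )
        if any(w < 1 for w in widths) or self.parallel_filter_size < 1:
            raise BlockConfigError("all branch widths and filter sizes must be >= 1")
        if self.strict and self.total_output_channels != self.PRESERVED_FEATURES:
            raise BlockConfigError(
                f"concatenated output is {self.total_output_channels} channels; the "
                f"feature-preservation rule requires {self.PRESERVED_FEATURES} "
                "(pass strict=False to allow other widths)"
            )

    @property
    def total_output_channels(self) -> int:
        return (
            self.avgpool_branch_filters
            + self.direct_branch_filters
            + sum(self.parallel_branch_filters)
        )

    @classmethod
    def literal_text(cls) -> "MV4BlockConfig":
        """The 256+384+256+256 = 1152-channel variant (strict mode off)."""
        return cls(parallel_branch_filters=(256, 256), strict=False)


# ---------------------------------------------------------------------------
# construction helpers


def _scaler(width_scale: float):
    if width_scale <= 0:
        raise ValueError("width_scale must be positive")
    if width_scale == 1.0:
        return lambda w: w
    return lambda w: max(1, int(round(w * width_scale)))


class _Assembler:
    """Adds conv+batchnorm+activation triples and pooling/concat nodes with
    hierarchical ids; every conv is followed by batchnorm then ReLU."""

    def __init__(self, graph: NetworkGraph, ws):
        self.g = graph
        self.ws = ws

    def conv(self, prev: str, name: str, filters: int, fh: int, fw: int,
             stride: int = 1, padding=0) -> str:
        g = self.g
        cid = g.chain(prev, LayerNode(f"{name}/conv", "conv", filter_height=fh,
                                      filter_width=fw, num_filters=self.ws(filters),
                                      stride=stride, padding=padding))
        bid = g.chain(cid, LayerNode(f"{name}/bn", "batchnorm"))
        return g.chain(bid, LayerNode(f"{name}/relu", "activation"))

    def pool(self, prev: str, name: str, kind: str, size: int = 3,
             stride: int = 1, padding=0) -> str:
        return self.g.chain(prev, LayerNode(name, kind, filter_height=size,
                                            filter_width=size, stride=stride,
                                            padding=padding))

    def concat(self, name: str, inputs: list[str]) -> str:
        nid = self.g.add_node(LayerNode(name, "concat"))
        for src in inputs:
            self.g.add_edge(src, nid)
        return nid


# ---------------------------------------------------------------------------
# inception V4 blocks (canonical widths)


def _stem_v4(a: _Assembler, prev: str) -> str:
    s = "stem"
    x = a.conv(prev, f"{s}/conv1", 32, 3, 3, stride=2)          # 299 -> 149
    x = a.conv(x, f"{s}/conv2", 32, 3, 3)                        # -> 147
    x = a.conv(x, f"{s}/conv3", 64, 3, 3, padding="same")
    p = a.pool(x, f"{s}/junc1/maxpool", "maxpool", 3, stride=2)  # -> 73
    c = a.conv(x, f"{s}/junc1/conv", 96, 3, 3, stride=2)
    x = a.concat(f"{s}/junc1/concat", [p, c])                    # 160 ch
    b1 = a.conv(x, f"{s}/junc2/b1/conv1", 64, 1, 1)
    b1 = a.conv(b1, f"{s}/junc2/b1/conv2", 96, 3, 3)             # -> 71
    b2 = a.conv(x, f"{s}/junc2/b2/conv1", 64, 1, 1)
    b2 = a.conv(b2, f"{s}/junc2/b2/conv2", 64, 7, 1, padding="same")
    b2 = a.conv(b2, f"{s}/junc2/b2/conv3", 64, 1, 7, padding="same")
    b2 = a.conv(b2, f"{s}/junc2/b2/conv4", 96, 3, 3)
    x = a.concat(f"{s}/junc2/concat", [b1, b2])                  # 192 ch
    c = a.conv(x, f"{s}/junc3/conv", 192, 3, 3, stride=2)        # -> 35
    p = a.pool(x, f"{s}/junc3/maxpool", "maxpool", 3, stride=2)
    return a.concat(f"{s}/junc3/concat", [c, p])                 # 384 ch


def _inception_a_v4(a: _Assembler, prev: str, name: str) -> str:
    b1 = a.pool(prev, f"{name}/b1/avgpool", "avgpool", 3, padding="same")
    b1 = a.conv(b1, f"{name}/b1/conv", 96, 1, 1)
    b2 = a.conv(prev, f"{name}/b2/conv", 96, 1, 1)
    b3 = a.conv(prev, f"{name}/b3/conv1", 64, 1, 1)
    b3 = a.conv(b3, f"{name}/b3/conv2", 96, 3, 3, padding="same")
    b4 = a.conv(prev, f"{name}/b4/conv1", 64, 1, 1)
    b4 = a.conv(b4, f"{name}/b4/conv2", 96, 3, 3, padding="same")
    b4 = a.conv(b4, f"{name}/b4/conv3", 96, 3, 3, padding="same")
    return a.concat(f"{name}/concat", [b1, b2, b3, b4])          # 384 ch


def _reduction_a(a: _Assembler, prev: str, name: str,
                 k: int, l: int, m: int, n: int) -> str:
    b1 = a.pool(prev, f"{name}/b1/maxpool", "maxpool", 3, stride=2)
    b2 = a.conv(prev, f"{name}/b2/conv", n, 3, 3, stride=2)
    b3 = a.conv(prev, f"{name}/b3/conv1", k, 1, 1)
    b3 = a.conv(b3, f"{name}/b3/conv2", l, 3, 3, padding="same")
    b3 = a.conv(b3, f"{name}/b3/conv3", m, 3, 3, stride=2)
    return a.concat(f"{name}/concat", [b1, b2, b3])


def _inception_b_v4(a: _Assembler, prev: str, name: str) -> str:
    # branch widths 128 + 384 + 256 + 256 = 1024
    b1 = a.pool(prev, f"{name}/b1/avgpool", "avgpool", 3, padding="same")
    b1 = a.conv(b1, f"{name}/b1/conv", 128, 1, 1)
    b2 = a.conv(prev, f"{name}/b2/conv", 384, 1, 1)
    b3 = a.conv(prev, f"{name}/b3/conv1", 192, 1, 1)
    b3 = a.conv(b3, f"{name}/b3/conv2", 224, 1, 7, padding="same")
    b3 = a.conv(b3, f"{name}/b3/conv3", 256, 7, 1, padding="same")
    b4 = a.conv(prev, f"{name}/b4/conv1", 192, 1, 1)
    b4 = a.conv(b4, f"{name}/b4/conv2", 192, 1, 7, padding="same")
    b4 = a.conv(b4, f"{name}/b4/conv3", 224, 7, 1, padding="same")
    b4 = a.conv(b4, f"{name}/b4/conv4", 224, 1, 7, padding="same")
    b4 = a.conv(b4, f"{name}/b4/conv5", 256, 7, 1, padding="same")
    return a.concat(f"{name}/concat", [b1, b2, b3, b4])          # 1024 ch


def _modified_inception_b(a: _Assembler, prev: str, name: str,
                          cfg: MV4BlockConfig) -> str:
    k = cfg.parallel_filter_size
    b1 = a.pool(prev, f"{name}/b1/avgpool", "avgpool", 3, padding="same")
    b1 = a.conv(b1, f"{name}/b1/conv1", cfg.avgpool_proj_filters, 1, 1)
    b1 = a.conv(b1, f"{name}/b1/conv2", cfg.avgpool_branch_filters, 3, 3, padding="same")
    b2 = a.conv(prev, f"{name}/b2/conv", cfg.direct_branch_filters, 1, 1)
    b3 = a.conv(prev, f"{name}/b3/conv1", cfg.stem_1x1_filters, 1, 1)
    p1 = a.conv(b3, f"{name}/b3/par1", cfg.parallel_branch_filters[0], k, k, padding="same")
    p2 = a.conv(b3, f"{name}/b3/par2", cfg.parallel_branch_filters[1], k, k, padding="same")
    return a.concat(f"{name}/concat", [b1, b2, p1, p2])


def _reduction_b_v4(a: _Assembler, prev: str, name: str) -> str:
    b1 = a.pool(prev, f"{name}/b1/maxpool", "maxpool", 3, stride=2)
    b2 = a.conv(prev, f"{name}/b2/conv1", 192, 1, 1)
    b2 = a.conv(b2, f"{name}/b2/conv2", 192, 3, 3, stride=2)
    b3 = a.conv(prev, f"{name}/b3/conv1", 256, 1, 1)
    b3 = a.conv(b3, f"{name}/b3/conv2", 256, 1, 7, padding="same")
    b3 = a.conv(b3, f"{name}/b3/conv3", 320, 7, 1, padding="same")
    b3 = a.conv(b3, f"{name}/b3/conv4", 320, 3, 3, stride=2)
    return a.concat(f"{name}/concat", [b1, b2, b3])              # in 1024 -> 1536


def _inception_c_v4(a: _Assembler, prev: str, name: str) -> str:
    b1 = a.pool(prev, f"{name}/b1/avgpool", "avgpool", 3, padding="same")
    b1 = a.conv(b1, f"{name}/b1/conv", 256, 1, 1)
    b2 = a.conv(prev, f"{name}/b2/conv", 256, 1, 1)
    b3 = a.conv(prev, f"{name}/b3/conv", 384, 1, 1)
    b3a = a.conv(b3, f"{name}/b3/par1", 256, 1, 3, padding="same")
    b3b = a.conv(b3, f"{name}/b3/par2", 256, 3, 1, padding="same")
    b4 = a.conv(prev, f"{name}/b4/conv1", 384, 1, 1)
    b4 = a.conv(b4, f"{name}/b4/conv2", 448, 1, 3, padding="same")
    b4 = a.conv(b4, f"{name}/b4/conv3", 512, 3, 1, padding="same")
    b4a = a.conv(b4, f"{name}/b4/par1", 256, 3, 1, padding="same")
    b4b = a.conv(b4, f"{name}/b4/par2", 256, 1, 3, padding="same")
    return a.concat(f"{name}/concat", [b1, b2, b3a, b3b, b4a, b4b])  # 1536 ch


# ---------------------------------------------------------------------------
# inception V3 blocks (canonical v3 filter geometry)


def _stem_v3(a: _Assembler, prev: str) -> str:
    s = "stem"
    x = a.conv(prev, f"{s}/conv1", 32, 3, 3, stride=2)           # 299 -> 149
    x = a.conv(x, f"{s}/conv2", 32, 3, 3)                        # -> 147
    x = a.conv(x, f"{s}/conv3", 64, 3, 3, padding="same")
    x = a.pool(x, f"{s}/maxpool1", "maxpool", 3, stride=2)       # -> 73
    x = a.conv(x, f"{s}/conv4", 80, 1, 1)
    x = a.conv(x, f"{s}/conv5", 192, 3, 3)                       # -> 71
    return a.pool(x, f"{s}/maxpool2", "maxpool", 3, stride=2)    # -> 35, 192 ch


def _inception_a_v3(a: _Assembler, prev: str, name: str, pool_proj: int) -> str:
    b1 = a.conv(prev, f"{name}/b1/conv", 64, 1, 1)
    b2 = a.conv(prev, f"{name}/b2/conv1", 48, 1, 1)
    b2 = a.conv(b2, f"{name}/b2/conv2", 64, 5, 5, padding="same")
    b3 = a.conv(prev, f"{name}/b3/conv1", 64, 1, 1)
    b3 = a.conv(b3, f"{name}/b3/conv2", 96, 3, 3, padding="same")
    b3 = a.conv(b3, f"{name}/b3/conv3", 96, 3, 3, padding="same")
    b4 = a.pool(prev, f"{name}/b4/avgpool", "avgpool", 3, padding="same")
    b4 = a.conv(b4, f"{name}/b4/conv", pool_proj, 1, 1)
    return a.concat(f"{name}/concat", [b1, b2, b3, b4])


def _reduction_a_v3(a: _Assembler, prev: str, name: str) -> str:
    b1 = a.conv(prev, f"{name}/b1/conv", 384, 3, 3, stride=2)
    b2 = a.conv(prev, f"{name}/b2/conv1", 64, 1, 1)
    b2 = a.conv(b2, f"{name}/b2/conv2", 96, 3, 3, padding="same")
    b2 = a.conv(b2, f"{name}/b2/conv3", 96, 3, 3, stride=2)
    b3 = a.pool(prev, f"{name}/b3/maxpool", "maxpool", 3, stride=2)
    return a.concat(f"{name}/concat", [b1, b2, b3])              # 288 -> 768


def _inception_b_v3(a: _Assembler, prev: str, name: str, c7: int) -> str:
    b1 = a.conv(prev, f"{name}/b1/conv", 192, 1, 1)
    b2 = a.conv(prev, f"{name}/b2/conv1", c7, 1, 1)
    b2 = a.conv(b2, f"{name}/b2/conv2", c7, 1, 7, padding="same")
    b2 = a.conv(b2, f"{name}/b2/conv3", 192, 7, 1, padding="same")
    b3 = a.conv(prev, f"{name}/b3/conv1", c7, 1, 1)
    b3 = a.conv(b3, f"{name}/b3/conv2", c7, 7, 1, padding="same")
    b3 = a.conv(b3, f"{name}/b3/conv3", c7, 1, 7, padding="same")
    b3 = a.conv(b3, f"{name}/b3/conv4", c7, 7, 1, padding="same")
    b3 = a.conv(b3, f"{name}/b3/conv5", 192, 1, 7, padding="same")
    b4 = a.pool(prev, f"{name}/b4/avgpool", "avgpool", 3, padding="same")
    b4 = a.conv(b4, f"{name}/b4/conv", 192, 1, 1)
    return a.concat(f"{name}/concat", [b1, b2, b3, b4])          # 768 ch


def _reduction_b_v3(a: _Assembler, prev: str, name: str) -> str:
    b1 = a.conv(prev, f"{name}/b1/conv1", 192, 1, 1)
    b1 = a.conv(b1, f"{name}/b1/conv2", 320, 3, 3, stride=2)
    b2 = a.conv(prev, f"{name}/b2/conv1", 192, 1, 1)
    b2 = a.conv(b2, f"{name}/b2/conv2", 192, 1, 7, padding="same")
    b2 = a.conv(b2, f"{name}/b2/conv3", 192, 7, 1, padding="same")
    b2 = a.conv(b2, f"{name}/b2/conv4", 192, 3, 3, stride=2)
    b3 = a.pool(prev, f"{name}/b3/maxpool", "maxpool", 3, stride=2)
    return a.concat(f"{name}/concat", [b1, b2, b3])              # 768 -> 1280


def _inception_c_v3(a: _Assembler, prev: str, name: str) -> str:
    b1 = a.conv(prev, f"{name}/b1/conv", 320, 1, 1)
    b2 = a.conv(prev, f"{name}/b2/conv", 384, 1, 1)
    b2a = a.conv(b2, f"{name}/b2/par1", 384, 1, 3, padding="same")
    b2b = a.conv(b2, f"{name}/b2/par2", 384, 3, 1, padding="same")
    b3 = a.conv(prev, f"{name}/b3/conv1", 448, 1, 1)
    b3 = a.conv(b3, f"{name}/b3/conv2", 384, 3, 3, padding="same")
    b3a = a.conv(b3, f"{name}/b3/par1", 384, 1, 3, padding="same")
    b3b = a.conv(b3, f"{name}/b3/par2", 384, 3, 1, padding="same")
    b4 = a.pool(prev, f"{name}/b4/avgpool", "avgpool", 3, padding="same")
    b4 = a.conv(b4, f"{name}/b4/conv", 192, 1, 1)
    return a.concat(f"{name}/concat", [b1, b2a, b2b, b3a, b3b, b4])  # 2048 ch


# ---------------------------------------------------------------------------
# heads and whole networks


def attach_head(graph: NetworkGraph, head: HeadSpec, prev: str,
                ws=lambda w: w) -> str:
    """Append the classifier head after node ``prev``.  Dense widths are
    never scaled: the binary output stays two units wide."""
    for i, op in enumerate(head.ops):
        name = f"head/{i}_{op[0]}"
        if op[0] == "global_avg_pool":
            prev = graph.chain(prev, LayerNode(name, "global_avg_pool"))
        elif op[0] == "dropout":
            prev = graph.chain(prev, LayerNode(name, "dropout", dropout_rate=op[1]))
        elif op[0] == "dense":
            prev = graph.chain(prev, LayerNode(name, "dense", num_filters=op[1]))
        elif op[0] == "softmax":
            prev = graph.chain(prev, LayerNode(name, "softmax"))
        elif op[0] == "classification":
            prev = graph.chain(prev, LayerNode(name, "classification"))
    return prev


def _finish(graph: NetworkGraph, input_shape: TensorShape) -> NetworkGraph:
    graph.validate()
    graph.infer_shapes(input_shape)  # raises on invalid geometry
    return graph


def build_inception_v4(
    input_shape: TensorShape | None = None,
    head: HeadSpec | None = None,
    width_scale: float = 1.0,
    block_repeats: tuple[int, int, int] = FULL_BLOCK_REPEATS,
) -> NetworkGraph:
    """Stem, 4 inception-A, reduction-A, 7 inception-B, reduction-B,
    3 inception-C, head; 1536 features enter the head at full width.
    ``block_repeats`` overrides the A/B/C repeat counts for scaled
    variants."""
    input_shape = input_shape or DEFAULT_INPUT
    head = head or default_v4_head()
    ws = _scaler(width_scale)
    na, nb, nc = block_repeats
    g = NetworkGraph("inception_v4")
    a = _Assembler(g, ws)
    x = g.add_node(LayerNode("input", "input"))
    x = _stem_v4(a, x)
    for i in range(1, na + 1):
        x = _inception_a_v4(a, x, f"inception_a{i}")
    x = _reduction_a(a, x, "reduction_a", 192, 224, 256, 384)
    for i in range(1, nb + 1):
        x = _inception_b_v4(a, x, f"inception_b{i}")
    x = _reduction_b_v4(a, x, "reduction_b")
    for i in range(1, nc + 1):
        x = _inception_c_v4(a, x, f"inception_c{i}")
    attach_head(g, head, x)
    return _finish(g, input_shape)


def build_inception_mv4(
    input_shape: TensorShape | None = None,
    head: HeadSpec | None = None,
    block_config: MV4BlockConfig | None = None,
    width_scale: float = 1.0,
    block_repeats: tuple[int, int, int] = FULL_BLOCK_REPEATS,
) -> NetworkGraph:
    """Identical to V4 except all 7 inception-B blocks are replaced by the
    modified block, each preserving 1024 concatenated output features
    under the default :class:`MV4BlockConfig`."""
    input_shape = input_shape or DEFAULT_INPUT
    head = head or default_v4_head()
    cfg = block_config or MV4BlockConfig()
    ws = _scaler(width_scale)
    na, nb, nc = block_repeats
    g = NetworkGraph("inception_mv4")
    a = _Assembler(g, ws)
    x = g.add_node(LayerNode("input", "input"))
    x = _stem_v4(a, x)
    for i in range(1, na + 1):
        x = _inception_a_v4(a, x, f"inception_a{i}")
    x = _reduction_a(a, x, "reduction_a", 192, 224, 256, 384)
    for i in range(1, nb + 1):
        x = _modified_inception_b(a, x, f"inception_b{i}", cfg)
    x = _reduction_b_v4(a, x, "reduction_b")
    for i in range(1, nc + 1):
        x = _inception_c_v4(a, x, f"inception_c{i}")
    attach_head(g, head, x)
    return _finish(g, input_shape)


def build_inception_v3(
    input_shape: TensorShape | None = None,
    head: HeadSpec | None = None,
    width_scale: float = 1.0,
) -> NetworkGraph:
    """Stem, 3 inception-A, reduction-A, 4 inception-B, reduction-B,
    2 inception-C, head; 2048 features enter the head at full width."""
    input_shape = input_shape or DEFAULT_INPUT
    head = head or default_v3_head()
    ws = _scaler(width_scale)
    g = NetworkGraph("inception_v3")
    a = _Assembler(g, ws)
    x = g.add_node(LayerNode("input", "input"))
    x = _stem_v3(a, x)
    for i, proj in enumerate((32, 64, 64), start=1):
        x = _inception_a_v3(a, x, f"inception_a{i}", proj)
    x = _reduction_a_v3(a, x, "reduction_a")
    for i, c7 in enumerate((128, 160, 160, 192), start=1):
        x = _inception_b_v3(a, x, f"inception_b{i}", c7)
    x = _reduction_b_v3(a, x, "reduction_b")
    for i in range(1, 3):
        x = _inception_c_v3(a, x, f"inception_c{i}")
    attach_head(g, head, x)
    return _finish(g, input_shape)


def make_modified_inception_b(
    block_config: MV4BlockConfig | None = None,
    in_channels: int = 1024,
    width_scale: float = 1.0,
) -> NetworkGraph:
    """Standalone modified inception-B fragment (input node -> branches ->
    concat).  ``in_channels`` documents the expected input width; the
    fragment itself is structural and shape inference supplies channels."""
    if in_channels < 1:
        raise ValueError("in_channels must be >= 1")
    cfg = block_config or MV4BlockConfig()
    g = NetworkGraph("custom")
    a = _Assembler(g, _scaler(width_scale))
    x = g.add_node(LayerNode("input", "input"))
    _modified_inception_b(a, x, "modified_b", cfg)
    g.validate(fragment=True)
    return g


def make_canonical_inception_b(width_scale: float = 1.0) -> NetworkGraph:
    """Standalone canonical inception-B fragment, for side-by-side
    comparison with the modified block."""
    g = NetworkGraph("custom")
    a = _Assembler(g, _scaler(width_scale))
    x = g.add_node(LayerNode("input", "input"))
    _inception_b_v4(a, x, "canonical_b")
    g.validate(fragment=True)
    return g


def count_inception_b_blocks(graph: NetworkGraph) -> int:
    stages = {n.stage for n in graph.nodes.values()}
    return sum(1 for s in stages if s.startswith("inception_b"))


def build_model(
    name: str,
    input_shape: TensorShape | None = None,
    head: HeadSpec | None = None,
    block_config: MV4BlockConfig | None = None,
) -> NetworkGraph:
    """Build a registered model by name; ``tiny-*`` variants preserve the
    block topology but scale filter counts by ``TINY_WIDTH_SCALE`` and
    default the input to ``TINY_SIDE`` x ``TINY_SIDE`` x 3."""
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    tiny = name.startswith("tiny-")
    scale = TINY_WIDTH_SCALE if tiny else 1.0
    if tiny and input_shape is None:
        input_shape = TensorShape(TINY_SIDE, TINY_SIDE, 3)
    if tiny and head is None:
        # tiny heads drop the 0.8-dropout: at reduced width the pooled
        # feature vector is a few hundred entries and an 80% drop rate
        # starves 3-epoch from-scratch training (full-width heads keep it).
        head = default_v3_head()
    repeats = TINY_BLOCK_REPEATS if tiny else FULL_BLOCK_REPEATS
    base = name.removeprefix("tiny-")
    if base == "v3":
        return build_inception_v3(input_shape, head, width_scale=scale)
    if base == "v4":
        return build_inception_v4(input_shape, head, width_scale=scale,
                                  block_repeats=repeats)
    return build_inception_mv4(input_shape, head, block_config,
                               width_scale=scale, block_repeats=repeats)
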