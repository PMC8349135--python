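"""Layer graphs for inception-style convolutional networks.

A :class:`NetworkGraph` is a directed acyclic graph of typed
:class:`LayerNode` objects — the common in-memory representation for the
inception V3, V4 and MV4 architectures built by :mod:`thermonet.builders`.
The module provides shape inference (the classic convolution output-size
rule ``floor((W - F + 2P) / S) + 1``), analytic parameter counting,
multiply-accumulate (FLOP) estimation, prefix freezing for transfer
learning, and a canonical JSON serialization under which graph isomorphism
reduces to string equality.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

__all__ = [
    "LayerNode",
    "TensorShape",
    "NetworkGraph",
    "ArchitectureSummary",
    "ParameterCount",
    "GeometryError",
    "ShapeConflictError",
    "GraphValidationError",
    "conv_output_size",
]

#: Node kinds understood by the graph machinery.
KINDS = frozenset(
    {
        "input",
        "conv",
        "batchnorm",
        "activation",
        "maxpool",
        "avgpool",
        "concat",
        "dropout",
        "global_avg_pool",
        "dense",
        "softmax",
        "classification",
    }
)

_WINDOWED = frozenset({"conv", "maxpool", "avgpool"})
_IDENTITY_KINDS = frozenset(
    {"batchnorm", "activation", "dropout", "softmax", "classification"}
)


class GeometryError(ValueError):
    """Invalid convolution/pooling geometry (non-positive output, bad args)."""


class ShapeConflictError(ValueError):
    """Incompatible tensor shapes meeting at a node (e.g. a concat)."""


class GraphValidationError(ValueError):
    """Structural violation of the layer-graph invariants."""


def _require_int(value, name: str) -> int:
    if isinstance(value, bool) or not isinstance(value, (int,)):
        # numpy integers pass through via __index__
        try:
            if isinstance(value, bool):
                raise TypeError
            return int(value.__index__())
        except (AttributeError, TypeError):
            raise GeometryError(f"{name} must be an integer, got {value!r}") from None
    return int(value)


def conv_output_size(input_size: int, filter_size: int, padding: int, stride: int) -> int:
    """Spatial output size of a convolution or pooling window.

    Implements ``floor((W - F + 2P) / S) + 1`` for input size ``W``, filter
    size ``F``, symmetric padding ``P`` and stride ``S``.  A non-integer
    quotient is permitted with floor semantics and a warning.  A
    non-positive result raises :class:`GeometryError` naming the offending
    dimension.
    """
    w = _require_int(input_size, "input_size")
    f = _require_int(filter_size, "filter_size")
    p = _require_int(padding, "padding")
    s = _require_int(stride, "stride")
    if f < 1:
        raise GeometryError(f"filter_size must be >= 1, got {f}")
    if s < 1:
        raise GeometryError(f"stride must be >= 1, got {s}")
    if p < 0:
        raise GeometryError(f"padding must be >= 0, got {p}")
    numerator = w - f + 2 * p
    if numerator < 0:
        raise GeometryError(
            f"input_size {w} is smaller than filter_size {f} minus twice padding {p}"
        )
    if numerator % s != 0:
        warnings.warn(
            f"({w} - {f} + 2*{p}) = {numerator} is not divisible by stride {s}; "
            "taking the floor",
            stacklevel=2,
        )
    out = numerator // s + 1
    if out < 1:
        raise GeometryError(f"non-positive output size {out} for input_size {w}")
    return out


@dataclass(frozen=True, order=True)
class TensorShape:
    """A height x width x channels activation shape."""

    height: int
    width: int
    channels: int

    def __post_init__(self):
        for name in ("height", "width", "channels"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or v < 1:
                raise GeometryError(f"TensorShape.{name} must be a positive integer, got {v!r}")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.height, self.width, self.channels)

    def __str__(self) -> str:  # 299x299x3
        return f"{self.height}x{self.width}x{self.channels}"


@dataclass
class LayerNode:
    """One typed node of a :class:`NetworkGraph`.

    ``filter_height``/``filter_width``/``stride``/``padding`` apply to conv
    and pooling nodes; ``num_filters`` to conv and dense nodes;
    ``dropout_rate`` exactly to dropout nodes.  ``padding`` is either a
    non-negative pixel count or the string ``"same"`` (stride-1 only).
    """

    id: str
    kind: str
    filter_height: int | None = None
    filter_width: int | None = None
    num_filters: int | None = None
    stride: int = 1
    padding: int | str = 0
    dropout_rate: float | None = None
    trainable: bool = True

    def __post_init__(self):
        if self.kind not in KINDS:
            raise GraphValidationError(f"unknown node kind {self.kind!r} for node {self.id!r}")
        if self.kind in _WINDOWED:
            if self.filter_height is None or self.filter_width is None:
                raise GraphValidationError(f"{self.kind} node {self.id!r} needs filter dims")
            if self.filter_height < 1 or self.filter_width < 1 or self.stride < 1:
                raise GeometryError(
                    f"{self.kind} node {self.id!r} requires filter dims >= 1 and stride >= 1"
                )
        if self.kind in ("conv", "dense"):
            if self.num_filters is None or self.num_filters < 1:
                raise GraphValidationError(
                    f"{self.kind} node {self.id!r} requires num_filters >= 1"
                )
        if (self.dropout_rate is not None) != (self.kind == "dropout"):
            raise GraphValidationError(
                f"dropout_rate must be present iff kind is dropout (node {self.id!r})"
            )
        if self.kind == "dropout" and not (0.0 <= self.dropout_rate <= 1.0):
            raise GraphValidationError(f"dropout_rate out of [0, 1] on node {self.id!r}")
        if isinstance(self.padding, str) and self.padding != "same":
            raise GraphValidationError(f"padding must be an int or 'same' (node {self.id!r})")
        if isinstance(self.padding, int) and self.padding < 0:
            raise GeometryError(f"negative padding on node {self.id!r}")

    @property
    def stage(self) -> str:
        """Stage name: the id prefix before the first '/'."""
        return self.id.split("/", 1)[0]

    def pad_for(self, size: int, axis_filter: int) -> int:
        """Resolve symmetric padding in pixels for one spatial axis."""
        if self.padding == "same":
            if self.stride != 1:
                raise GeometryError(
                    f"'same' padding with stride {self.stride} unsupported (node {self.id!r})"
                )
            return (axis_filter - 1) // 2 + ((axis_filter - 1) % 2)  # total//2 rounded up == F-1 even split below
        return self.padding


@dataclass(frozen=True)
class ParameterCount:
    total: int
    trainable: int


@dataclass(frozen=True)
class ArchitectureSummary:
    """Descriptive metadata of a built graph.

    ``layer_count`` follows the documented convention that every node of
    every kind counts as one layer; published counts produced by other
    toolboxes use their own (undocumented) conventions and are therefore
    not comparable.
    """

    name: str
    layer_count: int
    connection_count: int
    parameter_count: int
    trainable_parameter_count: int
    per_stage_output_shapes: tuple[tuple[str, TensorShape], ...]
    flops_estimate: int

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "layer_count": self.layer_count,
            "connection_count": self.connection_count,
            "parameter_count": self.parameter_count,
            "trainable_parameter_count": self.trainable_parameter_count,
            "per_stage_output_shapes": [
                [stage, list(shape.as_tuple())] for stage, shape in self.per_stage_output_shapes
            ],
            "flops_estimate": self.flops_estimate,
        }


class NetworkGraph:
    """Directed acyclic layer graph with one input and one terminal node.

    Nodes are stored in insertion order; edges are (from-id, to-id) pairs.
    Fragments (e.g. a single inception block) may be validated with
    ``fragment=True``, which waives the terminal-classification rule.
    """

    def __init__(self, name: str = "custom"):
        self.name = name
        self.nodes: dict[str, LayerNode] = {}
        self.edges: list[tuple[str, str]] = []
        self.input_id: str | None = None
        self.output_id: str | None = None

    # -- construction -------------------------------------------------

    def add_node(self, node: LayerNode) -> str:
        if node.id in self.nodes:
            raise GraphValidationError(f"duplicate node id {node.id!r}")
        self.nodes[node.id] = node
        if node.kind == "input":
            if self.input_id is not None:
                raise GraphValidationError("graph already has an input node")
            self.input_id = node.id
        self.output_id = node.id
        return node.id

    def add_edge(self, src: str, dst: str) -> None:
        for nid in (src, dst):
            if nid not in self.nodes:
                raise GraphValidationError(f"edge endpoint {nid!r} is not a node")
        self.edges.append((src, dst))

    def chain(self, prev: str, node: LayerNode) -> str:
        """Append ``node`` after ``prev`` and return the new node id."""
        nid = self.add_node(node)
        self.add_edge(prev, nid)
        return nid

    # -- structure ----------------------------------------------------

    def predecessors(self) -> dict[str, list[str]]:
        preds: dict[str, list[str]] = {nid: [] for nid in self.nodes}
        for src, dst in self.edges:
            preds[dst].append(src)
        return preds

    def successors(self) -> dict[str, list[str]]:
        succ: dict[str, list[str]] = {nid: [] for nid in self.nodes}
        for src, dst in self.edges:
            succ[src].append(dst)
        return succ

    def topological_order(self) -> list[str]:
        preds = self.predecessors()
        succ = self.successors()
        indeg = {nid: len(p) for nid, p in preds.items()}
        ready = [nid for nid in self.nodes if indeg[nid] == 0]  # insertion order
        order: list[str] = []
        while ready:
            nid = ready.pop(0)
            order.append(nid)
            for nxt in succ[nid]:
                indeg[nxt] -= 1
                if indeg[nxt] == 0:
                    ready.append(nxt)
        if len(order) != len(self.nodes):
            raise GraphValidationError("graph contains a cycle")
        return order

    def conv_ids_topological(self) -> list[str]:
        return [nid for nid in self.topological_order() if self.nodes[nid].kind == "conv"]

    def validate(self, fragment: bool = False) -> None:
        if self.input_id is None:
            raise GraphValidationError("graph has no input node")
        preds = self.predecessors()
        order = self.topological_order()  # raises on cycles
        n_inputs = sum(1 for n in self.nodes.values() if n.kind == "input")
        if n_inputs != 1:
            raise GraphValidationError(f"expected exactly one input node, found {n_inputs}")
        for nid, node in self.nodes.items():
            deg = len(preds[nid])
            if node.kind == "input":
                if deg != 0:
                    raise GraphValidationError(f"input node {nid!r} has in-degree {deg}")
            elif node.kind == "concat":
                if deg < 2:
                    raise GraphValidationError(f"concat node {nid!r} has in-degree {deg} < 2")
            elif deg != 1:
                raise GraphValidationError(f"node {nid!r} has in-degree {deg}, expected 1")
        # reachability from the input
        reach = {self.input_id}
        succ = self.successors()
        stack = [self.input_id]
        while stack:
            for nxt in succ[stack.pop()]:
                if nxt not in reach:
                    reach.add(nxt)
                    stack.append(nxt)
        unreachable = set(self.nodes) - reach
        if unreachable:
            raise GraphValidationError(f"nodes unreachable from input: {sorted(unreachable)}")
        if not fragment:
            terminals = [nid for nid in self.nodes if not succ[nid]]
            if len(terminals) != 1 or self.nodes[terminals[0]].kind != "classification":
                raise GraphValidationError(
                    "graph must end in exactly one terminal classification node"
                )
            self.output_id = terminals[0]

    # -- shape inference ----------------------------------------------

    def infer_shapes(self, input_shape: TensorShape) -> dict[str, TensorShape]:
        """Map every node id to its output :class:`TensorShape`.

        Conv and pooling nodes follow the output-size rule per spatial
        axis; concat nodes sum channels and require identical spatial
        dims; ``global_avg_pool`` maps HxWxC to 1x1xC; dense nodes require
        a 1x1 spatial input (i.e. they sit after global pooling).
        """
        preds = self.predecessors()
        shapes: dict[str, TensorShape] = {}
        for nid in self.topological_order():
            node = self.nodes[nid]
            if node.kind == "input":
                shapes[nid] = input_shape
                continue
            in_shapes = [shapes[p] for p in preds[nid]]
            if node.kind == "concat":
                h, w = in_shapes[0].height, in_shapes[0].width
                for s in in_shapes[1:]:
                    if (s.height, s.width) != (h, w):
                        raise ShapeConflictError(
                            f"spatial mismatch at concat node {nid!r}: "
                            f"{s.height}x{s.width} vs {h}x{w}"
                        )
                shapes[nid] = TensorShape(h, w, sum(s.channels for s in in_shapes))
                continue
            s = in_shapes[0]
            if node.kind in _WINDOWED:
                ph = node.pad_for(s.height, node.filter_height)
                pw = node.pad_for(s.width, node.filter_width)
                if node.padding == "same":
                    h, w = s.height, s.width
                else:
                    try:
                        h = conv_output_size(s.height, node.filter_height, ph, node.stride)
                        w = conv_output_size(s.width, node.filter_width, pw, node.stride)
                    except GeometryError as exc:
                        raise GeometryError(f"node {nid!r}: {exc}") from exc
                c = node.num_filters if node.kind == "conv" else s.channels
                shapes[nid] = TensorShape(h, w, c)
            elif node.kind == "global_avg_pool":
                shapes[nid] = TensorShape(1, 1, s.channels)
            elif node.kind == "dense":
                if (s.height, s.width) != (1, 1):
                    raise ShapeConflictError(
                        f"dense node {nid!r} requires 1x1 spatial input, got {s}"
                    )
                shapes[nid] = TensorShape(1, 1, node.num_filters)
            elif node.kind in _IDENTITY_KINDS:
                shapes[nid] = s
            else:  # pragma: no cover - kinds are closed
                raise GraphValidationError(f"cannot infer shape for kind {node.kind!r}")
        return shapes

    # -- analytics ----------------------------------------------------

    def count_parameters(
        self,
        input_shape: TensorShape,
        include_batchnorm: bool = True,
        include_bias: bool = True,
    ) -> ParameterCount:
        """Analytic parameter totals.

        conv: Fh*Fw*Cin*Cout (+Cout bias if ``include_bias``);
        dense: Cin*Cout + Cout; batchnorm: 2*C trainable scale/shift plus
        2*C non-trainable running statistics when ``include_batchnorm``;
        all other kinds contribute nothing.  Frozen nodes are counted in
        the total but excluded from the trainable count.
        """
        shapes = self.infer_shapes(input_shape)
        preds = self.predecessors()
        total = 0
        trainable = 0
        for nid, node in self.nodes.items():
            if node.kind == "conv":
                cin = shapes[preds[nid][0]].channels
                n = node.filter_height * node.filter_width * cin * node.num_filters
                if include_bias:
                    n += node.num_filters
            elif node.kind == "dense":
                cin = shapes[preds[nid][0]].channels
                n = cin * node.num_filters + node.num_filters
            elif node.kind == "batchnorm":
                if not include_batchnorm:
                    continue
                c = shapes[preds[nid][0]].channels
                total += 2 * c  # running mean/var, never trainable
                n = 2 * c
            else:
                continue
            total += n
            if node.trainable:
                trainable += n
        return ParameterCount(total=total, trainable=trainable)

    def estimate_flops(self, input_shape: TensorShape) -> int:
        """Multiply-accumulate estimate: conv Hout*Wout*Fh*Fw*Cin*Cout; dense Cin*Cout."""
        shapes = self.infer_shapes(input_shape)
        preds = self.predecessors()
        macs = 0
        for nid, node in self.nodes.items():
            if node.kind == "conv":
                out = shapes[nid]
                cin = shapes[preds[nid][0]].channels
                macs += (
                    out.height
                    * out.width
                    * node.filter_height
                    * node.filter_width
                    * cin
                    * node.num_filters
                )
            elif node.kind == "dense":
                macs += shapes[preds[nid][0]].channels * node.num_filters
        return macs

    def summarize(self, input_shape: TensorShape) -> ArchitectureSummary:
        shapes = self.infer_shapes(input_shape)
        params = self.count_parameters(input_shape)
        stage_shapes: dict[str, TensorShape] = {}
        stage_order: list[str] = []
        for nid in self.topological_order():
            stage = self.nodes[nid].stage
            if stage not in stage_shapes:
                stage_order.append(stage)
            stage_shapes[stage] = shapes[nid]
        return ArchitectureSummary(
            name=self.name,
            layer_count=len(self.nodes),
            connection_count=len(self.edges),
            parameter_count=params.total,
            trainable_parameter_count=params.trainable,
            per_stage_output_shapes=tuple((s, stage_shapes[s]) for s in stage_order),
            flops_estimate=self.estimate_flops(input_shape),
        )

    # -- transfer-learning helpers ------------------------------------

    def freeze_prefix(self, n_convs: int) -> "NetworkGraph":
        """Return a copy with the first ``n_convs`` conv nodes (topological
        order) marked non-trainable."""
        conv_ids = self.conv_ids_topological()
        if n_convs < 0 or n_convs > len(conv_ids):
            raise ValueError(
                f"n_convs={n_convs} out of range: graph has {len(conv_ids)} conv nodes"
            )
        frozen = set(conv_ids[:n_convs])
        return self._with_trainability(lambda node: node.id not in frozen and node.trainable)

    def freeze_region(self, stage_prefix: str) -> "NetworkGraph":
        """Freeze every node whose stage name starts with ``stage_prefix``
        (e.g. ``"stem"``).  Freezing, not zero-initialization, is how the
        package realizes 'stem weights fixed during fine-tuning'."""
        return self._with_trainability(
            lambda node: not node.stage.startswith(stage_prefix) and node.trainable
        )

    def _with_trainability(self, keep) -> "NetworkGraph":
        g = NetworkGraph(self.name)
        for node in self.nodes.values():
            g.add_node(replace(node, trainable=bool(keep(node))))
        g.edges = list(self.edges)
        g.input_id = self.input_id
        g.output_id = self.output_id
        return g

    # -- serialization ------------------------------------------------

    def to_json(self) -> str:
        """Canonical serialization: sorted node ids, sorted edges, stable
        key order.  Two isomorphic builds serialize to identical strings."""
        doc = {
            "name": self.name,
            "input_id": self.input_id,
            "output_id": self.output_id,
            "nodes": [
                {
                    "id": n.id,
                    "kind": n.kind,
                    "filter_height": n.filter_height,
                    "filter_width": n.filter_width,
                    "num_filters": n.num_filters,
                    "stride": n.stride,
                    "padding": n.padding,
                    "dropout_rate": n.dropout_rate,
                    "trainable": n.trainable,
                }
                for _, n in sorted(self.nodes.items())
            ],
            "edges": sorted(self.edges),
        }
        return json.dumps(doc, indent=1, sort_keys=False)

    @classmethod
    def from_json(cls, text: str) -> "NetworkGraph":
        doc = json.loads(text)
        g = cls(doc["name"])
        for nd in doc["nodes"]:
            nd = dict(nd)
            g.nodes[nd["id"]] = LayerNode(**nd)
        g.input_id = doc["input_id"]
        g.output_id = doc["output_id"]
        g.edges = [tuple(e) for e in doc["edges"]]
        return g

    def __repr__(self) -> str:
        return f"NetworkGraph({self.name!r}, {len(self.nodes)} nodes, {len(self.edges)} edges)"
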