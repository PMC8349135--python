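"""A NumPy forward/backward executor for :class:`~thermonet.graph.NetworkGraph`.

Executes a layer graph on NHWC float32 tensors: im2col convolutions,
batch normalization with running statistics, ReLU, max/average pooling,
channel concatenation, inverted dropout, global average pooling, dense
layers and a softmax/cross-entropy output.  Gradients are computed by
reverse-mode accumulation over the reverse topological order, so arbitrary
DAGs (multi-branch inception blocks) are handled uniformly.

The executor is deliberately plain: single process, no threads of its own,
every random draw (initialization, dropout) taken from one seeded
generator — which makes training runs bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .graph import NetworkGraph, TensorShape

__all__ = ["NetworkExecutor", "SGDM", "Adam", "RMSProp", "make_optimizer"]

_EPS = 1e-5  # batchnorm variance floor


def _pad_amounts(filter_size: int, padding) -> tuple[int, int]:
    if padding == "same":
        total = filter_size - 1
        return total // 2, total - total // 2
    return padding, padding


def _windows(xp: np.ndarray, fh: int, fw: int, stride: int) -> np.ndarray:
    """(N, Ho, Wo, fh, fw, C) view of padded input ``xp``."""
    win = sliding_window_view(xp, (fh, fw), axis=(1, 2))  # (N, H', W', C, fh, fw)
    win = win[:, ::stride, ::stride]
    return np.ascontiguousarray(np.moveaxis(win, 3, 5))


class NetworkExecutor:
    """Materialized weights plus forward/backward passes for one graph."""

    def __init__(
        self,
        graph: NetworkGraph,
        input_shape: TensorShape,
        rng: np.random.Generator,
        dtype=np.float32,
    ):
        graph.validate(fragment=(graph.output_id is None))
        self.graph = graph
        self.input_shape = input_shape
        self.dtype = dtype
        self.order = graph.topological_order()
        self.preds = graph.predecessors()
        self.shapes = graph.infer_shapes(input_shape)
        self.params: dict[str, dict[str, np.ndarray]] = {}
        self.bn_state: dict[str, dict[str, np.ndarray]] = {}
        self.bn_momentum = 0.9
        self._init_params(rng)

    # -- initialization ------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> None:
        for nid in self.order:
            node = self.graph.nodes[nid]
            cin = self.shapes[self.preds[nid][0]].channels if self.preds[nid] else None
            if node.kind == "conv":
                fan_in = node.filter_height * node.filter_width * cin
                w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                               size=(fan_in, node.num_filters))
                self.params[nid] = {"w": w.astype(self.dtype)}
            elif node.kind == "dense":
                w = rng.normal(0.0, np.sqrt(2.0 / cin), size=(cin, node.num_filters))
                self.params[nid] = {
                    "w": w.astype(self.dtype),
                    "b": np.zeros(node.num_filters, dtype=self.dtype),
                }
            elif node.kind == "batchnorm":
                c = self.shapes[nid].channels
                self.params[nid] = {
                    "gamma": np.ones(c, dtype=self.dtype),
                    "beta": np.zeros(c, dtype=self.dtype),
                }
                self.bn_state[nid] = {
                    "mean": np.zeros(c, dtype=self.dtype),
                    "var": np.ones(c, dtype=self.dtype),
                }

    def parameter_vector_size(self) -> int:
        return sum(int(a.size) for p in self.params.values() for a in p.values())

    def state_digest(self) -> bytes:
        """Concatenated little-endian bytes of all weights and BN stats —
        for bit-reproducibility checks."""
        chunks = []
        for nid in sorted(self.params):
            for key in sorted(self.params[nid]):
                chunks.append(self.params[nid][key].astype("<f4").tobytes())
        for nid in sorted(self.bn_state):
            for key in sorted(self.bn_state[nid]):
                chunks.append(self.bn_state[nid][key].astype("<f4").tobytes())
        return b"".join(chunks)

    # -- forward -------------------------------------------------------

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Run the graph on a (N, H, W, C) batch; returns (probs, cache)."""
        acts: dict[str, np.ndarray] = {}
        cache: dict[str, dict] = {"__acts__": acts}
        for nid in self.order:
            node = self.graph.nodes[nid]
            ins = [acts[p] for p in self.preds[nid]]
            if node.kind == "input":
                acts[nid] = np.asarray(x, dtype=self.dtype)
                continue
            xin = ins[0] if ins else None
            if node.kind == "conv":
                acts[nid], cache[nid] = self._conv_forward(node, xin)
            elif node.kind == "batchnorm":
                acts[nid], cache[nid] = self._bn_forward(nid, node, xin, training)
            elif node.kind == "activation":
                acts[nid] = np.maximum(xin, 0)
                cache[nid] = {"mask": acts[nid] > 0}
            elif node.kind == "maxpool":
                acts[nid], cache[nid] = self._pool_forward(node, xin, "max")
            elif node.kind == "avgpool":
                acts[nid], cache[nid] = self._pool_forward(node, xin, "avg")
            elif node.kind == "concat":
                acts[nid] = np.concatenate(ins, axis=-1)
                cache[nid] = {"splits": [a.shape[-1] for a in ins]}
            elif node.kind == "dropout":
                # active only when a generator is supplied: the BN
                # recalibration pass runs training-mode without one and
                # keeps dropout off
                if training and node.dropout_rate > 0 and rng is not None:
                    keep = 1.0 - node.dropout_rate
                    mask = (rng.random(xin.shape) < keep).astype(self.dtype) / keep
                    acts[nid] = xin * mask
                    cache[nid] = {"mask": mask}
                else:
                    acts[nid] = xin
                    cache[nid] = {"mask": None}
            elif node.kind == "global_avg_pool":
                acts[nid] = xin.mean(axis=(1, 2))
                cache[nid] = {"hw": xin.shape[1:3]}
            elif node.kind == "dense":
                p = self.params[nid]
                acts[nid] = xin @ p["w"] + p["b"]
                cache[nid] = {"x": xin}
            elif node.kind == "softmax":
                z = xin - xin.max(axis=-1, keepdims=True)
                e = np.exp(z)
                probs = e / e.sum(axis=-1, keepdims=True)
                acts[nid] = probs
                cache[nid] = {"probs": probs}
            elif node.kind == "classification":
                acts[nid] = xin
        return acts[self.order[-1]], cache

    def _conv_forward(self, node, x):
        ph = _pad_amounts(node.filter_height, node.padding)
        pw = _pad_amounts(node.filter_width, node.padding)
        xp = np.pad(x, ((0, 0), ph, pw, (0, 0)))
        win = _windows(xp, node.filter_height, node.filter_width, node.stride)
        n, ho, wo = win.shape[:3]
        cols = win.reshape(n * ho * wo, -1)
        out = (cols @ self.params[node.id]["w"]).reshape(n, ho, wo, -1)
        return out, {"cols": cols, "xp_shape": xp.shape, "ph": ph, "pw": pw,
                     "out_hw": (ho, wo)}

    def _bn_forward(self, nid, node, x, training):
        p = self.params[nid]
        state = self.bn_state[nid]
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.bn_momentum
            state["mean"] = (m * state["mean"] + (1 - m) * mean).astype(self.dtype)
            state["var"] = (m * state["var"] + (1 - m) * var).astype(self.dtype)
        else:
            mean, var = state["mean"], state["var"]
        invstd = 1.0 / np.sqrt(var + _EPS)
        xhat = (x - mean) * invstd
        out = xhat * p["gamma"] + p["beta"]
        return out.astype(self.dtype), {
            "xhat": xhat.astype(self.dtype),
            "invstd": invstd.astype(self.dtype),
            "training": training,
        }

    def _pool_forward(self, node, x, mode):
        fh, fw, s = node.filter_height, node.filter_width, node.stride
        ph = _pad_amounts(fh, node.padding)
        pw = _pad_amounts(fw, node.padding)
        fill = -np.inf if mode == "max" else 0.0
        xp = np.pad(x, ((0, 0), ph, pw, (0, 0)), constant_values=fill)
        win = _windows(xp, fh, fw, s)  # (N, Ho, Wo, fh, fw, C)
        n, ho, wo = win.shape[:3]
        flat = win.reshape(n, ho, wo, fh * fw, -1)
        if mode == "max":
            amax = flat.argmax(axis=3)
            out = np.take_along_axis(flat, amax[:, :, :, None, :], axis=3)[:, :, :, 0, :]
            extra = {"amax": amax}
        else:
            out = flat.mean(axis=3)
            extra = {}
        return out.astype(self.dtype), {
            "xp_shape": xp.shape, "ph": ph, "pw": pw, "out_hw": (ho, wo), **extra
        }

    # -- backward ------------------------------------------------------

    def backward(self, cache: dict, labels_onehot: np.ndarray) -> dict[str, dict]:
        """Cross-entropy gradient of every trainable parameter.

        ``labels_onehot`` is (N, num_classes); the loss is the mean
        cross-entropy over the batch, seeded into the softmax node as
        (probs - labels) / N.
        """
        acts = cache["__acts__"]
        n = labels_onehot.shape[0]
        grads: dict[str, dict] = {}
        dacc: dict[str, np.ndarray | None] = {nid: None for nid in self.order}

        def _add(nid, g):
            dacc[nid] = g if dacc[nid] is None else dacc[nid] + g

        for nid in reversed(self.order):
            node = self.graph.nodes[nid]
            preds = self.preds[nid]
            if node.kind == "classification":
                if dacc[nid] is not None:
                    _add(preds[0], dacc[nid])
                continue
            if node.kind == "softmax":
                probs = cache[nid]["probs"]
                _add(preds[0], ((probs - labels_onehot) / n).astype(self.dtype))
                continue
            g = dacc[nid]
            if g is None or node.kind == "input":
                continue
            if node.kind == "conv":
                dx, dw = self._conv_backward(node, cache[nid], g)
                if node.trainable:
                    grads[nid] = {"w": dw}
                _add(preds[0], dx)
            elif node.kind == "batchnorm":
                dx, dgamma, dbeta = self._bn_backward(nid, cache[nid], g)
                if node.trainable:
                    grads[nid] = {"gamma": dgamma, "beta": dbeta}
                _add(preds[0], dx)
            elif node.kind == "activation":
                _add(preds[0], g * cache[nid]["mask"])
            elif node.kind == "maxpool":
                _add(preds[0], self._maxpool_backward(node, cache[nid], g))
            elif node.kind == "avgpool":
                _add(preds[0], self._avgpool_backward(node, cache[nid], g))
            elif node.kind == "concat":
                splits = np.cumsum(cache[nid]["splits"])[:-1]
                for pid, piece in zip(preds, np.split(g, splits, axis=-1)):
                    _add(pid, piece)
            elif node.kind == "dropout":
                mask = cache[nid]["mask"]
                _add(preds[0], g if mask is None else g * mask)
            elif node.kind == "global_avg_pool":
                h, w = cache[nid]["hw"]
                _add(preds[0], np.broadcast_to(
                    g[:, None, None, :] / (h * w),
                    (g.shape[0], h, w, g.shape[1])).astype(self.dtype))
            elif node.kind == "dense":
                p = self.params[nid]
                xin = cache[nid]["x"]
                if node.trainable:
                    grads[nid] = {"w": xin.T @ g, "b": g.sum(axis=0)}
                _add(preds[0], g @ p["w"].T)
        return grads

    def _conv_backward(self, node, c, g):
        fh, fw, s = node.filter_height, node.filter_width, node.stride
        ho, wo = c["out_hw"]
        n = g.shape[0]
        gr = g.reshape(n * ho * wo, -1)
        dw = c["cols"].T @ gr
        dcols = (gr @ self.params[node.id]["w"].T).reshape(n, ho, wo, fh, fw, -1)
        dxp = np.zeros(c["xp_shape"], dtype=self.dtype)
        for i in range(fh):
            for j in range(fw):
                dxp[:, i : i + s * ho : s, j : j + s * wo : s, :] += dcols[:, :, :, i, j, :]
        (pt, pb), (pl, pr) = c["ph"], c["pw"]
        h, w = dxp.shape[1] - pt - pb, dxp.shape[2] - pl - pr
        return dxp[:, pt : pt + h, pl : pl + w, :], dw

    def _bn_backward(self, nid, c, g):
        xhat, invstd = c["xhat"], c["invstd"]
        gamma = self.params[nid]["gamma"]
        axes = tuple(range(g.ndim - 1))
        m = float(np.prod([g.shape[a] for a in axes]))
        dbeta = g.sum(axis=axes)
        dgamma = (g * xhat).sum(axis=axes)
        if c["training"]:
            dx = (gamma * invstd / m) * (m * g - dbeta - xhat * dgamma)
        else:
            dx = g * gamma * invstd
        return dx.astype(self.dtype), dgamma, dbeta

    def _maxpool_backward(self, node, c, g):
        fh, fw, s = node.filter_height, node.filter_width, node.stride
        ho, wo = c["out_hw"]
        amax = c["amax"]  # (N, Ho, Wo, C) flat window index
        dxp = np.zeros(c["xp_shape"], dtype=self.dtype)
        for i in range(fh):
            for j in range(fw):
                sel = amax == (i * fw + j)
                dxp[:, i : i + s * ho : s, j : j + s * wo : s, :] += g * sel
        (pt, pb), (pl, pr) = c["ph"], c["pw"]
        h, w = dxp.shape[1] - pt - pb, dxp.shape[2] - pl - pr
        return dxp[:, pt : pt + h, pl : pl + w, :]

    def _avgpool_backward(self, node, c, g):
        fh, fw, s = node.filter_height, node.filter_width, node.stride
        ho, wo = c["out_hw"]
        share = (g / (fh * fw)).astype(self.dtype)
        dxp = np.zeros(c["xp_shape"], dtype=self.dtype)
        for i in range(fh):
            for j in range(fw):
                dxp[:, i : i + s * ho : s, j : j + s * wo : s, :] += share
        (pt, pb), (pl, pr) = c["ph"], c["pw"]
        h, w = dxp.shape[1] - pt - pb, dxp.shape[2] - pl - pr
        return dxp[:, pt : pt + h, pl : pl + w, :]

    # -- training steps ------------------------------------------------

    def loss(self, probs: np.ndarray, labels_onehot: np.ndarray) -> float:
        p = np.clip(probs, 1e-12, 1.0)
        return float(-(labels_onehot * np.log(p)).sum(axis=-1).mean())

    def train_step(self, x, labels_onehot, optimizer, rng) -> tuple[float, np.ndarray]:
        probs, cache = self.forward(x, training=True, rng=rng)
        loss = self.loss(probs, labels_onehot)
        grads = self.backward(cache, labels_onehot)
        optimizer.step(self.params, grads)
        return loss, probs

    def recalibrate_batchnorm(self, x, batch_size: int | None = None) -> None:
        """Re-estimate BN running statistics with a momentum-0 forward
        pass over ``x`` (precise-BN).  Small-batch training leaves the
        running averages lagging behind the final weights; one cascaded
        full-data pass replaces them with the exact activation statistics."""
        if not self.bn_state:
            return
        old = self.bn_momentum
        self.bn_momentum = 0.0
        try:
            self.forward(x if batch_size is None else x[:batch_size], training=True)
        finally:
            self.bn_momentum = old

    def predict_proba(self, x, batch_size: int = 32) -> np.ndarray:
        outs = []
        for i in range(0, len(x), batch_size):
            probs, _ = self.forward(x[i : i + batch_size], training=False)
            outs.append(probs)
        return np.concatenate(outs, axis=0)


# ---------------------------------------------------------------------------
# optimizers


class _Optimizer:
    def __init__(self, lr: float):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.lr = lr
        self.slots: dict[tuple[str, str], dict[str, np.ndarray]] = {}

    def step(self, params, grads) -> None:
        for nid in sorted(grads):
            for key in sorted(grads[nid]):
                slot = self.slots.setdefault(
                    (nid, key), self._init_slot(params[nid][key])
                )
                self._update(params[nid], key, grads[nid][key], slot)


class SGDM(_Optimizer):
    """Stochastic gradient descent with momentum (default 0.9)."""

    def __init__(self, lr: float, momentum: float = 0.9):
        super().__init__(lr)
        self.momentum = momentum

    def _init_slot(self, p):
        return {"v": np.zeros_like(p)}

    def _update(self, params, key, g, slot):
        slot["v"] = self.momentum * slot["v"] - self.lr * g
        params[key] = params[key] + slot["v"]


class Adam(_Optimizer):
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def _init_slot(self, p):
        return {"m": np.zeros_like(p), "v": np.zeros_like(p), "t": np.zeros(1)}

    def _update(self, params, key, g, slot):
        slot["t"] += 1
        t = float(slot["t"][0])
        slot["m"] = self.beta1 * slot["m"] + (1 - self.beta1) * g
        slot["v"] = self.beta2 * slot["v"] + (1 - self.beta2) * g * g
        mhat = slot["m"] / (1 - self.beta1**t)
        vhat = slot["v"] / (1 - self.beta2**t)
        params[key] = params[key] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RMSProp(_Optimizer):
    def __init__(self, lr: float, decay: float = 0.9, eps: float = 1e-8):
        super().__init__(lr)
        self.decay, self.eps = decay, eps

    def _init_slot(self, p):
        return {"v": np.zeros_like(p)}

    def _update(self, params, key, g, slot):
        slot["v"] = self.decay * slot["v"] + (1 - self.decay) * g * g
        params[key] = params[key] - self.lr * g / (np.sqrt(slot["v"]) + self.eps)


def make_optimizer(name: str, lr: float) -> _Optimizer:
    table = {"sgdm": SGDM, "adam": Adam, "rmsprop": RMSProp}
    if name not in table:
        raise ValueError(f"unknown optimizer {name!r}; choose from {sorted(table)}")
    return table[name](lr)
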