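"""Minimal CPU tensor-network engine for the detector family.

Networks are flat DAGs of primitive nodes (convolution, batch norm, SiLU,
max-pool, nearest upsample, concat, add, channel-chunk, attention). Each
primitive implements ``forward`` and ``backward``; a generic graph
executor runs the DAG and reverse-accumulates gradients, which is all the
training loop needs. Convolutions run as im2col + BLAS matmul in float32.

This is deliberately a small engine, not a framework: just enough to
construct the detector variants, count their parameters and operations
exactly, run inference, and overfit small synthetic datasets on a CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _sigmoid(x):
    out = np.empty_like(x)
    np.negative(np.abs(x), out=out)
    np.exp(out, out=out)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + out[pos])
    neg = ~pos
    out[neg] = out[neg] / (1.0 + out[neg])
    return out


def autopad(k: int) -> int:
    return k // 2


class Node:
    """Base primitive. Subclasses set ``params`` (name -> array) and
    matching ``grads`` after backward."""

    def __init__(self, sources: Sequence[int]):
        self.sources = list(sources)
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.out_channels: int = 0
        self.cache = None

    def n_params(self, fused: bool = True) -> int:
        return sum(int(np.prod(p.shape)) for p in self.params.values())

    def macs(self, h: int, w: int) -> int:
        """Weight multiply-accumulates at the node's *output* resolution."""
        return 0

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        return h, w

    def forward(self, xs: list[np.ndarray], training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> list[np.ndarray]:
        raise NotImplementedError


class Conv(Node):
    """Convolution + optional batch norm + optional SiLU, bias-free when
    normalized (the norm's shift plays that role, and the pair fuses to a
    biased convolution at deployment)."""

    def __init__(self, src, c1, c2, k=1, s=1, g=1, act=True, bn=True, bias=None):
        super().__init__([src])
        self.c1, self.c2, self.k, self.s, self.g = c1, c2, k, s, g
        self.p = autopad(k)
        self.act, self.bn = act, bn
        self.has_bias = (not bn) if bias is None else bias
        self.out_channels = c2
        rng = _INIT_RNG
        fan_in = c1 // g * k * k
        self.params["w"] = (
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c2, c1 // g, k, k))
        ).astype(np.float32)
        if self.has_bias:
            self.params["b"] = np.zeros(c2, dtype=np.float32)
        if bn:
            self.params["gamma"] = np.ones(c2, dtype=np.float32)
            self.params["beta"] = np.zeros(c2, dtype=np.float32)
            self.running_mean = np.zeros(c2, dtype=np.float32)
            self.running_var = np.ones(c2, dtype=np.float32)
            self.momentum, self.eps = 0.03, 1e-3

    def n_params(self, fused: bool = True) -> int:
        w = int(np.prod(self.params["w"].shape))
        if self.bn:
            # fused: conv weight + folded bias; unfused adds 2*c2 norm affine
            return w + self.c2 if fused else w + 2 * self.c2
        return w + (self.c2 if self.has_bias else 0)

    def macs(self, h: int, w: int) -> int:
        return (self.c1 // self.g) * self.c2 * self.k * self.k * h * w

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        return ((h + 2 * self.p - self.k) // self.s + 1,
                (w + 2 * self.p - self.k) // self.s + 1)

    # -- conv core -----------------------------------------------------
    def _im2col(self, x):
        if self.p:
            x = np.pad(x, ((0, 0), (0, 0), (self.p, self.p), (self.p, self.p)))
        win = sliding_window_view(x, (self.k, self.k), axis=(2, 3))
        win = win[:, :, :: self.s, :: self.s]  # n,c,oh,ow,k,k
        return win, win.shape[2], win.shape[3], x.shape

    def forward(self, xs, training):
        x = xs[0]
        n = x.shape[0]
        win, oh, ow, padded_shape = self._im2col(x)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, self.c1 * self.k * self.k)
        if self.g == 1:
            wmat = self.params["w"].reshape(self.c2, -1)
            y = cols @ wmat.T
        else:
            cg = self.c1 // self.g
            og = self.c2 // self.g
            cols_g = cols.reshape(n * oh * ow, self.g, cg * self.k * self.k)
            wg = self.params["w"].reshape(self.g, og, cg * self.k * self.k)
            y = np.einsum("ngk,gok->ngo", cols_g, wg).reshape(n * oh * ow, self.c2)
        y = y.reshape(n, oh, ow, self.c2).transpose(0, 3, 1, 2)
        if self.has_bias:
            y += self.params["b"][None, :, None, None]
        self.cache = {"x_shape": padded_shape, "cols": cols, "n": n, "oh": oh, "ow": ow}
        if self.bn:
            if training:
                mean = y.mean(axis=(0, 2, 3))
                var = y.var(axis=(0, 2, 3))
                self.running_mean += self.momentum * (mean - self.running_mean)
                self.running_var += self.momentum * (var - self.running_var)
            else:
                mean, var = self.running_mean, self.running_var
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (y - mean[None, :, None, None]) * inv[None, :, None, None]
            y = self.params["gamma"][None, :, None, None] * xhat \
                + self.params["beta"][None, :, None, None]
            self.cache.update(xhat=xhat, inv=inv)
        if self.act:
            sig = _sigmoid(y)
            self.cache.update(pre=y, sig=sig)
            y = y * sig
        return y.astype(np.float32)

    def backward(self, gout):
        c = self.cache
        if self.act:
            pre, sig = c["pre"], c["sig"]
            gout = gout * (sig * (1.0 + pre * (1.0 - sig)))
        if self.bn:
            xhat, inv = c["xhat"], c["inv"]
            n_elem = gout.shape[0] * gout.shape[2] * gout.shape[3]
            self.grads["gamma"] = (gout * xhat).sum(axis=(0, 2, 3)).astype(np.float32)
            self.grads["beta"] = gout.sum(axis=(0, 2, 3)).astype(np.float32)
            g = self.params["gamma"][None, :, None, None]
            gx = gout * g
            mean_gx = gx.mean(axis=(0, 2, 3), keepdims=True)
            mean_gx_xhat = (gx * xhat).mean(axis=(0, 2, 3), keepdims=True)
            gout = (gx - mean_gx - xhat * mean_gx_xhat) * inv[None, :, None, None]
        if self.has_bias:
            self.grads["b"] = gout.sum(axis=(0, 2, 3)).astype(np.float32)
        n, oh, ow = c["n"], c["oh"], c["ow"]
        gflat = gout.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.c2)
        cols = c["cols"]
        if self.g == 1:
            self.grads["w"] = (gflat.T @ cols).reshape(self.params["w"].shape).astype(np.float32)
            gcols = gflat @ self.params["w"].reshape(self.c2, -1)
        else:
            cg = self.c1 // self.g
            og = self.c2 // self.g
            cols_g = cols.reshape(n * oh * ow, self.g, cg * self.k * self.k)
            gf = gflat.reshape(n * oh * ow, self.g, og)
            gw = np.einsum("ngo,ngk->gok", gf, cols_g)
            self.grads["w"] = gw.reshape(self.params["w"].shape).astype(np.float32)
            wg = self.params["w"].reshape(self.g, og, cg * self.k * self.k)
            gcols = np.einsum("ngo,gok->ngk", gf, wg).reshape(n * oh * ow, -1)
        # scatter columns back (col2im)
        ph, pw = c["x_shape"][2], c["x_shape"][3]
        gx = np.zeros((n, self.c1, ph, pw), dtype=np.float32)
        gcols = gcols.reshape(n, oh, ow, self.c1, self.k, self.k).transpose(0, 3, 1, 2, 4, 5)
        for ki in range(self.k):
            for kj in range(self.k):
                gx[:, :, ki:ki + self.s * (oh - 1) + 1:self.s,
                   kj:kj + self.s * (ow - 1) + 1:self.s] += gcols[:, :, :, :, ki, kj]
        if self.p:
            gx = gx[:, :, self.p:ph - self.p, self.p:pw - self.p]
        self.cache = None
        return [gx]


class MaxPool(Node):
    def __init__(self, src, c, k=5, s=1):
        super().__init__([src])
        self.k, self.s, self.p = k, s, autopad(k)
        self.out_channels = c

    def forward(self, xs, training):
        x = xs[0]
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.p, self.p), (self.p, self.p)),
                    constant_values=-np.inf)
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))[:, :, ::self.s, ::self.s]
        oh, ow = win.shape[2], win.shape[3]
        flat = win.reshape(n, c, oh, ow, self.k * self.k)
        idx = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self.cache = (x.shape, idx, oh, ow)
        return y.astype(np.float32)

    def backward(self, gout):
        x_shape, idx, oh, ow = self.cache
        n, c, h, w = x_shape
        gx = np.zeros((n, c, h + 2 * self.p, w + 2 * self.p), dtype=np.float32)
        ki, kj = np.divmod(idx, self.k)
        oy, ox = np.meshgrid(np.arange(oh), np.arange(ow), indexing="ij")
        rows = oy[None, None] * self.s + ki
        colsj = ox[None, None] * self.s + kj
        nn_, cc_ = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        np.add.at(gx, (nn_[..., None, None], cc_[..., None, None], rows, colsj), gout)
        if self.p:
            gx = gx[:, :, self.p:-self.p, self.p:-self.p]
        self.cache = None
        return [gx]


class Upsample(Node):
    def __init__(self, src, c, factor=2):
        super().__init__([src])
        self.factor = factor
        self.out_channels = c

    def out_hw(self, h, w):
        return h * self.factor, w * self.factor

    def forward(self, xs, training):
        f = self.factor
        return np.repeat(np.repeat(xs[0], f, axis=2), f, axis=3)

    def backward(self, gout):
        f = self.factor
        n, c, h, w = gout.shape
        return [gout.reshape(n, c, h // f, f, w // f, f).sum(axis=(3, 5))]


class Concat(Node):
    def __init__(self, sources, channels):
        super().__init__(sources)
        self.splits = list(channels)
        self.out_channels = sum(channels)

    def forward(self, xs, training):
        return np.concatenate(xs, axis=1)

    def backward(self, gout):
        out, start = [], 0
        for c in self.splits:
            out.append(gout[:, start:start + c])
            start += c
        return out


class Add(Node):
    def __init__(self, sources, c):
        super().__init__(sources)
        self.out_channels = c

    def forward(self, xs, training):
        return xs[0] + xs[1]

    def backward(self, gout):
        return [gout, gout]


class Chunk(Node):
    """Take one contiguous channel slice of the source."""

    def __init__(self, src, c_in, start, stop):
        super().__init__([src])
        self.c_in, self.start, self.stop = c_in, start, stop
        self.out_channels = stop - start

    def forward(self, xs, training):
        return xs[0][:, self.start:self.stop]

    def backward(self, gout):
        n, _, h, w = gout.shape
        gx = np.zeros((n, self.c_in, h, w), dtype=np.float32)
        gx[:, self.start:self.stop] = gout
        return [gx]


class Attention(Node):
    """Position-sensitive multi-head attention block (inference only).

    Matches the partial-self-attention design used in the stock detector
    tail: qkv/proj 1x1 convs with norm, a depthwise positional conv on the
    values, softmax attention over flattened space. Backward is not
    implemented; only the stock baselines contain it and they are never
    trained here.
    """

    def __init__(self, src, dim, num_heads, attn_ratio=0.5):
        super().__init__([src])
        self.dim, self.num_heads = dim, num_heads
        self.head_dim = dim // num_heads
        self.key_dim = int(self.head_dim * attn_ratio)
        self.scale = self.key_dim ** -0.5
        h = dim + self.key_dim * num_heads * 2
        self.h = h
        self.qkv = Conv(-1, dim, h, 1, act=False)
        self.proj = Conv(-1, dim, dim, 1, act=False)
        self.pe = Conv(-1, dim, dim, 3, g=dim, act=False)
        self.out_channels = dim
        for name, sub in (("qkv", self.qkv), ("proj", self.proj), ("pe", self.pe)):
            for pname, arr in sub.params.items():
                self.params[f"{name}.{pname}"] = arr

    def n_params(self, fused=True):
        return sum(m.n_params(fused) for m in (self.qkv, self.proj, self.pe))

    def macs(self, h, w):
        return sum(m.macs(h, w) for m in (self.qkv, self.proj, self.pe))

    def forward(self, xs, training):
        x = xs[0]
        n, c, hh, ww = x.shape
        qkv = self.qkv.forward([x], False)
        L = hh * ww
        qkv = qkv.reshape(n, self.num_heads, self.key_dim * 2 + self.head_dim, L)
        q = qkv[:, :, : self.key_dim]
        k = qkv[:, :, self.key_dim: 2 * self.key_dim]
        v = qkv[:, :, 2 * self.key_dim:]
        attn = np.einsum("nhkl,nhkm->nhlm", q, k) * self.scale
        attn -= attn.max(axis=-1, keepdims=True)
        np.exp(attn, out=attn)
        attn /= attn.sum(axis=-1, keepdims=True)
        out = np.einsum("nhcm,nhlm->nhcl", v, attn).reshape(n, c, hh, ww)
        pe = self.pe.forward([v.reshape(n, c, hh, ww)], False)
        return self.proj.forward([out + pe], False)

    def backward(self, gout):
        raise NotImplementedError("attention backward is not supported")


@dataclass
class LayerMeta:
    """Bookkeeping for reports: which plan block a node expanded from."""

    block_index: int
    block_kind: str


class Network:
    """Flat DAG of primitives with plan-block provenance.

    ``taps`` are the node indices whose outputs the caller wants (the
    three detection feature maps).
    """

    def __init__(self):
        self.nodes: list[Node] = []
        self.meta: list[LayerMeta] = []
        self.taps: list[int] = []
        self.in_channels = 3

    def add(self, node: Node, meta: LayerMeta) -> int:
        self.nodes.append(node)
        self.meta.append(meta)
        return len(self.nodes) - 1

    # -- execution -----------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> list[np.ndarray]:
        outputs: list[Optional[np.ndarray]] = [None] * len(self.nodes)
        self._keep = [0] * len(self.nodes)
        for node in self.nodes:
            for s in node.sources:
                if s >= 0:
                    self._keep[s] += 1
        for s in self.taps:
            self._keep[s] += 1
        x = np.ascontiguousarray(x, dtype=np.float32)
        for i, node in enumerate(self.nodes):
            xs = [x if s == -1 else outputs[s] for s in node.sources]
            outputs[i] = node.forward(xs, training)
            if not training:
                for s in node.sources:
                    if s >= 0:
                        self._keep[s] -= 1
                        if self._keep[s] == 0:
                            outputs[s] = None
        self._outputs = outputs if training else None
        return [outputs[t] for t in self.taps]

    def backward(self, tap_grads: list[np.ndarray]) -> None:
        grads: list[Optional[np.ndarray]] = [None] * len(self.nodes)

        def accumulate(idx, g):
            if idx == -1:
                return
            if grads[idx] is None:
                grads[idx] = g.copy()
            else:
                grads[idx] += g

        for t, g in zip(self.taps, tap_grads):
            accumulate(t, g)
        for i in range(len(self.nodes) - 1, -1, -1):
            g = grads[i]
            if g is None:
                continue
            gs = self.nodes[i].backward(g)
            for s, gsub in zip(self.nodes[i].sources, gs):
                accumulate(s, gsub)
            grads[i] = None
        self._outputs = None

    # -- parameter access ----------------------------------------------
    def parameters(self):
        for node in self.nodes:
            for name, p in node.params.items():
                yield node, name, p

    def n_params(self, fused: bool = True) -> int:
        return sum(n.n_params(fused) for n in self.nodes)

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, node in enumerate(self.nodes):
            for name, p in node.params.items():
                out[f"{i}.{name}"] = p
            if isinstance(node, Conv) and node.bn:
                out[f"{i}.running_mean"] = node.running_mean
                out[f"{i}.running_var"] = node.running_var
        return out

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        for i, node in enumerate(self.nodes):
            for name in list(node.params):
                node.params[name][...] = d[f"{i}.{name}"]
            if isinstance(node, Conv) and node.bn:
                node.running_mean[...] = d[f"{i}.running_mean"]
                node.running_var[...] = d[f"{i}.running_var"]


_INIT_RNG = np.random.default_rng(0)


def set_init_seed(seed: int) -> None:
    """Reset the weight-initialization stream (call before building)."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)
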