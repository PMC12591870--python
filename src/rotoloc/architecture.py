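"""Detector construction and exact complexity accounting.

Models are built from declarative layer plans (YAML files shipped with
the package, one per architecture). A plan lists blocks -- plain
convolution+norm, C3k2 cross-stage-partial blocks, SPPF context pooling,
partial-self-attention tail, inverted-residual (MIRB) and universal
inverted-bottleneck (MUIB) blocks, upsample/concat wiring and the
decoupled detection head -- together with the channel-width multiplier
applied to nominal channels. Blocks marked ``literal`` keep their printed
channels at every model scale; everything else scales.

Two complexity conventions are used throughout and documented here once:

* **Parameters** are reported *fused*: each convolution + norm pair counts
  its convolution weight plus one folded bias per output channel (what
  the pair collapses to at deployment), and the detection head includes
  the 16 fixed weights of the distribution-focal projection. This is the
  convention under which the published totals for the stock baselines are
  reproduced exactly.
* **FLOPs** are ``2 x`` convolution weight-multiply-accumulates at the
  evaluation resolution (default 640 x 640); normalization, activation,
  pooling, resampling and attention arithmetic count as zero. Calibrated
  so the stock small-model baseline reproduces its published figure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import nn
from .geometry import Box, ObjectClass, iou

REG_MAX = 16


class PlanError(ValueError):
    """A layer plan is internally inconsistent."""


def make_divisible(x: float, divisor: int = 8) -> int:
    return int(math.ceil(x / divisor) * divisor)


@dataclass
class BlockSpec:
    """One block of a layer plan."""

    kind: str
    out_channels: int = 0
    kernel_size: int = 3
    stride: int = 1
    expansion_ratio: Optional[float] = None
    repeats: int = 1
    c3k: bool = False
    pruning: str | bool = False  # False | "conv" (single light conv) | "identity"
    bottleneck_ratio: float = 0.5
    start_kernel: int = 0
    shortcut: bool = True
    literal: bool = False
    hidden: int = 0
    sources: list[int] = field(default_factory=lambda: [-1])

    @staticmethod
    def from_dict(d: dict) -> "BlockSpec":
        known = {
            "kind", "out", "k", "s", "e", "n", "c3k", "pruning", "be",
            "start_k", "literal", "hidden", "from", "shortcut",
        }
        unknown = set(d) - known
        if unknown:
            raise PlanError(f"unknown block keys: {sorted(unknown)}")
        return BlockSpec(
            kind=d["kind"],
            out_channels=d.get("out", 0),
            kernel_size=d.get("k", 3),
            stride=d.get("s", 1),
            expansion_ratio=d.get("e"),
            repeats=d.get("n", 1),
            c3k=d.get("c3k", False),
            pruning=d.get("pruning", False),
            bottleneck_ratio=d.get("be", 0.5),
            start_kernel=d.get("start_k", 0),
            shortcut=d.get("shortcut", True),
            literal=d.get("literal", False),
            hidden=d.get("hidden", 0),
            sources=list(d.get("from", [-1])),
        )


@dataclass
class ModelSpec:
    """A named architecture: ordered blocks plus scaling parameters."""

    name: str
    width: float
    max_channels: int
    depth: float
    num_classes: int
    input_size: int
    blocks: list[BlockSpec]

    def scaled_channels(self, nominal: int, literal: bool) -> int:
        if literal:
            return nominal
        return make_divisible(min(nominal, self.max_channels) * self.width)

    def scaled_repeats(self, n: int) -> int:
        return max(round(n * self.depth), 1) if n > 1 else n

    @staticmethod
    def from_yaml(path: str | Path) -> "ModelSpec":
        d = yaml.safe_load(Path(path).read_text())
        return ModelSpec(
            name=d["name"],
            width=d.get("width", 1.0),
            max_channels=d.get("max_channels", 1024),
            depth=d.get("depth", 1.0),
            num_classes=d.get("num_classes", 2),
            input_size=d.get("input_size", 640),
            blocks=[BlockSpec.from_dict(b) for b in d["layers"]],
        )


def load_spec(name: str, num_classes: int = 2, input_size: int = 640) -> ModelSpec:
    """Load a registered architecture plan by name."""
    ref = resources.files("rotoloc.plans").joinpath(f"{name}.yaml")
    if not ref.is_file():
        available = sorted(
            p.name[:-5] for p in resources.files("rotoloc.plans").iterdir()
            if p.name.endswith(".yaml")
        )
        raise PlanError(f"unknown architecture {name!r}; available: {available}")
    with resources.as_file(ref) as path:
        spec = ModelSpec.from_yaml(path)
    spec.num_classes = num_classes
    spec.input_size = input_size
    return spec


# ---------------------------------------------------------------------------
# builder
# ---------------------------------------------------------------------------

class _Builder:
    """Expands plan blocks into flat primitive nodes."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.net = nn.Network()
        self.block_out: list[int] = []      # node index of each block's output
        self.block_ch: list[int] = []       # channels of each block's output
        self.block_hw: list[tuple[int, int]] = []
        self._cur_block = -1

    def _node(self, node: nn.Node) -> int:
        return self.net.add(
            node, nn.LayerMeta(self._cur_block, self.spec.blocks[self._cur_block].kind)
        )

    def _resolve(self, ref: int) -> tuple[int, int]:
        """block ref -> (node index, channels); -1 means previous block."""
        if ref == -1:
            if not self.block_out:
                return -1, self.net.in_channels
            return self.block_out[-1], self.block_ch[-1]
        return self.block_out[ref], self.block_ch[ref]

    def _conv(self, src, c1, c2, k=1, s=1, g=1, act=True, bn=True, bias=None):
        return self._node(nn.Conv(src, c1, c2, k, s, g, act=act, bn=bn, bias=bias))

    def _bottleneck(self, src, c, e, shortcut=True, prune=False):
        c_ = int(c * e)
        if prune == "identity":
            # fully pruned: the partial branch passes through unrefined
            return src
        if prune:
            # light variant: single 3x3 path, no expansion pair
            y = self._conv(src, c, c, 3)
            return self._node(nn.Add([src, y], c)) if shortcut else y
        y = self._conv(src, c, c_, 3)
        y = self._conv(y, c_, c, 3)
        return self._node(nn.Add([src, y], c)) if shortcut else y

    def _c3k(self, src, c, shortcut=True):
        c_ = c // 2
        a = self._conv(src, c, c_, 1)
        b = self._conv(src, c, c_, 1)
        m = a
        for _ in range(2):
            m = self._bottleneck(m, c_, 1.0, shortcut)
        cat = self._node(nn.Concat([m, b], [c_, c_]))
        return self._conv(cat, 2 * c_, c, 1)

    def _c3k2(self, src, c1, c2, n, c3k, e, shortcut=True, prune=False):
        c = int(c2 * e)
        y = self._conv(src, c1, 2 * c, 1)
        a = self._node(nn.Chunk(y, 2 * c, 0, c))
        b = self._node(nn.Chunk(y, 2 * c, c, 2 * c))
        parts, chans = [a, b], [c, c]
        m = b
        for _ in range(n):
            m = self._c3k(m, c, shortcut) if c3k else self._bottleneck(m, c, 0.5, shortcut, prune)
            parts.append(m)
            chans.append(c)
        cat = self._node(nn.Concat(parts, chans))
        return self._conv(cat, sum(chans), c2, 1)

    def _c2f(self, src, c1, c2, n, shortcut=True):
        c = int(c2 * 0.5)
        y = self._conv(src, c1, 2 * c, 1)
        a = self._node(nn.Chunk(y, 2 * c, 0, c))
        b = self._node(nn.Chunk(y, 2 * c, c, 2 * c))
        parts, chans = [a, b], [c, c]
        m = b
        for _ in range(n):
            m = self._bottleneck(m, c, 1.0, shortcut)
            parts.append(m)
            chans.append(c)
        cat = self._node(nn.Concat(parts, chans))
        return self._conv(cat, sum(chans), c2, 1)

    def _sppf(self, src, c1, c2, k=5):
        c_ = c1 // 2
        x = self._conv(src, c1, c_, 1)
        p1 = self._node(nn.MaxPool(x, c_, k))
        p2 = self._node(nn.MaxPool(p1, c_, k))
        p3 = self._node(nn.MaxPool(p2, c_, k))
        cat = self._node(nn.Concat([x, p1, p2, p3], [c_] * 4))
        return self._conv(cat, 4 * c_, c2, 1)

    def _c2psa(self, src, c, n):
        ch = c // 2
        y = self._conv(src, c, 2 * ch, 1)
        a = self._node(nn.Chunk(y, 2 * ch, 0, ch))
        b = self._node(nn.Chunk(y, 2 * ch, ch, 2 * ch))
        m = b
        for _ in range(n):
            att = self._node(nn.Attention(m, ch, max(ch // 64, 1)))
            m = self._node(nn.Add([m, att], ch))
            f = self._conv(m, ch, 2 * ch, 1)
            f = self._conv(f, 2 * ch, ch, 1, act=False)
            m = self._node(nn.Add([m, f], ch))
        cat = self._node(nn.Concat([a, m], [ch, ch]))
        return self._conv(cat, 2 * ch, c, 1)

    def _mirb(self, src, c1, c2, k, s, e):
        mid = int(c1 * e)
        y = self._conv(src, c1, mid, 1)
        y = self._conv(y, mid, mid, k, s, g=mid)
        y = self._conv(y, mid, c2, 1, act=False)
        if s == 1 and c1 == c2:
            y = self._node(nn.Add([src, y], c2))
        return y

    def _muib(self, src, c1, c2, k, s, e, start_k):
        mid = int(c1 * e)
        y = src
        if start_k:
            y = self._conv(y, c1, c1, start_k, act=False, g=c1)
        y = self._conv(y, c1, mid, 1)
        if k:
            y = self._conv(y, mid, mid, k, s, g=mid)
        y = self._conv(y, mid, c2, 1, act=False)
        if s == 1 and c1 == c2:
            y = self._node(nn.Add([src, y], c2))
        return y

    def _detect(self, refs: list[int], legacy: bool = False):
        nc = self.spec.num_classes
        chans = [self.block_ch[r] for r in refs]
        c2 = max(16, chans[0] // 4, REG_MAX * 4)
        c3 = max(chans[0], min(nc, 100))
        taps = []
        for r, x in zip(refs, chans):
            src = self.block_out[r]
            b = self._conv(src, x, c2, 3)
            b = self._conv(b, c2, c2, 3)
            b = self._conv(b, c2, 4 * REG_MAX, 1, act=False, bn=False, bias=True)
            if legacy:
                cl = self._conv(src, x, c3, 3)
                cl = self._conv(cl, c3, c3, 3)
            else:
                cl = self._conv(src, x, x, 3, g=x)
                cl = self._conv(cl, x, c3, 1)
                cl = self._conv(cl, c3, c3, 3, g=c3)
                cl = self._conv(cl, c3, c3, 1)
            cl = self._conv(cl, c3, nc, 1, act=False, bn=False, bias=True)
            cat = self._node(nn.Concat([b, cl], [4 * REG_MAX, nc]))
            taps.append(cat)
        self.net.taps = taps

    def build(self):
        spec = self.spec
        hw = (spec.input_size, spec.input_size)
        for bi, blk in enumerate(spec.blocks):
            self._cur_block = bi
            kind = blk.kind
            if kind in ("detect", "detect_legacy"):
                self._detect(blk.sources, legacy=kind == "detect_legacy")
                self.block_out.append(self.net.taps[-1])
                self.block_ch.append(0)
                self.block_hw.append(hw)
                continue
            src, c1 = self._resolve(blk.sources[0])
            c2 = spec.scaled_channels(blk.out_channels, blk.literal) if blk.out_channels else c1
            n = spec.scaled_repeats(blk.repeats)
            if kind == "conv_bn":
                out = self._conv(src, c1, c2, blk.kernel_size, blk.stride)
            elif kind == "c3k2":
                out = self._c3k2(
                    src, c1, c2, n, blk.c3k, blk.bottleneck_ratio,
                    shortcut=blk.shortcut, prune=blk.pruning,
                )
            elif kind == "c2f":
                out = self._c2f(src, c1, c2, n, shortcut=blk.shortcut)
            elif kind == "sppf":
                out = self._sppf(src, c1, c2, blk.kernel_size)
            elif kind == "sppf_lite":
                h = blk.hidden
                x = self._conv(src, c1, h, 1)
                p1 = self._node(nn.MaxPool(x, h, blk.kernel_size))
                p2 = self._node(nn.MaxPool(p1, h, blk.kernel_size))
                p3 = self._node(nn.MaxPool(p2, h, blk.kernel_size))
                cat = self._node(nn.Concat([x, p1, p2, p3], [h] * 4))
                out = self._conv(cat, 4 * h, c2, 1)
            elif kind == "c2psa":
                out = self._c2psa(src, c1, n)
                c2 = c1
            elif kind == "mirb":
                out = src
                cin = c1
                for i in range(n):
                    out = self._mirb(out, cin, c2, blk.kernel_size,
                                     blk.stride if i == 0 else 1, blk.expansion_ratio)
                    cin = c2
            elif kind == "muib":
                out = src
                cin = c1
                for i in range(n):
                    out = self._muib(out, cin, c2, blk.kernel_size,
                                     blk.stride if i == 0 else 1, blk.expansion_ratio,
                                     blk.start_kernel)
                    cin = c2
            elif kind == "upsample":
                out = self._node(nn.Upsample(src, c1))
                c2 = c1
            elif kind == "concat":
                pairs = [self._resolve(r) for r in blk.sources]
                out = self._node(nn.Concat([p[0] for p in pairs], [p[1] for p in pairs]))
                c2 = sum(p[1] for p in pairs)
            else:
                raise PlanError(f"unsupported block kind {kind!r} (block {bi})")
            self.block_out.append(out)
            self.block_ch.append(c2)
            self.block_hw.append(hw)
        return self.net


@dataclass
class ComplexityReport:
    """Per-block and total parameter / FLOP accounting."""

    name: str
    input_size: int
    total_params: int
    gflops: float
    per_layer: list[tuple[int, str, int, float]]  # (block, kind, params, gflops)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "input_size": self.input_size,
            "total_params": self.total_params,
            "gflops": round(self.gflops, 4),
            "per_layer": [
                {"block": b, "kind": k, "params": p, "gflops": round(f, 5)}
                for b, k, p, f in self.per_layer
            ],
        }

    def format_table(self) -> str:
        lines = [f"{'block':>5}  {'kind':<10} {'params':>10}  {'GFLOPs':>8}"]
        for b, k, p, f in self.per_layer:
            lines.append(f"{b:>5}  {k:<10} {p:>10,}  {f:>8.3f}")
        lines.append(f"{'':>5}  {'total':<10} {self.total_params:>10,}  {self.gflops:>8.2f}")
        return "\n".join(lines)


class Model:
    """An executable detector built from a :class:`ModelSpec`."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        nn.set_init_seed(seed)
        self.spec = spec
        builder = _Builder(spec)
        self.network = builder.build()
        self.block_ch = builder.block_ch
        self.strides = (8, 16, 32)
        self.num_classes = spec.num_classes
        # fixed distribution-focal projection (16 weights, not trained)
        self.dfl_weight = np.arange(REG_MAX, dtype=np.float32)
        self._bias_init()

    def _bias_init(self):
        """Detection-head prior: low objectness for cls, neutral box."""
        for node, meta in zip(self.network.nodes, self.network.meta):
            if meta.block_kind == "detect" and isinstance(node, nn.Conv) \
                    and not node.bn and node.out_channels == self.num_classes:
                node.params["b"][...] = -4.6  # sigmoid ~ 0.01

    # -- complexity ----------------------------------------------------
    def count_parameters(self, fused: bool = True) -> int:
        total = self.network.n_params(fused)
        if any(m.block_kind.startswith("detect") for m in self.network.meta):
            total += REG_MAX  # fixed projection weights travel with checkpoints
        return total

    def count_flops(self, input_size: Optional[int] = None) -> float:
        size = input_size or self.spec.input_size
        total = 0
        hw = {-1: (size, size)}
        for i, node in enumerate(self.network.nodes):
            src_hw = hw[node.sources[0]]
            oh, ow = node.out_hw(*src_hw)
            total += node.macs(oh, ow)
            hw[i] = (oh, ow)
        return 2.0 * total / 1e9

    def complexity_report(self, input_size: Optional[int] = None) -> ComplexityReport:
        size = input_size or self.spec.input_size
        per: dict[int, list] = {}
        hw = {-1: (size, size)}
        for i, (node, meta) in enumerate(zip(self.network.nodes, self.network.meta)):
            oh, ow = node.out_hw(*hw[node.sources[0]])
            hw[i] = (oh, ow)
            entry = per.setdefault(meta.block_index, [meta.block_kind, 0, 0.0])
            entry[1] += node.n_params(True)
            entry[2] += 2.0 * node.macs(oh, ow) / 1e9
        if any(m.block_kind.startswith("detect") for m in self.network.meta):
            last = max(per)
            per[last][1] += REG_MAX
        layers = [(b, k, p, f) for b, (k, p, f) in sorted(per.items())]
        return ComplexityReport(
            name=self.spec.name,
            input_size=size,
            total_params=sum(p for _, _, p, _ in layers),
            gflops=sum(f for _, _, _, f in layers),
            per_layer=layers,
        )

    # -- inference -----------------------------------------------------
    def forward_raw(self, images: np.ndarray, training: bool = False) -> list[np.ndarray]:
        """Raw per-level maps, channels = 4*REG_MAX + num_classes."""
        if images.ndim == 3:
            images = images[None]
        if images.shape[1] not in (1, 3):
            raise ValueError("images must be NCHW with 1 or 3 channels")
        if images.shape[1] == 1:
            images = np.repeat(images, 3, axis=1)
        return self.network.forward(images.astype(np.float32), training)

    def decode(
        self,
        maps: list[np.ndarray],
        conf_threshold: float = 0.25,
        iou_threshold: float = 0.45,
        max_det: int = 30,
    ) -> list[list[Box]]:
        """Decode raw maps to per-image Box lists (with per-class NMS)."""
        n = maps[0].shape[0]
        all_boxes, all_scores, all_cls = [], [], []
        for level, m in enumerate(maps):
            stride = self.strides[level]
            _, ch, h, w = m.shape
            box = m[:, : 4 * REG_MAX].reshape(n, 4, REG_MAX, h * w)
            box = box - box.max(axis=2, keepdims=True)
            np.exp(box, out=box)
            box /= box.sum(axis=2, keepdims=True)
            dist = np.einsum("nkrl,r->nkl", box, self.dfl_weight)
            ys, xs = np.divmod(np.arange(h * w), w)
            ax = (xs + 0.5) * stride
            ay = (ys + 0.5) * stride
            x1 = ax[None] - dist[:, 0] * stride
            y1 = ay[None] - dist[:, 1] * stride
            x2 = ax[None] + dist[:, 2] * stride
            y2 = ay[None] + dist[:, 3] * stride
            cls = _sigmoid_np(m[:, 4 * REG_MAX:].reshape(n, self.num_classes, h * w))
            all_boxes.append(np.stack([x1, y1, x2, y2], axis=1))
            all_scores.append(cls)
        boxes = np.concatenate([b.reshape(n, 4, -1) for b in all_boxes], axis=2)
        scores = np.concatenate([s.reshape(n, self.num_classes, -1) for s in all_scores], axis=2)
        out: list[list[Box]] = []
        for i in range(n):
            dets: list[Box] = []
            for c in range(self.num_classes):
                sc = scores[i, c]
                keep = np.nonzero(sc >= conf_threshold)[0]
                if not len(keep):
                    continue
                order = keep[np.argsort(-sc[keep])][: 5 * max_det]
                cand = []
                for j in order:
                    x1, y1, x2, y2 = boxes[i, :, j]
                    if x2 - x1 < 1 or y2 - y1 < 1:
                        continue
                    b = Box(
                        max(float(x1), 0.0), max(float(y1), 0.0),
                        float(x2 - max(x1, 0.0)), float(y2 - max(y1, 0.0)),
                        class_id=ObjectClass(c), confidence=float(sc[j]),
                    )
                    if all(iou(b, prev) < iou_threshold for prev in cand):
                        cand.append(b)
                    if len(cand) >= max_det:
                        break
                dets.extend(cand)
            out.append(dets)
        return out

    def predict(self, images: np.ndarray, conf_threshold: float = 0.25) -> list[list[Box]]:
        return self.decode(self.forward_raw(images), conf_threshold)

    # -- persistence ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            __name__=np.array(self.spec.name),
            __nc__=np.array(self.num_classes),
            **self.network.state_dict(),
        )

    @staticmethod
    def load(path: str | Path) -> "Model":
        data = np.load(path)
        spec = load_spec(str(data["__name__"]), num_classes=int(data["__nc__"]))
        model = Model(spec)
        model.network.load_state_dict({k: data[k] for k in data.files if not k.startswith("__")})
        return model


def _sigmoid_np(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def build_model(name_or_spec, num_classes: int = 2, input_size: int = 640, seed: int = 0) -> Model:
    """Build a registered architecture (or an explicit :class:`ModelSpec`)."""
    if isinstance(name_or_spec, ModelSpec):
        return Model(name_or_spec, seed=seed)
    return Model(load_spec(name_or_spec, num_classes, input_size), seed=seed)


def count_parameters(model: Model) -> int:
    return model.count_parameters()


def count_flops(model: Model, input_size: int = 640) -> float:
    return model.count_flops(input_size)


def complexity_report(name_or_spec, num_classes: int = 2, input_size: int = 640) -> ComplexityReport:
    return build_model(name_or_spec, num_classes, input_size).complexity_report()


# ---------------------------------------------------------------------------
# analytic per-block accounting (independent of instantiation)
# ---------------------------------------------------------------------------

def block_params(spec: BlockSpec, in_channels: int, model_spec: ModelSpec) -> int:
    """Closed-form fused parameter count of a single plan block.

    Kept deliberately independent of the network builder: tests require
    the analytic sums to match the instantiated model's count exactly.
    """
    if spec.out_channels < 0 or (spec.kind == "conv_bn" and spec.out_channels == 0):
        raise PlanError(f"invalid out_channels for {spec.kind}")
    c1 = in_channels
    c2 = model_spec.scaled_channels(spec.out_channels, spec.literal) if spec.out_channels else c1
    n = model_spec.scaled_repeats(spec.repeats)

    def conv(a, b, k=1, g=1):
        return a * b * k * k // g + b

    if spec.kind == "conv_bn":
        return conv(c1, c2, spec.kernel_size)
    if spec.kind == "c3k2":
        c = int(c2 * spec.bottleneck_ratio)
        total = conv(c1, 2 * c, 1) + conv((2 + n) * c, c2, 1)
        for _ in range(n):
            if spec.c3k:
                c_ = c // 2
                total += 2 * conv(c, c_, 1) + conv(2 * c_, c, 1)
                total += 2 * (conv(c_, c_, 3) + conv(c_, c_, 3))
            elif spec.pruning == "identity":
                pass
            elif spec.pruning:
                total += conv(c, c, 3)
            else:
                total += conv(c, int(c * 0.5), 3) + conv(int(c * 0.5), c, 3)
        return total
    if spec.kind == "c2f":
        c = int(c2 * 0.5)
        total = conv(c1, 2 * c, 1) + conv((2 + n) * c, c2, 1)
        total += n * (conv(c, c, 3) + conv(c, c, 3))
        return total
    if spec.kind == "sppf":
        c_ = c1 // 2
        return conv(c1, c_, 1) + conv(4 * c_, c2, 1)
    if spec.kind == "sppf_lite":
        return conv(c1, spec.hidden, 1) + conv(4 * spec.hidden, c2, 1)
    if spec.kind == "c2psa":
        ch = c1 // 2
        heads = max(ch // 64, 1)
        key_dim = int(ch // heads * 0.5)
        h = ch + 2 * key_dim * heads
        total = conv(c1, 2 * ch, 1) + conv(2 * ch, c1, 1)
        total += n * (
            conv(ch, h, 1) + conv(ch, ch, 1) + conv(ch, ch, 3, g=ch)
            + conv(ch, 2 * ch, 1) + conv(2 * ch, ch, 1)
        )
        return total
    if spec.kind == "mirb":
        total, cin = 0, c1
        for i in range(n):
            mid = int(cin * spec.expansion_ratio)
            total += conv(cin, mid, 1) + conv(mid, mid, spec.kernel_size, g=mid) + conv(mid, c2, 1)
            cin = c2
        return total
    if spec.kind == "muib":
        total, cin = 0, c1
        for i in range(n):
            mid = int(cin * spec.expansion_ratio)
            if spec.start_kernel:
                total += conv(cin, cin, spec.start_kernel, g=cin)
            total += conv(cin, mid, 1)
            if spec.kernel_size:
                total += conv(mid, mid, spec.kernel_size, g=mid)
            total += conv(mid, c2, 1)
            cin = c2
        return total
    if spec.kind in ("upsample", "concat"):
        return 0
    if spec.kind == "detect":
        raise PlanError("detect-head accounting needs all three input widths; "
                        "use complexity_report")
    raise PlanError(f"unsupported block kind {spec.kind!r}")
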