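"""CPU training of the detector on YOLO-layout datasets.

The objective follows the anchor-free decoupled-head design: a binary
cross-entropy classification loss over every grid cell, and a
distribution-focal regression loss at positive cells, where each of the
four box distances is learned as a 16-bin categorical distribution whose
expectation is the distance in stride units. Positive cells are those
whose anchor point falls inside a ground-truth box within a small radius
of its center, at every pyramid level able to represent the box (all four
distances under the bin range). A box quality term (mean 1 - IoU of the
decoded positives) is logged for monitoring.

The optimizer is SGD with momentum (Adam variants available), linear
warm-up and cosine decay, with early stopping on the monitored metric.
Everything is plain numpy; intended scale is small synthetic datasets --
capacity/overfit checks, not clinical training runs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .architecture import Model, REG_MAX, build_model
from .config import AugmentationConfig, TrainingConfig
from .geometry import Box, ObjectClass
from .metrics import GroundTruthSet, average_precision_50
from .synth import read_yolo_dataset


class DataError(ValueError):
    """Dataset and labels disagree."""


# ---------------------------------------------------------------------------
# data
# ---------------------------------------------------------------------------

@dataclass
class DetectionDataset:
    """Images resized to a square training resolution with scaled boxes."""

    images: np.ndarray          # (n, 1, s, s) float32 in [0, 1]
    boxes: list[list[Box]]      # per image, in resized coordinates
    ids: list[str]
    imgsz: int

    @staticmethod
    def from_yolo(root: str | Path, imgsz: int) -> "DetectionDataset":
        from PIL import Image

        root = Path(root)
        label_boxes, _, manifest = read_yolo_dataset(root)
        w0, h0 = manifest["image_size"]
        sx, sy = imgsz / w0, imgsz / h0
        images, boxes, ids = [], [], []
        for stem in sorted(label_boxes):
            img_path = root / "images" / f"{stem}.png"
            if not img_path.exists():
                raise DataError(f"label without image: {stem}.txt")
            img = Image.open(img_path).convert("L").resize((imgsz, imgsz))
            images.append(np.asarray(img, dtype=np.float32)[None] / 255.0)
            boxes.append([
                Box(b.x * sx, b.y * sy, b.length * sx, b.height * sy,
                    class_id=b.class_id)
                for b in label_boxes[stem]
            ])
            ids.append(stem)
        if not images:
            raise DataError(f"no samples under {root}")
        return DetectionDataset(np.stack(images), boxes, ids, imgsz)


def _augment_batch(
    images: np.ndarray,
    boxes: list[list[Box]],
    acfg: AugmentationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[list[Box]]]:
    """Horizontal flip, brightness gain, scale jitter, random erasing.

    Hue/saturation gains are accepted for config compatibility but are
    no-ops on single-channel ultrasound; mosaic is handled at the batch
    assembly level by the caller.
    """
    n, _, s, _ = images.shape
    out_imgs = images.copy()
    out_boxes: list[list[Box]] = []
    for i in range(n):
        bs = list(boxes[i])
        if rng.random() < acfg.fliplr:
            out_imgs[i] = out_imgs[i, :, :, ::-1]
            bs = [Box(s - b.x - b.length, b.y, b.length, b.height, class_id=b.class_id)
                  for b in bs]
        if acfg.hsv_v > 0:
            out_imgs[i] = np.clip(
                out_imgs[i] * (1.0 + rng.uniform(-acfg.hsv_v, acfg.hsv_v)), 0, 1
            )
        if acfg.erasing > 0 and rng.random() < acfg.erasing:
            ew, eh = int(s * rng.uniform(0.05, 0.2)), int(s * rng.uniform(0.05, 0.2))
            ex, ey = rng.integers(0, s - ew), rng.integers(0, s - eh)
            out_imgs[i, :, ey:ey + eh, ex:ex + ew] = rng.random()
        out_boxes.append(bs)
    return out_imgs, out_boxes


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _assign(
    boxes: list[Box], imgsz: int, strides: Sequence[int], nc: int,
    center_radius: float = 2.5,
):
    """Per-level targets: cls map (nc,h,w), distance map (4,h,w) in cell
    units, positive mask (h,w)."""
    targets = []
    for s in strides:
        g = imgsz // s
        cls_t = np.zeros((nc, g, g), dtype=np.float32)
        dist_t = np.zeros((4, g, g), dtype=np.float32)
        pos = np.zeros((g, g), dtype=bool)
        ax = (np.arange(g) + 0.5) * s

        def claim(b, i, j):
            l = max((ax[j] - b.x) / s, 0.0)
            t = max((ax[i] - b.y) / s, 0.0)
            r = max((b.x2 - ax[j]) / s, 0.0)
            d = max((b.y2 - ax[i]) / s, 0.0)
            if max(l, t, r, d) >= REG_MAX - 1:
                return False  # level cannot represent this box here
            if pos[i, j] and dist_t[:, i, j].sum() <= l + t + r + d:
                return False  # keep the smaller box on conflicts
            pos[i, j] = True
            dist_t[:, i, j] = (l, t, r, d)
            cls_t[:, i, j] = 0.0
            cls_t[int(b.class_id), i, j] = 1.0
            return True

        for b in boxes:
            cx, cy = b.center
            inside_x = (ax > b.x) & (ax < b.x2) & (np.abs(ax - cx) < center_radius * s)
            inside_y = (ax > b.y) & (ax < b.y2) & (np.abs(ax - cy) < center_radius * s)
            ii = np.nonzero(inside_y)[0]
            jj = np.nonzero(inside_x)[0]
            claimed = False
            for i in ii:
                for j in jj:
                    claimed |= claim(b, i, j)
            if not claimed:
                # thin boxes may enclose no anchor point: fall back to the
                # anchor nearest the box center (distances clamped at 0)
                i = int(np.clip(cy // s, 0, g - 1))
                j = int(np.clip(cx // s, 0, g - 1))
                claim(b, i, j)
        targets.append((cls_t, dist_t, pos))
    return targets


def _softmax(x, axis):
    x = x - x.max(axis=axis, keepdims=True)
    np.exp(x, out=x)
    x /= x.sum(axis=axis, keepdims=True)
    return x


def detection_loss_and_grads(
    maps: list[np.ndarray],
    batch_boxes: list[list[Box]],
    imgsz: int,
    strides: Sequence[int],
    nc: int,
    cls_gain: float = 1.0,
    dfl_gain: float = 1.0,
    box_gain: float = 0.0,
):
    """Return (loss components dict, per-level gradients wrt raw maps)."""
    n = maps[0].shape[0]
    grads = [np.zeros_like(m) for m in maps]
    cls_loss = dfl_loss = box_loss = 0.0
    total_pos = 0
    per_image_targets = [
        _assign(batch_boxes[i], imgsz, strides, nc) for i in range(n)
    ]
    total_pos = sum(
        int(t[2].sum()) for targets in per_image_targets for t in targets
    )
    norm = max(total_pos, 1)
    for li, m in enumerate(maps):
        _, ch, g, _ = m.shape
        for i in range(n):
            cls_t, dist_t, pos = per_image_targets[i][li]
            logits = m[i, 4 * REG_MAX:]
            p = 1.0 / (1.0 + np.exp(-np.clip(logits, -60, 60)))
            eps = 1e-9
            cls_loss += float(-(cls_t * np.log(p + eps)
                                + (1 - cls_t) * np.log(1 - p + eps)).sum())
            grads[li][i, 4 * REG_MAX:] = cls_gain * (p - cls_t) / (norm * nc)
            if not pos.any():
                continue
            raw = m[i, : 4 * REG_MAX].reshape(4, REG_MAX, g, g)
            pr = _softmax(raw.copy(), axis=1)
            tgt = dist_t
            lo = np.floor(tgt).astype(int)
            hi = lo + 1
            w_hi = tgt - lo
            w_lo = 1.0 - w_hi
            target_dist = np.zeros_like(pr)
            ii, jj = np.nonzero(pos)
            for a in range(4):
                target_dist[a, lo[a, ii, jj], ii, jj] += w_lo[a, ii, jj]
                target_dist[a, np.minimum(hi[a, ii, jj], REG_MAX - 1), ii, jj] += w_hi[a, ii, jj]
            mask = pos[None, None, :, :]
            dfl_loss += float(-(target_dist * np.log(pr + 1e-9) * mask).sum())
            g_dfl = dfl_gain * (pr - target_dist) * mask / norm
            # IoU loss through the decoded (softmax-expectation) distances:
            # d(1-IoU)/d(dist) chained via d(dist)/d(logit) = p * (k - dist)
            bins = np.arange(REG_MAX, dtype=np.float32)
            dec = np.einsum("rkhw,k->rhw", pr, bins)
            dl = dec[:, ii, jj]              # (4, npos) pred distances
            tg = tgt[:, ii, jj]
            iw = np.minimum(dl[0], tg[0]) + np.minimum(dl[2], tg[2])
            ih = np.minimum(dl[1], tg[1]) + np.minimum(dl[3], tg[3])
            inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
            area_p = (dl[0] + dl[2]) * (dl[1] + dl[3])
            area_g = (tg[0] + tg[2]) * (tg[1] + tg[3])
            union = np.maximum(area_p + area_g - inter, 1e-9)
            iou_v = inter / union
            box_loss += float((1.0 - iou_v).sum())
            # dI/d(dist): the per-side intersection slope, 0 once past target
            dI = np.empty_like(dl)
            dI[0] = ih * (dl[0] < tg[0]); dI[2] = ih * (dl[2] < tg[2])
            dI[1] = iw * (dl[1] < tg[1]); dI[3] = iw * (dl[3] < tg[3])
            dA = np.empty_like(dl)
            dA[0] = dA[2] = dl[1] + dl[3]
            dA[1] = dA[3] = dl[0] + dl[2]
            # d(IoU)/d dist = (dI*U - I*(dA - dI)) / U^2 ; loss grad is negative
            g_dist = -(dI * union - inter * (dA - dI)) / union**2
            # chain into the bin logits
            jac = pr[:, :, ii, jj] * (bins[None, :, None] - dl[:, None, :])
            g_iou = np.zeros_like(pr)
            g_iou[:, :, ii, jj] = box_gain * g_dist[:, None, :] * jac / norm
            grads[li][i, : 4 * REG_MAX] = (g_dfl + g_iou).reshape(4 * REG_MAX, g, g)
    losses = {
        "cls": cls_gain * cls_loss / (norm * nc),
        "dfl": dfl_gain * dfl_loss / norm,
        "box": box_loss / norm,
        "n_pos": total_pos,
    }
    return losses, grads


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class SGD:
    """SGD with momentum and decoupled-by-kind weight decay (no decay on
    norm affine or biases)."""

    def __init__(self, model: Model, cfg: TrainingConfig):
        self.model = model
        self.cfg = cfg
        self.velocity: dict[int, dict[str, np.ndarray]] = {}

    def step(self, lr: float) -> None:
        for idx, node in enumerate(self.model.network.nodes):
            if not node.grads:
                continue
            vel = self.velocity.setdefault(idx, {})
            for name, grad in node.grads.items():
                p = node.params[name]
                g = grad
                if name == "w" and self.cfg.weight_decay:
                    g = g + self.cfg.weight_decay * p
                v = vel.setdefault(name, np.zeros_like(p))
                v *= self.cfg.momentum
                v += g
                p -= lr * v
            node.grads = {}


class Adam:
    """Adam/AdamW/NAdam (selected by cfg.optimizer)."""

    def __init__(self, model: Model, cfg: TrainingConfig):
        self.model = model
        self.cfg = cfg
        self.m: dict[tuple[int, str], np.ndarray] = {}
        self.v: dict[tuple[int, str], np.ndarray] = {}
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, lr: float) -> None:
        self.t += 1
        kind = self.cfg.optimizer
        for idx, node in enumerate(self.model.network.nodes):
            if not node.grads:
                continue
            for name, grad in node.grads.items():
                p = node.params[name]
                g = grad
                if kind != "AdamW" and name == "w" and self.cfg.weight_decay:
                    g = g + self.cfg.weight_decay * p
                key = (idx, name)
                m = self.m.setdefault(key, np.zeros_like(p))
                v = self.v.setdefault(key, np.zeros_like(p))
                m *= self.b1; m += (1 - self.b1) * g
                v *= self.b2; v += (1 - self.b2) * g * g
                mhat = m / (1 - self.b1 ** self.t)
                vhat = v / (1 - self.b2 ** self.t)
                if kind == "NAdam":
                    mhat = self.b1 * mhat + (1 - self.b1) * g / (1 - self.b1 ** self.t)
                if kind == "AdamW" and name == "w" and self.cfg.weight_decay:
                    p -= lr * self.cfg.weight_decay * p
                p -= lr * mhat / (np.sqrt(vhat) + self.eps)
            node.grads = {}


def make_optimizer(model: Model, cfg: TrainingConfig):
    return SGD(model, cfg) if cfg.optimizer == "SGD" else Adam(model, cfg)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclass
class EpochLog:
    epoch: int
    box_loss: float
    cls_loss: float
    dfl_loss: float
    precision: float
    recall: float
    map50: float
    lr: float
    seconds: float


@dataclass
class TrainResult:
    model: Model
    history: list[EpochLog]
    best_epoch: int
    best_map50: float
    stopped_early: bool

    def history_dicts(self) -> list[dict]:
        return [vars(e) for e in self.history]


def _train_set_map50(model: Model, data: DetectionDataset, conf=0.01) -> tuple[float, float, float]:
    """(precision, recall, mAP50) of the model on the dataset itself."""
    preds: dict[str, list[Box]] = {}
    bs = 8
    for start in range(0, len(data.ids), bs):
        batch = data.images[start:start + bs]
        for off, dets in enumerate(model.predict(batch, conf_threshold=conf)):
            preds[data.ids[start + off]] = dets
    gts = GroundTruthSet(
        boxes={i: data.boxes[k] for k, i in enumerate(data.ids)},
        patients={i: "p0" for i in data.ids},
    )
    from .metrics import match_detections

    aps = []
    for cls in ObjectClass:
        if gts.class_count(cls) > 0:
            aps.append(average_precision_50(preds, gts, cls))
    m = match_detections(preds, gts)
    tp = sum(m.tp.values()); fp = sum(m.fp.values()); fn = sum(m.fn.values())
    prec = tp / max(tp + fp, 1)
    rec = tp / max(tp + fn, 1)
    return prec, rec, float(np.mean(aps)) if aps else 0.0


def train(
    dataset_dir: str | Path,
    arch: str = "yolov11n_plus",
    cfg: TrainingConfig = None,
    aug: AugmentationConfig = None,
    augment: bool = False,
    log_path: Optional[str | Path] = None,
    checkpoint_path: Optional[str | Path] = None,
    eval_every: int = 1,
    eval_imgsz: Optional[int] = None,
    verbose: bool = False,
) -> TrainResult:
    """Train ``arch`` on a YOLO-layout dataset directory.

    Early stopping monitors mAP50 on the training set (these runs are
    capacity checks on synthetic data; there is no held-out clinical
    set). ``eval_imgsz`` lets the fully-convolutional model be evaluated
    at a different (typically slightly larger) resolution than it is
    trained at, which reduces the relative localization error of thin
    objects. Returns the trained model plus the per-epoch metric log.
    """
    cfg = cfg or TrainingConfig()
    aug = aug or AugmentationConfig()
    rng = np.random.default_rng(cfg.seed)
    data = DetectionDataset.from_yolo(dataset_dir, cfg.imgsz)
    eval_data = data
    if eval_imgsz is not None and eval_imgsz != cfg.imgsz:
        eval_data = DetectionDataset.from_yolo(dataset_dir, eval_imgsz)
    model = build_model(arch, num_classes=2, input_size=cfg.imgsz, seed=cfg.seed)
    opt = make_optimizer(model, cfg)
    n = len(data.ids)
    batch = max(1, min(cfg.batch, n))
    steps_per_epoch = (n + batch - 1) // batch
    history: list[EpochLog] = []
    best_map, best_epoch, best_state = -1.0, -1, None
    stopped = False
    for epoch in range(cfg.epochs):
        t0 = time.time()
        order = rng.permutation(n)
        sums = {"cls": 0.0, "dfl": 0.0, "box": 0.0}
        for step_i in range(steps_per_epoch):
            frac = (epoch + step_i / steps_per_epoch)
            if frac < cfg.warmup_epochs:
                lr = cfg.lr0 * (0.1 + 0.9 * frac / cfg.warmup_epochs)
            else:
                prog = (frac - cfg.warmup_epochs) / max(cfg.epochs - cfg.warmup_epochs, 1e-9)
                lr = cfg.lr0 * (cfg.lrf + (1 - cfg.lrf) * 0.5 * (1 + np.cos(np.pi * prog)))
            idx = order[step_i * batch:(step_i + 1) * batch]
            imgs = data.images[idx]
            boxes = [data.boxes[i] for i in idx]
            if augment:
                imgs, boxes = _augment_batch(imgs, boxes, aug, rng)
            maps = model.forward_raw(imgs, training=True)
            losses, grads = detection_loss_and_grads(
                maps, boxes, cfg.imgsz, model.strides, model.num_classes
            )
            model.network.backward(grads)
            opt.step(lr)
            for k in sums:
                sums[k] += losses[k]
        prec = rec = map50 = float("nan")
        if (epoch + 1) % eval_every == 0 or epoch == cfg.epochs - 1:
            prec, rec, map50 = _train_set_map50(model, eval_data)
        log = EpochLog(
            epoch=epoch,
            box_loss=sums["box"] / steps_per_epoch,
            cls_loss=sums["cls"] / steps_per_epoch,
            dfl_loss=sums["dfl"] / steps_per_epoch,
            precision=prec, recall=rec, map50=map50,
            lr=lr, seconds=time.time() - t0,
        )
        history.append(log)
        if verbose:
            print(f"epoch {epoch}: box {log.box_loss:.3f} cls {log.cls_loss:.3f} "
                  f"dfl {log.dfl_loss:.3f} mAP50 {map50:.3f} ({log.seconds:.1f}s)")
        if not np.isnan(map50) and map50 > best_map + 1e-6:
            best_map, best_epoch = map50, epoch
            best_state = {k: v.copy() for k, v in model.network.state_dict().items()}
        if epoch - best_epoch >= cfg.patience:
            stopped = True
            break
    if best_state is not None:
        model.network.load_state_dict(best_state)
    if log_path is not None:
        Path(log_path).write_text(json.dumps([vars(e) for e in history], indent=1))
    if checkpoint_path is not None:
        model.save(checkpoint_path)
    return TrainResult(model, history, best_epoch, best_map, stopped)
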