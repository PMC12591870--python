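"""Synthetic ultrasound-like sessions with exact ground truth.

The clinical videos behind this project are not public, so every other
module is exercised against generated data: grayscale frames with
multiplicative speckle texture, one bright elongated rectangle (the cutter
slot) and one dark ("hypoechoic") ellipse (the tumor), moved along
scripted trajectories. The speckle model is multiplicative gamma noise on
a smooth background -- the simplest texture that exercises a detector; it
makes no claim of acoustic realism (no wave propagation, attenuation or
shadowing), so results on it bound software correctness, not clinical
performance.

Scripts are built so the activation predicate flips exactly at a known
frame, which gives end-to-end tests (and the detector stub) a sharp
oracle: with all noise at zero, the full pipeline must prompt at the
scripted frame, exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .engine import FramePacket
from .geometry import Box, DecisionConfig, ObjectClass, is_activation_position


class SceneError(ValueError):
    """Scene parameters place an object outside the frame."""


class ScriptError(ValueError):
    """A session script violates its procedure's visibility invariant."""


@dataclass(frozen=True)
class SceneParams:
    """Rendering parameters for one synthetic ultrasound scene.

    Intensities are 8-bit gray levels. ``speckle_variance`` is the
    variance of the unit-mean multiplicative field (0 disables texture).
    ``jitter`` is the amplitude in pixels of uniform per-frame positional
    noise added to both objects (clamped to keep them in frame).
    """

    width: int = 640
    height: int = 640
    background: float = 70.0
    speckle_variance: float = 0.05
    tumor_axes: tuple[float, float] = (45.0, 28.0)
    tumor_intensity: float = 22.0
    slot_size: tuple[float, float] = (150.0, 26.0)
    slot_intensity: float = 215.0
    jitter: float = 0.0


@dataclass(frozen=True)
class SessionScript:
    """Frame-by-frame object placement for one surgical session.

    ``slot_boxes``/``tumor_boxes`` hold one optional Box per frame (None =
    object not in the field of view). ``alignment_onset`` is the first
    frame index at which the visible geometry satisfies the activation
    rules; ``expected_prompt_frame`` is where the decision engine must
    fire given ``config`` (for the lateral approach this accounts for the
    cumulative overlap count, not just the onset).
    """

    procedure: int
    slot_boxes: tuple[Optional[Box], ...]
    tumor_boxes: tuple[Optional[Box], ...]
    alignment_onset: Optional[int]
    expected_prompt_frame: Optional[int]
    config: DecisionConfig = DecisionConfig()

    @property
    def n_frames(self) -> int:
        return len(self.slot_boxes)

    def __post_init__(self) -> None:
        if len(self.slot_boxes) != len(self.tumor_boxes):
            raise ScriptError("slot and tumor tracks must have equal length")
        if self.procedure not in (1, 2):
            raise ScriptError(f"procedure must be 1 or 2, got {self.procedure}")
        _validate_script(self)

    def ground_truth(self, i: int) -> list[Box]:
        out = []
        if self.slot_boxes[i] is not None:
            out.append(self.slot_boxes[i])
        if self.tumor_boxes[i] is not None:
            out.append(self.tumor_boxes[i])
        return out

    def to_json(self, path: str | Path) -> None:
        def enc(b: Optional[Box]):
            if b is None:
                return None
            return [b.x, b.y, b.length, b.height, int(b.class_id)]

        Path(path).write_text(json.dumps({
            "procedure": self.procedure,
            "alignment_onset": self.alignment_onset,
            "expected_prompt_frame": self.expected_prompt_frame,
            "slot_boxes": [enc(b) for b in self.slot_boxes],
            "tumor_boxes": [enc(b) for b in self.tumor_boxes],
        }))

    @staticmethod
    def from_json(path: str | Path) -> "SessionScript":
        d = json.loads(Path(path).read_text())

        def dec(v, cls):
            if v is None:
                return None
            return Box(v[0], v[1], v[2], v[3], class_id=ObjectClass(v[4]))

        return SessionScript(
            procedure=d["procedure"],
            slot_boxes=tuple(dec(v, ObjectClass.SLOT) for v in d["slot_boxes"]),
            tumor_boxes=tuple(dec(v, ObjectClass.TUMOR) for v in d["tumor_boxes"]),
            alignment_onset=d["alignment_onset"],
            expected_prompt_frame=d["expected_prompt_frame"],
        )


def _slot_box(cx: float, cy: float, scene: SceneParams) -> Box:
    L, H = scene.slot_size
    return Box(cx - L / 2, cy - H / 2, L, H, class_id=ObjectClass.SLOT)

def _tumor_box(cx: float, cy: float, scene: SceneParams) -> Box:
    a, b = scene.tumor_axes
    return Box(cx - a, cy - b, 2 * a, 2 * b, class_id=ObjectClass.TUMOR)


def procedure1_script(
    n_frames: int,
    onset: int,
    scene: SceneParams = SceneParams(),
    cfg: DecisionConfig = DecisionConfig(),
) -> SessionScript:
    """Co-visible approach: tumor static, slot rises from below toward it.

    The slot descends one pixel per frame (the cutter is advanced deeper
    beneath the skin); its trajectory is placed so the vertical overlap
    condition first holds exactly at ``onset`` (the horizontal condition
    holds throughout). Prompt is expected at onset.
    """
    if not 0 < onset < n_frames:
        raise ScriptError("onset must lie strictly inside the session")
    tum_cx, tum_cy = scene.width * 0.55, scene.height * 0.35
    tumor = _tumor_box(tum_cx, tum_cy, scene)
    # vertical condition: tumor.y - vf*H2 < slot.y  (slot top below threshold)
    thresh = tumor.y - cfg.vertical_factor * tumor.height
    slot_cx = tum_cx - scene.slot_size[0] * 0.25
    slots, tumors = [], []
    for t in range(n_frames):
        # vertical condition needs slot.y > thresh: the slot starts shallow
        # (above the threshold line) and crosses it exactly at `onset`
        y_top = thresh + 0.5 + (t - onset)  # > thresh iff t >= onset
        y_top = min(y_top, scene.height - scene.slot_size[1] - 1)
        slot = replace(
            _slot_box(slot_cx, scene.height / 2, scene), y=max(y_top, 0.0)
        )
        slots.append(slot)
        tumors.append(tumor)
        sat = is_activation_position(slot, tumor, cfg)
        if (t >= onset) != sat:
            raise ScriptError(f"trajectory fails to flip at onset (frame {t})")
    return SessionScript(1, tuple(slots), tuple(tumors), onset, onset, cfg)


def procedure2_script(
    slot_block: int = 10,
    tumor_block: int = 100,
    scene: SceneParams = SceneParams(),
    cfg: DecisionConfig = DecisionConfig(),
    tail_frames: int = 10,
) -> SessionScript:
    """Lateral approach: alternating slot-only and tumor-only visibility.

    Starts with a slot-only block (long enough to confirm the slot memory),
    then alternates tumor-only and slot-only blocks. Every tumor frame
    overlaps the remembered slot, so the engine's cumulative counter
    increments on each; the expected prompt frame is the
    ``cfg.overlap_frames_required``-th tumor frame of the session.
    """
    if slot_block < cfg.slot_confirm_frames:
        raise ScriptError(
            f"slot_block ({slot_block}) shorter than confirmation run "
            f"({cfg.slot_confirm_frames})"
        )
    tum_cx, tum_cy = scene.width * 0.55, scene.height * 0.35
    tumor = _tumor_box(tum_cx, tum_cy, scene)
    slot = replace(
        _slot_box(tum_cx - scene.slot_size[0] * 0.25, scene.height / 2, scene),
        y=tumor.y - cfg.vertical_factor * tumor.height + scene.tumor_axes[1] * 1.5,
    )
    if slot.y < 0 or slot.y2 > scene.height:
        raise ScriptError("slot resting position outside frame")
    if not is_activation_position(slot, tumor, cfg):
        raise ScriptError("lateral-script geometry does not overlap")
    slots: list[Optional[Box]] = []
    tumors: list[Optional[Box]] = []
    overlaps = 0
    expected = None
    slots += [slot] * slot_block
    tumors += [None] * slot_block
    while overlaps < cfg.overlap_frames_required:
        take = min(tumor_block, cfg.overlap_frames_required - overlaps)
        for _ in range(take):
            slots.append(None)
            tumors.append(tumor)
            overlaps += 1
            if overlaps == cfg.overlap_frames_required:
                expected = len(slots) - 1
        if overlaps < cfg.overlap_frames_required:
            slots += [slot] * slot_block
            tumors += [None] * slot_block
    slots += [None] * tail_frames
    tumors += [tumor] * tail_frames
    onset = slot_block  # first overlapping (tumor) frame
    return SessionScript(2, tuple(slots), tuple(tumors), onset, expected, cfg)


def random_scene_script(
    rng: np.random.Generator,
    scene: SceneParams = SceneParams(),
) -> SessionScript:
    """Single-frame script with randomized object geometry (both visible),
    for building independent-image detection datasets."""
    w, h = scene.width, scene.height
    a = rng.uniform(25, 70); b = rng.uniform(18, 45)
    tum = _tumor_box(rng.uniform(a + 5, w - a - 5), rng.uniform(b + 5, h * 0.6),
                     replace(scene, tumor_axes=(a, b)))
    L = rng.uniform(90, 200); H = rng.uniform(16, 40)
    sl = _slot_box(rng.uniform(L / 2 + 5, w - L / 2 - 5), h / 2,
                   replace(scene, slot_size=(L, H)))
    sl = replace(sl, y=float(rng.uniform(h * 0.3, h - H - 5)))
    return SessionScript(1, (sl,), (tum,), None, None)


def render_frame(
    scene: SceneParams,
    slot: Optional[Box],
    tumor: Optional[Box],
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, list[Box]]:
    """Render one grayscale frame and return it with its tight boxes.

    The background is a smooth random echogenicity field; visible objects
    are painted (bright rectangle, dark ellipse with soft edge) and the
    whole image is multiplied by unit-mean gamma speckle.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w, h = scene.width, scene.height
    for b in (slot, tumor):
        if b is not None and (b.x < 0 or b.y < 0 or b.x2 > w or b.y2 > h):
            raise SceneError(f"object outside {w}x{h} frame: {b}")
    base = np.full((h, w), scene.background, dtype=np.float64)
    field_ = gaussian_filter(rng.normal(0.0, 1.0, size=(h // 8, w // 8)), 3.0)
    base *= 1.0 + 0.25 * np.kron(field_, np.ones((8, 8)))[:h, :w]
    yy, xx = np.mgrid[0:h, 0:w]
    boxes: list[Box] = []
    if tumor is not None:
        cx, cy = tumor.center
        a, b2 = tumor.length / 2.0, tumor.height / 2.0
        r2 = ((xx + 0.5 - cx) / a) ** 2 + ((yy + 0.5 - cy) / b2) ** 2
        inside = np.clip((1.05 - r2) / 0.1, 0.0, 1.0)  # soft rim
        base = base * (1 - inside) + scene.tumor_intensity * inside
        boxes.append(tumor)
    if slot is not None:
        mask = (
            (xx + 0.5 >= slot.x) & (xx + 0.5 <= slot.x2)
            & (yy + 0.5 >= slot.y) & (yy + 0.5 <= slot.y2)
        )
        base[mask] = scene.slot_intensity
        boxes.append(slot)
    if scene.speckle_variance > 0:
        k = 1.0 / scene.speckle_variance
        base = base * rng.gamma(k, 1.0 / k, size=base.shape)
    return np.clip(base, 0, 255).astype(np.uint8), boxes


def _jittered(b: Optional[Box], dx: float, dy: float, scene: SceneParams) -> Optional[Box]:
    if b is None:
        return None
    x = min(max(b.x + dx, 0.0), scene.width - b.length)
    y = min(max(b.y + dy, 0.0), scene.height - b.height)
    return replace(b, x=x, y=y)


def simulate_session(
    script: SessionScript,
    scene: SceneParams = SceneParams(),
    seed: int = 0,
    render: bool = False,
    fps: float = 30.0,
) -> Iterator[tuple[FramePacket, list[Box], Optional[np.ndarray]]]:
    """Yield (packet, ground-truth boxes, image or None) per frame.

    The packet's ``detections`` are left empty -- a detector (stub or
    model) fills them downstream; ground truth is returned alongside.
    Deterministic given seed; rendering is optional because the decision
    engine operates purely on boxes.
    """
    _validate_script(script)
    for i in range(script.n_frames):
        rng = np.random.default_rng([seed, i])
        dx = dy = 0.0
        if scene.jitter > 0:
            dx, dy = rng.uniform(-scene.jitter, scene.jitter, size=2)
        slot = _jittered(script.slot_boxes[i], dx, dy, scene)
        tumor = _jittered(script.tumor_boxes[i], dx, dy, scene)
        image = None
        gt = [b for b in (slot, tumor) if b is not None]
        if render:
            image, gt = render_frame(scene, slot, tumor, rng)
        packet = FramePacket(frame_index=i, timestamp=i / fps)
        yield packet, gt, image


def _validate_script(script: SessionScript) -> None:
    if script.procedure == 1:
        started = False
        for s, t in zip(script.slot_boxes, script.tumor_boxes):
            if s is not None and t is not None:
                started = True
            elif started and (s is None) != (t is None):
                raise ScriptError(
                    "co-visible procedure: both objects must stay visible "
                    "after insertion"
                )
    else:
        for s, t in zip(script.slot_boxes, script.tumor_boxes):
            if s is not None and t is not None:
                raise ScriptError(
                    "lateral procedure: slot and tumor may not be co-visible"
                )


@dataclass(frozen=True)
class DetectorStub:
    """Ground-truth-backed detector with controllable degradation.

    With all noise parameters at zero it returns exactly the ground truth
    at confidence 1.0. Localization noise is Gaussian per coordinate;
    misses are Bernoulli per object; false positives are Poisson per frame
    with uniformly random geometry. Detections are deterministic given
    (seed, frame index).
    """

    noise_sd: float = 0.0
    miss_prob: float = 0.0
    fp_rate: float = 0.0
    confidence_loc: float = 0.9
    confidence_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.miss_prob <= 1.0:
            raise ValueError("miss_prob must lie in [0, 1]")
        if self.noise_sd < 0 or self.fp_rate < 0:
            raise ValueError("noise_sd and fp_rate must be >= 0")


def stub_detect(
    stub: DetectorStub,
    ground_truth: Sequence[Box],
    frame_index: int,
    scene: SceneParams = SceneParams(),
) -> list[Box]:
    """Detections for one frame under the stub's noise model."""
    rng = np.random.default_rng([stub.seed, frame_index])
    out: list[Box] = []
    for b in ground_truth:
        if rng.random() < stub.miss_prob:
            continue
        if stub.noise_sd > 0:
            dx, dy, dl, dh = rng.normal(0.0, stub.noise_sd, size=4)
        else:
            dx = dy = dl = dh = 0.0
        conf = 1.0 if stub.noise_sd == 0 and stub.miss_prob == 0 and stub.fp_rate == 0 \
            else float(np.clip(rng.normal(stub.confidence_loc, stub.confidence_sd), 0.05, 1.0))
        out.append(Box(
            x=max(b.x + dx, 0.0), y=max(b.y + dy, 0.0),
            length=max(b.length + dl, 1.0), height=max(b.height + dh, 1.0),
            class_id=b.class_id, confidence=conf,
        ))
    n_fp = rng.poisson(stub.fp_rate) if stub.fp_rate > 0 else 0
    for _ in range(n_fp):
        L = rng.uniform(20, 200); H = rng.uniform(10, 80)
        out.append(Box(
            x=rng.uniform(0, scene.width - L), y=rng.uniform(0, scene.height - H),
            length=L, height=H,
            class_id=ObjectClass(int(rng.integers(0, 2))),
            confidence=float(np.clip(rng.normal(0.4, 0.15), 0.05, 1.0)),
        ))
    return out


# ---------------------------------------------------------------------------
# YOLO-format dataset output
# ---------------------------------------------------------------------------

def box_to_yolo_line(b: Box, width: int, height: int) -> str:
    """Normalized 'class x_center y_center w h' label line."""
    cx = (b.x + b.length / 2) / width
    cy = (b.y + b.height / 2) / height
    return (
        f"{int(b.class_id)} {cx:.6f} {cy:.6f} "
        f"{b.length / width:.6f} {b.height / height:.6f}"
    )


def yolo_line_to_box(line: str, width: int, height: int, confidence: float = 1.0) -> Box:
    parts = line.split()
    cls = ObjectClass(int(parts[0]))
    cx, cy, wn, hn = (float(v) for v in parts[1:5])
    return Box(
        x=max(cx * width - wn * width / 2, 0.0),
        y=max(cy * height - hn * height / 2, 0.0),
        length=wn * width, height=hn * height,
        class_id=cls, confidence=confidence,
    )


def write_yolo_dataset(
    sessions: Sequence[tuple[str, SessionScript]],
    out_dir: str | Path,
    scene: SceneParams = SceneParams(),
    seed: int = 0,
) -> dict:
    """Write sessions as an images/ + labels/ tree with a dataset YAML and
    a patient-id sidecar.

    Each (patient_id, script) pair is rendered frame by frame; every frame
    gets a PNG and a label file (empty file -- not absent -- when no
    object is visible, so frame counts are preserved). Returns the
    manifest dictionary that is also written as ``dataset.yaml``.
    """
    import yaml

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    patients: dict[str, str] = {}
    n_images = 0
    for s_idx, (patient_id, script) in enumerate(sessions):
        for packet, gt, image in simulate_session(script, scene, seed=seed + s_idx, render=True):
            stem = f"s{s_idx:03d}_f{packet.frame_index:05d}"
            from PIL import Image

            Image.fromarray(image).save(out / "images" / f"{stem}.png")
            lines = [box_to_yolo_line(b, scene.width, scene.height) for b in gt]
            (out / "labels" / f"{stem}.txt").write_text(
                "\n".join(lines) + ("\n" if lines else "")
            )
            patients[stem] = patient_id
            n_images += 1
    manifest = {
        "path": str(out),
        "images": "images",
        "labels": "labels",
        "names": {0: "cutter_slot", 1: "tumor"},
        "nc": 2,
        "n_images": n_images,
        "image_size": [scene.width, scene.height],
    }
    (out / "dataset.yaml").write_text(yaml.safe_dump(manifest))
    (out / "patients.json").write_text(json.dumps(patients, indent=0))
    return manifest


def read_yolo_dataset(root: str | Path) -> tuple[dict[str, list[Box]], dict[str, str], dict]:
    """Read back an images/labels tree: returns (boxes per image id,
    patient ids, manifest)."""
    import yaml

    root = Path(root)
    manifest = yaml.safe_load((root / "dataset.yaml").read_text())
    w, h = manifest["image_size"]
    boxes: dict[str, list[Box]] = {}
    for label_file in sorted((root / "labels").glob("*.txt")):
        lines = [ln for ln in label_file.read_text().splitlines() if ln.strip()]
        boxes[label_file.stem] = [yolo_line_to_box(ln, w, h) for ln in lines]
    patients = json.loads((root / "patients.json").read_text())
    return boxes, patients, manifest
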