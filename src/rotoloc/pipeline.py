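"""Real-time session loop: ingest frames, detect, decide, annotate, log.

A *source* is anything that yields frames in order: a directory of
numbered PNG/JPEG images, a list of arrays, or a scripted synthetic
session. A *detector* is a callable ``(image, frame_index, ground_truth)
-> list[Box]``; the ground-truth argument lets the synthetic stub operate
without rendering, while image-based detectors ignore it.

The loop is single-threaded and frame-ordered by contract: no frame is
ever skipped, and a session is a pure function of (source, detector
configuration, decision configuration), so a recorded session replays to
identical events.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Optional, Sequence

import numpy as np

from .engine import (
    ActivationState,
    FramePacket,
    PromptEvent,
    PROMPT_MESSAGE,
    step,
)
from .geometry import Box, DecisionConfig, ObjectClass
from .synth import DetectorStub, SceneParams, SessionScript, simulate_session, stub_detect

Detector = Callable[[Optional[np.ndarray], int, Sequence[Box]], list[Box]]

SLOT_COLOR = (80, 220, 100)
TUMOR_COLOR = (235, 80, 80)


class DetectorContractError(ValueError):
    """The detector returned something that is not a list of valid boxes."""


class StreamIOError(IOError):
    """A frame source could not be read or written."""


def ground_truth_detector(stub: DetectorStub, scene: SceneParams = SceneParams()) -> Detector:
    """Wrap a :class:`DetectorStub` as a pipeline detector."""

    def detect(image, frame_index, ground_truth):
        return stub_detect(stub, ground_truth, frame_index, scene)

    return detect


def iter_image_dir(path: str | Path) -> Iterator[np.ndarray]:
    """Yield frames from a directory of numbered PNG/JPEG files in
    lexicographic (= numeric, when zero-padded) order."""
    from PIL import Image

    path = Path(path)
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg")
    )
    if not files:
        raise StreamIOError(f"no image frames found in {path}")
    for p in files:
        yield np.asarray(Image.open(p))


@dataclass
class FrameRecord:
    """Loggable summary of one processed frame."""

    frame_index: int
    timestamp: float
    detections: list[dict]

    @staticmethod
    def from_packet(p: FramePacket) -> "FrameRecord":
        return FrameRecord(
            p.frame_index,
            p.timestamp,
            [
                {
                    "x": b.x, "y": b.y, "length": b.length, "height": b.height,
                    "class_id": int(b.class_id), "confidence": b.confidence,
                }
                for b in p.detections
            ],
        )

    def to_packet(self) -> FramePacket:
        return FramePacket(
            self.frame_index,
            self.timestamp,
            tuple(
                Box(
                    d["x"], d["y"], d["length"], d["height"],
                    class_id=ObjectClass(d["class_id"]), confidence=d["confidence"],
                )
                for d in self.detections
            ),
        )


@dataclass
class SessionLog:
    """Complete record of a processed session."""

    procedure: int
    config: dict
    seed: Optional[int]
    frames: list[FrameRecord] = field(default_factory=list)
    events: list[PromptEvent] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "procedure": self.procedure,
            "config": self.config,
            "seed": self.seed,
            "frames": [asdict(f) for f in self.frames],
            "events": [asdict(e) for e in self.events],
        }, indent=0))

    @staticmethod
    def from_json(path: str | Path) -> "SessionLog":
        d = json.loads(Path(path).read_text())
        log = SessionLog(d["procedure"], d["config"], d["seed"])
        log.frames = [FrameRecord(**f) for f in d["frames"]]
        log.events = [PromptEvent(**e) for e in d["events"]]
        return log

    def events_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in self.events:
                fh.write(json.dumps(asdict(e)) + "\n")

    def replay(self, cfg: Optional[DecisionConfig] = None) -> list[PromptEvent]:
        """Re-run the decision engine over the logged detections; must
        reproduce the logged events."""
        cfg = cfg or DecisionConfig(**{
            k: v for k, v in self.config.items()
            if k in DecisionConfig.__dataclass_fields__
        })
        state = ActivationState.initial(self.procedure)
        events = []
        for rec in self.frames:
            state, event = step(state, rec.to_packet(), cfg)
            if event is not None:
                events.append(event)
        return events


def _validate_detections(dets, frame_index: int) -> list[Box]:
    if not isinstance(dets, (list, tuple)):
        raise DetectorContractError(
            f"detector returned {type(dets).__name__} at frame {frame_index}"
        )
    for b in dets:
        if not isinstance(b, Box):
            raise DetectorContractError(
                f"detector returned non-Box item at frame {frame_index}: {b!r}"
            )
    return list(dets)


def run_session(
    source,
    detector: Detector,
    procedure: int,
    cfg: DecisionConfig = DecisionConfig(),
    scene: SceneParams = SceneParams(),
    seed: int = 0,
    conf_threshold: float = 0.25,
    fps: float = 30.0,
    render: bool = False,
    annotate_dir: Optional[str | Path] = None,
) -> SessionLog:
    """Process a stream end to end and return the full session log.

    ``source`` may be a :class:`SessionScript` (synthetic session, with
    optional rendering), a directory path of numbered frames, or an
    iterable of images. Detections below ``conf_threshold`` are dropped
    before the decision engine; annotation output is written per frame
    when ``annotate_dir`` is given.
    """
    state = ActivationState.initial(procedure)
    log = SessionLog(
        procedure=procedure,
        config={**asdict(cfg), "conf_threshold": conf_threshold},
        seed=seed,
    )
    if annotate_dir is not None:
        Path(annotate_dir).mkdir(parents=True, exist_ok=True)

    for frame_index, timestamp, image, gt in _frames(source, scene, seed, fps, render or annotate_dir is not None):
        dets = _validate_detections(detector(image, frame_index, gt), frame_index)
        dets = [b for b in dets if b.confidence >= conf_threshold]
        packet = FramePacket(frame_index, timestamp, tuple(dets))
        state, event = step(state, packet, cfg)
        if event is not None:
            log.events.append(event)
        log.frames.append(FrameRecord.from_packet(packet))
        if annotate_dir is not None and image is not None:
            from PIL import Image

            out = annotate_frame(image, dets, state)
            Image.fromarray(out).save(Path(annotate_dir) / f"frame_{frame_index:05d}.png")
    return log


def _frames(source, scene, seed, fps, want_images):
    if isinstance(source, SessionScript):
        for packet, gt, image in simulate_session(
            source, scene, seed=seed, render=want_images, fps=fps
        ):
            yield packet.frame_index, packet.timestamp, image, gt
    elif isinstance(source, (str, Path)):
        for i, image in enumerate(iter_image_dir(source)):
            yield i, i / fps, image, []
    else:
        for i, image in enumerate(source):
            yield i, i / fps, np.asarray(image), []


def annotate_frame(
    image: np.ndarray,
    detections: Sequence[Box],
    state: ActivationState,
) -> np.ndarray:
    """Return an RGB copy of the frame with class-colored rectangles,
    confidence labels, and the activation banner once prompted."""
    from PIL import Image, ImageDraw

    img = Image.fromarray(image).convert("RGB")
    draw = ImageDraw.Draw(img)
    w, h = img.size
    for b in detections:
        color = SLOT_COLOR if b.class_id is ObjectClass.SLOT else TUMOR_COLOR
        x1 = min(max(b.x, 0), w - 1); y1 = min(max(b.y, 0), h - 1)
        x2 = min(max(b.x2, 0), w - 1); y2 = min(max(b.y2, 0), h - 1)
        draw.rectangle([x1, y1, x2, y2], outline=color, width=2)
        name = "slot" if b.class_id is ObjectClass.SLOT else "tumor"
        draw.text((x1 + 2, max(y1 - 12, 0)), f"{name} {b.confidence:.2f}", fill=color)
    if state.prompt_emitted:
        banner_h = max(18, h // 24)
        draw.rectangle([0, 0, w - 1, banner_h], fill=(20, 120, 40))
        draw.text((6, 3), PROMPT_MESSAGE, fill=(255, 255, 255))
    return np.asarray(img)


def extract_keyframes(
    source,
    interval: float = 10.0,
    fps: float = 30.0,
    out_dir: Optional[str | Path] = None,
) -> list[tuple[float, np.ndarray]]:
    """Uniformly sample one frame every ``interval`` seconds.

    Returns (timestamp, frame) pairs at t = 0, interval, 2*interval, ...;
    when ``out_dir`` is given each keyframe is also saved with its source
    timestamp in the filename.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    frames = []
    if isinstance(source, (str, Path)):
        it = iter_image_dir(source)
    else:
        it = iter(source)
    next_t = 0.0
    for i, image in enumerate(it):
        t = i / fps
        if t + 1e-9 >= next_t:
            frames.append((round(next_t, 6), np.asarray(image)))
            next_t += interval
    if out_dir is not None:
        from PIL import Image

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for t, img in frames:
            Image.fromarray(img).save(out / f"key_t{t:08.1f}.png")
    return frames


def write_session_video(
    log: SessionLog,
    frames: Iterable[np.ndarray],
    out: str | Path,
) -> Path:
    """Burn annotations into the frames and write an image-sequence
    'video' (numbered PNGs plus an index manifest).

    Container encoding (MP4/AVI) needs an ffmpeg backend, which this
    distribution does not assume; an image-sequence directory is the
    lossless, dependency-free equivalent and is accepted everywhere this
    package reads video.
    """
    out = Path(out)
    frames = list(frames)
    if not frames:
        raise StreamIOError("refusing to write an empty session video")
    if len(frames) != len(log.frames):
        raise StreamIOError(
            f"frame count mismatch: {len(frames)} images vs {len(log.frames)} log records"
        )
    out.mkdir(parents=True, exist_ok=True)
    from PIL import Image

    prompted_at = log.events[0].frame_index if log.events else None
    for rec, image in zip(log.frames, frames):
        state = ActivationState(
            procedure=log.procedure,
            prompt_emitted=prompted_at is not None and rec.frame_index >= prompted_at,
        )
        annotated = annotate_frame(np.asarray(image), rec.to_packet().detections, state)
        Image.fromarray(annotated).save(out / f"frame_{rec.frame_index:05d}.png")
    (out / "index.json").write_text(json.dumps({
        "n_frames": len(frames),
        "events": [asdict(e) for e in log.events],
    }))
    return out
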