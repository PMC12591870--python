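"""Per-frame activation state machines for the two surgical workflows.

Workflow I (co-visible approach): the cutter is inserted beneath the tumor
with probe held still, so slot and tumor appear together; the prompt fires
on the first frame whose detections satisfy the activation-position rules.

Workflow II (lateral approach): the cutter sits lateral to the tumor and
the probe alternates between the two, so they are rarely co-visible. The
slot position is recorded after a run of consecutive slot sightings, then
every tumor frame is tested against that remembered slot; once the
cumulative count of overlapping frames reaches the configured threshold
(500 by default) the prompt fires.

Both step functions are pure: they return a new state and never mutate
their inputs, so a recorded stream can be replayed to identical events.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .geometry import Box, DecisionConfig, ObjectClass, is_activation_position

PROMPT_MESSAGE = "The operation can begin now."


class StreamOrderError(ValueError):
    """Frame indices must be strictly increasing within a session."""


@dataclass(frozen=True)
class FramePacket:
    """One frame of a detection stream: index, timestamp and the boxes
    the detector reported for it. The image itself is referenced by path
    (or omitted) so packets stay cheap to copy and log."""

    frame_index: int
    timestamp: float = 0.0
    detections: tuple[Box, ...] = ()
    image_ref: Optional[str] = None


@dataclass(frozen=True)
class PromptEvent:
    """The single activation notification of a session."""

    frame_index: int
    timestamp: float
    message: str = PROMPT_MESSAGE


@dataclass(frozen=True)
class ActivationState:
    """Immutable state of the activation decision across a stream."""

    procedure: int = 1
    overlap_count: int = 0
    remembered_slot: Optional[Box] = None
    slot_sighting_streak: int = 0
    prompt_emitted: bool = False
    last_frame_index: int = -1

    @staticmethod
    def initial(procedure: int) -> "ActivationState":
        if procedure not in (1, 2):
            raise ValueError(f"procedure must be 1 or 2, got {procedure}")
        return ActivationState(procedure=procedure)


def select_primary(detections: Sequence[Box], class_id: ObjectClass) -> Optional[Box]:
    """Pick the single box that represents a class in a frame.

    Highest confidence wins; ties break to the larger area, then to the
    smaller x, so the choice is deterministic for any input order.
    """
    boxes = [b for b in detections if b.class_id is class_id]
    if not boxes:
        return None
    return max(boxes, key=lambda b: (b.confidence, b.area, -b.x))


def _check_order(state: ActivationState, frame: FramePacket) -> None:
    if frame.frame_index <= state.last_frame_index:
        raise StreamOrderError(
            f"frame index {frame.frame_index} not greater than "
            f"previous {state.last_frame_index}"
        )


def procedure1_step(
    state: ActivationState, frame: FramePacket, cfg: DecisionConfig = DecisionConfig()
) -> tuple[ActivationState, Optional[PromptEvent]]:
    """Advance the co-visible-approach state machine by one frame.

    Emits the prompt on the first frame where a slot and a tumor are both
    detected and the activation-position rules hold; the prompt is
    emitted at most once per session.
    """
    if state.procedure != 1:
        raise ValueError("procedure1_step requires a procedure-1 state")
    _check_order(state, frame)
    state = replace(state, last_frame_index=frame.frame_index)
    if state.prompt_emitted:
        return state, None
    slot = select_primary(frame.detections, ObjectClass.SLOT)
    tumor = select_primary(frame.detections, ObjectClass.TUMOR)
    if slot is None or tumor is None:
        return state, None
    if is_activation_position(slot, tumor, cfg):
        event = PromptEvent(frame.frame_index, frame.timestamp)
        return replace(state, prompt_emitted=True), event
    return state, None


def procedure2_step(
    state: ActivationState, frame: FramePacket, cfg: DecisionConfig = DecisionConfig()
) -> tuple[ActivationState, Optional[PromptEvent]]:
    """Advance the lateral-approach state machine by one frame.

    Slot sightings build a consecutive streak; once the streak reaches
    ``cfg.slot_confirm_frames`` the latest slot box is recorded (and later
    confirmed sightings update it). Frames with a tumor detection and a
    recorded slot are tested for positional overlap; each hit increments a
    cumulative counter that never resets (unless ``cfg.reset_on_miss``),
    and the prompt fires on the frame where the counter reaches
    ``cfg.overlap_frames_required``.
    """
    if state.procedure != 2:
        raise ValueError("procedure2_step requires a procedure-2 state")
    _check_order(state, frame)
    state = replace(state, last_frame_index=frame.frame_index)

    slot = select_primary(frame.detections, ObjectClass.SLOT)
    tumor = select_primary(frame.detections, ObjectClass.TUMOR)

    if slot is not None:
        streak = state.slot_sighting_streak + 1
        remembered = state.remembered_slot
        if streak >= cfg.slot_confirm_frames:
            remembered = slot
        state = replace(state, slot_sighting_streak=streak, remembered_slot=remembered)
    else:
        state = replace(state, slot_sighting_streak=0)

    if state.prompt_emitted:
        return state, None

    if tumor is not None and state.remembered_slot is not None:
        if is_activation_position(state.remembered_slot, tumor, cfg):
            state = replace(state, overlap_count=state.overlap_count + 1)
        elif cfg.reset_on_miss:
            state = replace(state, overlap_count=0)

    if state.overlap_count >= cfg.overlap_frames_required:
        event = PromptEvent(frame.frame_index, frame.timestamp)
        return replace(state, prompt_emitted=True), event
    return state, None


def step(
    state: ActivationState, frame: FramePacket, cfg: DecisionConfig = DecisionConfig()
) -> tuple[ActivationState, Optional[PromptEvent]]:
    """Dispatch to the state machine matching ``state.procedure``."""
    if state.procedure == 1:
        return procedure1_step(state, frame, cfg)
    return procedure2_step(state, frame, cfg)
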