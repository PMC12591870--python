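"""Geometric activation rules for cutter-slot positioning.

During ultrasound-guided rotational resection of a breast tumor, the
aperture ("cutter slot") of the rotating cannula must sit horizontally to
the left of and vertically overlapping the tumor before the surgeon may
activate cutting. Both structures are detected per frame as axis-aligned
boxes; the rules below compare the two boxes.

All rules are dimensionally homogeneous of degree one: rescaling both
boxes (and the pixel margin) by a common factor does not change any
decision. Coordinates are image pixels, origin top-left, y downward.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace


class ObjectClass(enum.IntEnum):
    """Detection classes; integer values match the dataset label ids."""

    SLOT = 0
    TUMOR = 1


class SizeScenario(enum.Enum):
    """Relative-size regimes that select which alignment rule applies."""

    SLOT_LARGER = "slot_larger"
    TUMOR_LARGER = "tumor_larger"
    SIMILAR = "similar"


class InvalidGeometryError(ValueError):
    """A box violates its geometric invariants."""


class RoleError(ValueError):
    """A box was passed in the wrong detection-class role."""


@dataclass(frozen=True)
class Box:
    """Axis-aligned pixel rectangle: top-left corner, length (x extent),
    height (y extent).

    Coordinates are real-valued; detector outputs are sub-pixel and no
    rounding happens inside the decision rules.
    """

    x: float
    y: float
    length: float
    height: float
    class_id: ObjectClass = ObjectClass.TUMOR
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not (self.length > 0 and self.height > 0):
            raise InvalidGeometryError(
                f"box dimensions must be positive, got length={self.length}, "
                f"height={self.height}"
            )
        if self.x < 0 or self.y < 0:
            raise InvalidGeometryError(
                f"box origin must be non-negative, got ({self.x}, {self.y})"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise InvalidGeometryError(
                f"confidence must lie in [0, 1], got {self.confidence}"
            )

    @property
    def x2(self) -> float:
        return self.x + self.length

    @property
    def y2(self) -> float:
        return self.y + self.height

    @property
    def area(self) -> float:
        return self.length * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.length / 2.0, self.y + self.height / 2.0)

    def scaled(self, s: float) -> "Box":
        """Return the box with all coordinates and dimensions multiplied by s."""
        if s <= 0:
            raise InvalidGeometryError(f"scale must be positive, got {s}")
        return replace(
            self, x=self.x * s, y=self.y * s, length=self.length * s, height=self.height * s
        )


@dataclass(frozen=True)
class DecisionConfig:
    """Thresholds of the activation rules.

    size_margin
        Pixel margin deciding when the slot and tumor count as different
        sized (default 20 px).
    horizontal_factor
        Fraction of the reference length allowed as horizontal tolerance
        (default 0.2).
    vertical_factor
        Fraction of the tumor height used in the vertical-overlap test
        (default 1.1).
    extension_factor
        Temporary tumor-length extension applied in the similar-size
        regime (default 1.2).
    overlap_frames_required
        Cumulative overlapping frames required before the lateral-approach
        procedure prompts (default 500).
    slot_confirm_frames
        Consecutive slot sightings required before the lateral-approach
        procedure records the slot position (default 5).
    reset_on_miss
        If True, a non-overlapping frame resets the overlap counter
        (stricter, consecutive interpretation). Default False: the counter
        is cumulative.
    """

    size_margin: float = 20.0
    horizontal_factor: float = 0.2
    vertical_factor: float = 1.1
    extension_factor: float = 1.2
    overlap_frames_required: int = 500
    slot_confirm_frames: int = 5
    reset_on_miss: bool = False

    def __post_init__(self) -> None:
        if self.size_margin < 0:
            raise ValueError("size_margin must be >= 0")
        for name in ("horizontal_factor", "vertical_factor", "extension_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.overlap_frames_required < 1:
            raise ValueError("overlap_frames_required must be >= 1")
        if self.slot_confirm_frames < 1:
            raise ValueError("slot_confirm_frames must be >= 1")


def _require_roles(slot: Box, tumor: Box) -> None:
    if slot.class_id is not ObjectClass.SLOT or tumor.class_id is not ObjectClass.TUMOR:
        raise RoleError(
            f"expected (slot, tumor) roles, got ({slot.class_id.name}, {tumor.class_id.name})"
        )


def size_scenario(slot: Box, tumor: Box, cfg: DecisionConfig = DecisionConfig()) -> SizeScenario:
    """Classify the relative horizontal size of slot and tumor.

    The slot counts as larger when L1 - L2 exceeds the margin, smaller
    when L2 - L1 exceeds it; everything else -- including an exact-margin
    tie -- is the similar-size regime, whose extension rule is the
    fallback for ambiguous sizes.
    """
    _require_roles(slot, tumor)
    diff = slot.length - tumor.length
    if diff > cfg.size_margin:
        return SizeScenario.SLOT_LARGER
    if -diff > cfg.size_margin:
        return SizeScenario.TUMOR_LARGER
    return SizeScenario.SIMILAR


def aligned_slot_larger(slot: Box, tumor: Box, cfg: DecisionConfig = DecisionConfig()) -> bool:
    """Alignment test when the slot is the larger object.

    Horizontal: x1 - L1*0.2 < x2 (slot's left edge, minus a 20 % slack of
    its own length, lies left of the tumor). Vertical: y2 - H2*1.1 < y1
    (slot top edge below the tumor's slack-extended top). Both strict.
    """
    horizontal = slot.x - slot.length * cfg.horizontal_factor < tumor.x
    vertical = tumor.y - tumor.height * cfg.vertical_factor < slot.y
    return horizontal and vertical


def aligned_slot_smaller(slot: Box, tumor: Box, cfg: DecisionConfig = DecisionConfig()) -> bool:
    """Alignment test when the tumor is the larger object.

    The horizontal comparison is reversed -- x2 - L2*0.2 < x1 -- so that
    the tumor falls within the slot's horizontal range; the vertical test
    is the same as in the slot-larger regime.
    """
    horizontal = tumor.x - tumor.length * cfg.horizontal_factor < slot.x
    vertical = tumor.y - tumor.height * cfg.vertical_factor < slot.y
    return horizontal and vertical


def extend_tumor(tumor: Box, cfg: DecisionConfig = DecisionConfig()) -> Box:
    """Return the tumor with its length temporarily extended (L2' = L2 * 1.2),
    top-left corner unchanged. The input box is not modified."""
    return replace(tumor, length=tumor.length * cfg.extension_factor)


def is_activation_position(
    slot: Box, tumor: Box, cfg: DecisionConfig = DecisionConfig()
) -> bool:
    """Full activation-position decision.

    Dispatches on the relative-size regime: slot-larger and tumor-larger
    use their respective alignment rules directly; similar sizes apply the
    tumor-larger rule to the length-extended tumor.
    """
    scenario = size_scenario(slot, tumor, cfg)
    if scenario is SizeScenario.SLOT_LARGER:
        return aligned_slot_larger(slot, tumor, cfg)
    if scenario is SizeScenario.TUMOR_LARGER:
        return aligned_slot_smaller(slot, tumor, cfg)
    return aligned_slot_smaller(slot, extend_tumor(tumor, cfg), cfg)


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes."""
    ix = min(a.x2, b.x2) - max(a.x, b.x)
    iy = min(a.y2, b.y2) - max(a.y, b.y)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)
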