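"""Activation-rule unit and property tests.

The brute-force oracle re-evaluates the printed inequalities directly,
without the scenario-dispatch layer, and must agree everywhere.
"""

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from rotoloc.geometry import (
    Box,
    DecisionConfig,
    InvalidGeometryError,
    ObjectClass,
    RoleError,
    SizeScenario,
    aligned_slot_larger,
    aligned_slot_smaller,
    extend_tumor,
    is_activation_position,
    size_scenario,
)
from conftest import make_slot, make_tumor


def oracle(slot: Box, tumor: Box, cfg: DecisionConfig) -> bool:
    """Direct evaluation of the printed inequalities, no dispatch layer."""
    x1, y1, L1, H1 = slot.x, slot.y, slot.length, slot.height
    x2, y2, L2, H2 = tumor.x, tumor.y, tumor.length, tumor.height
    vertical = y2 - H2 * cfg.vertical_factor < y1
    if L1 - L2 > cfg.size_margin:
        return (x1 - L1 * cfg.horizontal_factor < x2) and vertical
    if L2 - L1 > cfg.size_margin:
        return (x2 - L2 * cfg.horizontal_factor < x1) and vertical
    L2e = L2 * cfg.extension_factor
    return (x2 - L2e * cfg.horizontal_factor < x1) and vertical


class TestSizeScenario:
    @pytest.mark.parametrize(
        "L1, L2, expected",
        [
            (100, 60, SizeScenario.SLOT_LARGER),
            (60, 100, SizeScenario.TUMOR_LARGER),
            (100, 90, SizeScenario.SIMILAR),
            (100, 80, SizeScenario.SIMILAR),  # |diff| == margin -> similar
            (80, 100, SizeScenario.SIMILAR),
            (100.0, 79.9999, SizeScenario.SLOT_LARGER),
        ],
    )
    def test_dispatch(self, L1, L2, expected, cfg):
        assert size_scenario(make_slot(length=L1), make_tumor(length=L2), cfg) is expected

    def test_partition_is_total(self, cfg, rng):
        """Every (L1, L2) pair lands in exactly one regime."""
        for L1, L2 in rng.uniform(1, 500, size=(500, 2)):
            s = size_scenario(make_slot(length=L1), make_tumor(length=L2), cfg)
            assert s in SizeScenario

    def test_role_enforcement(self, cfg):
        with pytest.raises(RoleError):
            size_scenario(make_tumor(), make_tumor(), cfg)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(InvalidGeometryError):
            Box(0, 0, -5, 10)
        with pytest.raises(InvalidGeometryError):
            Box(0, 0, 5, 0)
        with pytest.raises(InvalidGeometryError):
            Box(-1, 0, 5, 5)


class TestAlignmentRules:
    def test_slot_larger_hand_case(self, cfg):
        # 200 - 20 = 180 < 190 and 140 - 44 = 96 < 150
        assert aligned_slot_larger(make_slot(), make_tumor(), cfg)

    def test_slot_larger_vertical_fails(self, cfg):
        # slot too shallow: 96 < 50 is false
        assert not aligned_slot_larger(make_slot(y=50), make_tumor(), cfg)

    def test_slot_larger_extreme_separation(self, cfg):
        slot = make_slot(x=0, y=1e6, length=1, height=1)
        tumor = make_tumor(x=1e6, y=0, length=1, height=1)
        assert aligned_slot_larger(slot, tumor, cfg)

    def test_slot_smaller_hand_case(self, cfg):
        slot = make_slot(x=300, y=120, length=40, height=20)
        tumor = make_tumor(x=290, y=100, length=80, height=50)
        # 290 - 16 = 274 < 300 and 100 - 55 = 45 < 120
        assert aligned_slot_smaller(slot, tumor, cfg)

    def test_slot_smaller_horizontal_fails(self, cfg):
        slot = make_slot(x=100, y=120, length=40, height=20)
        tumor = make_tumor(x=290, y=100, length=80, height=50)
        assert not aligned_slot_smaller(slot, tumor, cfg)

    def test_identical_boxes_align(self, cfg):
        slot = make_slot(x=0, y=0, length=50, height=50)
        tumor = make_tumor(x=0, y=0, length=50, height=50)
        # 0 - 10 = -10 < 0 and 0 - 55 = -55 < 0
        assert aligned_slot_smaller(slot, tumor, cfg)


class TestExtendTumor:
    def test_printed_extension(self, cfg):
        t = make_tumor(x=50, y=60, length=100, height=40)
        e = extend_tumor(t, cfg)
        assert (e.x, e.y, e.length, e.height) == (50, 60, 120, 40)
        assert t.length == 100  # input untouched

    def test_identity_factor(self):
        t = make_tumor(length=77.0)
        assert extend_tumor(t, DecisionConfig(extension_factor=1.0)).length == 77.0

    def test_fractional_lengths_not_rounded(self, cfg):
        assert extend_tumor(make_tumor(length=0.5), cfg).length == pytest.approx(0.6)


class TestActivationPosition:
    def test_similar_path_hand_case(self, cfg):
        slot = make_slot(x=300, y=120, length=100, height=30)
        tumor = make_tumor(x=290, y=100, length=95, height=50)
        # similar sizes; L2' = 114; 290 - 22.8 = 267.2 < 300; 100 - 55 = 45 < 120
        assert is_activation_position(slot, tumor, cfg)

    def test_vertical_condition_is_common(self, cfg, rng):
        """If y2 - 1.1*H2 >= y1, the answer is no in every regime."""
        for _ in range(200):
            L1, L2 = rng.uniform(10, 300, size=2)
            H2 = rng.uniform(10, 100)
            y2 = rng.uniform(H2 * 1.1 + 1, 1000)  # ensures threshold >= 0
            y1 = rng.uniform(0, y2 - H2 * 1.1)
            slot = make_slot(x=rng.uniform(0, 500), y=y1, length=L1)
            tumor = make_tumor(x=rng.uniform(0, 500), y=y2, length=L2, height=H2)
            assert not is_activation_position(slot, tumor, cfg)

    def test_oracle_equivalence_exhaustive_grid(self, cfg):
        """>= 10^4 box pairs spanning all three regimes agree with the
        direct inequality oracle."""
        vals = np.linspace(1, 400, 12)
        count = 0
        for x1 in vals[::2]:
            for y1 in vals[::2]:
                for L1 in (30, 60, 90, 150):
                    for x2 in vals[::2]:
                        for y2 in vals[::3]:
                            for L2 in (40, 70, 130):
                                slot = make_slot(x=x1, y=y1, length=L1, height=25)
                                tumor = make_tumor(x=x2, y=y2, length=L2, height=45)
                                assert is_activation_position(slot, tumor, cfg) == oracle(
                                    slot, tumor, cfg
                                )
                                count += 1
        assert count >= 10_000

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        x1=st.floats(0, 1000), y1=st.floats(0, 1000), L1=st.floats(1, 500),
        H1=st.floats(1, 200), x2=st.floats(0, 1000), y2=st.floats(0, 1000),
        L2=st.floats(1, 500), H2=st.floats(1, 200),
        s=st.floats(0.01, 100),
    )
    def test_scale_covariance(self, x1, y1, L1, H1, x2, y2, L2, H2, s):
        """All conditions are homogeneous of degree 1: rescaling the boxes
        and the pixel margin together leaves the decision unchanged."""
        slot = make_slot(x=x1, y=y1, length=L1, height=H1)
        tumor = make_tumor(x=x2, y=y2, length=L2, height=H2)
        cfg = DecisionConfig()
        # keep clear of decision boundaries where float rounding of the
        # scaled arithmetic could legitimately flip a strict inequality
        for margin in (
            abs(L1 - L2) - cfg.size_margin,
            x1 - L1 * cfg.horizontal_factor - x2,
            x2 - L2 * cfg.horizontal_factor - x1,
            x2 - L2 * cfg.extension_factor * cfg.horizontal_factor - x1,
            y2 - H2 * cfg.vertical_factor - y1,
        ):
            assume(abs(margin) > 1e-6 * max(abs(x1), abs(x2), L1, L2, abs(y1), abs(y2), 1.0))
        scaled_cfg = DecisionConfig(size_margin=cfg.size_margin * s)
        base = is_activation_position(slot, tumor, cfg)
        scaled = is_activation_position(slot.scaled(s), tumor.scaled(s), scaled_cfg)
        assert base == scaled
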