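"""Morphometrics against brute-force and closed-form shape oracles."""

import numpy as np
import pytest

from vnqi.morphometrics import measure, skeletonize_and_graph
from vnqi.synthetic import GeneratorConfig, VesselMask, generate_mask

from .conftest import bar_mask


def test_all_zero_mask_gives_empty_graph_and_zero_metrics():
    mask = VesselMask(np.zeros((64, 64), dtype=np.uint8), 2.0)
    g = skeletonize_and_graph(mask)
    assert g.nodes == [] and g.segments == []
    mm = measure(mask)
    assert all(v == 0 for v in mm.as_dict().values())


def test_all_ones_mask_has_full_coverage():
    mask = VesselMask(np.ones((100, 100), dtype=np.uint8), 1.0)
    assert measure(mask).vessel_coverage == 1.0


def test_single_bar_graph_and_metrics():
    """A 3x100 px bar: one segment between two endpoints; coverage, length
    and diameter match the hand-computed values within pixel tolerances."""
    mask = bar_mask()
    g = skeletonize_and_graph(mask)
    assert g.endpoint_count == 2
    assert g.branchpoint_count == 0
    assert len(g.segments) == 1

    mm = measure(mask)
    assert mm.vessel_coverage == pytest.approx(300 / 40000)
    assert mm.segment_count == 1
    assert mm.branchpoint_count == 0
    # skeleton endpoints retract into the bar: allow 4 px slack
    assert mm.total_vessel_length == pytest.approx(100.0, abs=4.0)
    # EDT-based diameter overestimates a 3 px bar by up to 1 px
    assert mm.mean_segment_diameter == pytest.approx(3.0, abs=1.0)


def test_plus_sign_branch_topology():
    """Two crossing 3 px bars: one merged branchpoint, 4 arms, 4 endpoints."""
    px = np.zeros((200, 200), dtype=np.uint8)
    px[99:102, 50:150] = 1
    px[50:150, 99:102] = 1
    g = skeletonize_and_graph(VesselMask(px, 1.0))
    assert g.branchpoint_count == 1
    assert g.endpoint_count == 4
    assert len(g.segments) == 4


def _rect_library():
    """>= 10 disjoint axis-aligned rectangle masks with closed-form metrics."""
    shapes = []
    # single bars of varying width/length
    for w, ln in [(3, 60), (5, 40), (7, 80), (3, 100), (9, 50)]:
        px = np.zeros((160, 160), dtype=np.uint8)
        px[30 : 30 + w, 20 : 20 + ln] = 1
        shapes.append((px, [(w, ln)]))
    # multi-bar "grids" of disjoint rectangles
    for k, w, ln in [(3, 3, 70), (4, 5, 50), (5, 3, 90), (2, 7, 60), (6, 3, 40)]:
        px = np.zeros((220, 220), dtype=np.uint8)
        bars = []
        for i in range(k):
            r = 15 + i * 30
            px[r : r + w, 10 : 10 + ln] = 1
            bars.append((w, ln))
        shapes.append((px, bars))
    return shapes


@pytest.mark.parametrize("pitch", [1.0, 2.5])
def test_rectangle_library_matches_closed_forms(pitch):
    for px, bars in _rect_library():
        mask = VesselMask(px, pitch)
        mm = measure(mask)
        n_px = sum(w * ln for w, ln in bars)
        assert mm.vessel_coverage == pytest.approx(n_px / px.size)
        assert mm.segment_count == len(bars)
        assert mm.branchpoint_count == 0
        # each bar's skeleton is a straight run of ~length px, retracted by
        # at most its width at each end
        lo = sum((ln - 2 * w) * pitch for w, ln in bars)
        hi = sum(ln * pitch for w, ln in bars)
        assert lo <= mm.total_vessel_length <= hi
        # EDT diameter of a w-px bar lies in [w-1, w+1] px
        diams = [mm.mean_segment_diameter]
        mean_w = np.mean([w for w, _ in bars]) * pitch
        assert abs(diams[0] - mean_w) <= 1.2 * pitch


def test_metrics_invariant_under_translation():
    a = bar_mask(row=40, col0=20)
    b = bar_mask(row=120, col0=70)
    assert measure(a).as_dict() == measure(b).as_dict()


def test_metrics_invariant_under_rotation_constructed():
    """Exact count/coverage equality, lengths within 1%, for a clean shape."""
    px = np.zeros((200, 200), dtype=np.uint8)
    px[99:102, 50:150] = 1
    px[50:150, 99:102] = 1
    a = measure(VesselMask(px, 1.0))
    b = measure(VesselMask(np.rot90(px).copy(), 1.0))
    assert a.vessel_coverage == b.vessel_coverage
    assert a.segment_count == b.segment_count
    assert a.branchpoint_count == b.branchpoint_count
    assert b.total_vessel_length == pytest.approx(a.total_vessel_length, rel=0.01)


def test_metrics_near_invariant_under_rotation_generated():
    """Thinning is not exactly rotation-equivariant on complex networks:
    coverage matches exactly, counts to ~5%, lengths to 1%."""
    mask = generate_mask(GeneratorConfig(rng_seed=5))
    a = measure(mask)
    b = measure(VesselMask(np.rot90(mask.pixels).copy(), mask.pixel_pitch))
    assert a.vessel_coverage == b.vessel_coverage
    assert b.segment_count == pytest.approx(a.segment_count, rel=0.05)
    assert b.branchpoint_count == pytest.approx(a.branchpoint_count, rel=0.05)
    assert b.total_vessel_length == pytest.approx(a.total_vessel_length, rel=0.01)
    assert b.mean_segment_diameter == pytest.approx(a.mean_segment_diameter, rel=0.02)


def test_dilation_never_decreases_coverage_or_diameter():
    from scipy import ndimage

    for seed in (1, 2, 3):
        mask = generate_mask(GeneratorConfig(rng_seed=seed))
        grown = VesselMask(
            ndimage.binary_dilation(mask.pixels).astype(np.uint8), mask.pixel_pitch
        )
        a, b = measure(mask), measure(grown)
        assert b.vessel_coverage >= a.vessel_coverage
        assert b.mean_segment_diameter >= a.mean_segment_diameter


def test_non_binary_mask_rejected():
    arr = np.zeros((10, 10), dtype=np.uint8)
    arr[3, 3] = 7
    with pytest.raises(ValueError, match="not binary"):
        VesselMask(arr, 1.0)


def test_spur_pruning_removes_short_terminal_branches():
    """A bar with a 3 px stub: pruned at spur_len_px=5, kept at 0."""
    px = np.zeros((60, 120), dtype=np.uint8)
    px[29:32, 10:110] = 1
    px[26:29, 60] = 1  # 3 px stub off the top edge
    pruned = skeletonize_and_graph(VesselMask(px, 1.0), spur_len_px=5)
    kept = skeletonize_and_graph(VesselMask(px, 1.0), spur_len_px=0)
    assert len(pruned.segments) <= len(kept.segments)
    assert len(pruned.segments) == 1
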