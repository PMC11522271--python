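"""Boundary tracing and key-point detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import ndimage

from dtwstrain import (
    KeypointFailure,
    NoForeground,
    find_annular_endpoints,
    find_apex,
    trace_boundary,
)
from dtwstrain.geometry import shoelace_area
from dtwstrain.landmarks import clean_mask
from dtwstrain.pipeline import extract_contours
from dtwstrain.types import MaskSequence, RunConfig


class TestTraceBoundary:
    def test_empty_mask_raises(self):
        with pytest.raises(NoForeground):
            trace_boundary(np.zeros((10, 10), dtype=bool))

    def test_largest_component_wins(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[2:12, 2:12] = True       # 100 px
        mask[20:25, 25:26] = True     # 5 px
        poly = trace_boundary(mask)
        assert shoelace_area(poly) == pytest.approx(100.0)

    def test_area_matches_pixel_count_on_phantom(self, phantom_factory):
        _, masks, _ = phantom_factory(shortening_amplitude=0.2, n_frames=32)
        mask = masks.frames[0]
        poly = trace_boundary(mask)
        count = clean_mask(mask).sum()
        assert abs(shoelace_area(poly) - count) / count < 0.02

    def test_boundary_vertices_unique(self, phantom_factory):
        _, masks, _ = phantom_factory(shortening_amplitude=0.2, n_frames=32)
        poly = trace_boundary(masks.frames[0])
        assert len(np.unique(poly, axis=0)) == len(poly)

    def test_diagonal_pinch_still_single_polygon(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = mask[1, 1] = True  # corner-touching pair
        poly = trace_boundary(mask)
        assert shoelace_area(poly) == pytest.approx(2.0)

    @settings(max_examples=40, deadline=None)
    @given(hnp.arrays(bool, (12, 12), elements=st.booleans()))
    def test_area_equals_component_pixel_count(self, mask):
        if not mask.any():
            with pytest.raises(NoForeground):
                trace_boundary(mask)
            return
        poly = trace_boundary(mask)
        assert shoelace_area(poly) == pytest.approx(clean_mask(mask).sum())


class TestAnnularEndpoints:
    def test_filled_disk_has_no_opening(self):
        yy, xx = np.mgrid[0:64, 0:64]
        disk = (xx - 32) ** 2 + (yy - 32) ** 2 < 20**2
        with pytest.raises(KeypointFailure):
            find_annular_endpoints(disk)

    def test_symmetric_phantom_endpoints_mirror(self, phantom_factory):
        spec, masks, _ = phantom_factory(
            shortening_amplitude=0.0, n_frames=8,
            thickness_septal=12.0, thickness_lateral=12.0,
        )
        septal, lateral, _ = find_annular_endpoints(masks.frames[0])
        cx = spec.image_size[1] / 2.0
        assert abs((septal[0] - cx) + (lateral[0] - cx)) <= 2.0
        assert abs(septal[1] - lateral[1]) <= 2.0

    def test_endpoints_near_ground_truth(self, deforming_run):
        _, _, truth, result = deforming_run
        for f, cf in enumerate(result.contours):
            assert np.hypot(*(cf.septal_annulus - truth.annulus_per_frame[f, 0])) < 3.0
            assert np.hypot(*(cf.lateral_annulus - truth.annulus_per_frame[f, 1])) < 3.0

    def test_endpoints_inside_foreground(self, deforming_run):
        _, masks, _, result = deforming_run
        for f, cf in enumerate(result.contours):
            for p in (cf.septal_annulus, cf.lateral_annulus):
                assert masks.frames[f][int(round(p[1])), int(round(p[0]))]

    def test_septal_side_convention_flips(self, phantom_factory):
        _, masks, _ = phantom_factory(shortening_amplitude=0.0, n_frames=8)
        s_left, l_left, _ = find_annular_endpoints(masks.frames[0], septal_side="left")
        s_right, l_right, _ = find_annular_endpoints(masks.frames[0], septal_side="right")
        assert s_left[0] < l_left[0]
        assert s_right[0] > l_right[0]


class TestApex:
    def test_apex_near_ground_truth(self, deforming_run):
        _, _, truth, result = deforming_run
        for f, cf in enumerate(result.contours):
            assert np.hypot(*(cf.apex - truth.apex_outer_per_frame[f])) < 3.0

    def test_apex_farther_from_base_than_annuli(self, deforming_run):
        _, _, _, result = deforming_run
        for cf in result.contours:
            base_mid = 0.5 * (cf.septal_annulus + cf.lateral_annulus)
            d_apex = np.hypot(*(cf.apex - base_mid))
            assert d_apex > np.hypot(*(cf.septal_annulus - base_mid))
            assert d_apex > np.hypot(*(cf.lateral_annulus - base_mid))

    def test_rotation_robustness(self, phantom_factory):
        _, masks, truth = phantom_factory(shortening_amplitude=0.2, n_frames=32)
        frame = masks.frames[0]
        rot = ndimage.rotate(frame.astype(np.uint8), 30, reshape=False, order=0)
        rot = rot.astype(bool)
        boundary = trace_boundary(rot)
        septal, lateral, _ = find_annular_endpoints(rot)
        apex = find_apex(boundary, septal, lateral)
        ang = np.deg2rad(30)
        c = (np.array(frame.shape[::-1]) - 1) / 2.0
        rotm = np.array([[np.cos(ang), np.sin(ang)], [-np.sin(ang), np.cos(ang)]])
        apex_truth = rotm @ (truth.apex_outer_per_frame[0] - c) + c
        sep_truth = rotm @ (truth.annulus_per_frame[0, 0] - c) + c
        assert np.hypot(*(apex - apex_truth)) < 3.0
        # the rotated septal annulus stays the more counterclockwise end;
        # compare against whichever detected endpoint is nearer
        d = min(np.hypot(*(septal - sep_truth)), np.hypot(*(lateral - sep_truth)))
        assert d < 3.0


class TestCavityAreaSeries:
    def test_constant_sequence_ties_break_earliest(self, static_run):
        _, _, _, result = static_run
        assert result.ed_frame == 0
        assert result.es_frame == 0
        assert np.all(result.cavity_areas > 0)

    def test_single_cycle_ed_and_es_phase(self, deforming_run):
        spec, _, _, result = deforming_run
        assert result.ed_frame == 0
        assert abs(result.es_frame - spec.n_frames // 2) <= 1
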