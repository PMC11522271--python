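"""Layer splitting and fixed-count arc resampling."""

import numpy as np
import pytest

from dtwstrain import resample_layer, split_contour_layers
from dtwstrain.resample import smooth_arc
from dtwstrain.errors import DegenerateArc
from dtwstrain.geometry import polyline_length, project_point_onto_polyline
from dtwstrain.resample import cavity_centroid


@pytest.fixture(scope="module")
def split_frame(deforming_run):
    """Raw (staircase) arcs straight from the boundary split."""
    _, _, _, result = deforming_run
    cf = result.contours[0]
    endo, epi = split_contour_layers(cf)
    return cf, endo, epi


@pytest.fixture(scope="module")
def smooth_frame(split_frame):
    """The arcs as the pipeline feeds them to the resampler."""
    cf, endo, epi = split_frame
    return cf, smooth_arc(endo), smooth_arc(epi)


class TestSplit:
    def test_endo_closer_to_cavity_centroid(self, split_frame):
        cf, endo, epi = split_frame
        cav = cavity_centroid(cf.mask)
        d_endo = np.hypot(*(endo - cav).T).mean()
        d_epi = np.hypot(*(epi - cav).T).mean()
        assert d_endo < d_epi

    def test_arcs_ordered_septal_first(self, split_frame):
        cf, endo, epi = split_frame
        for arc in (endo, epi):
            d_sep = np.hypot(*(arc[0] - cf.septal_annulus))
            d_lat = np.hypot(*(arc[0] - cf.lateral_annulus))
            assert d_sep < d_lat

    def test_arcs_are_disjoint_boundary_subsets(self, split_frame):
        cf, endo, epi = split_frame
        boundary_set = {tuple(p) for p in cf.boundary}
        endo_set = {tuple(p) for p in endo}
        epi_set = {tuple(p) for p in epi}
        assert endo_set <= boundary_set and epi_set <= boundary_set
        assert not (endo_set & epi_set)


class TestResampleLayer:
    def test_fixed_point_count(self, smooth_frame):
        cf, endo, _ = smooth_frame
        out = resample_layer(endo, cf.apex, 193)
        assert out.shape == (193, 2)

    def test_apex_pinned_at_middle_index(self, smooth_frame):
        cf, endo, _ = smooth_frame
        out = resample_layer(endo, cf.apex, 193)
        s_apex, proj = project_point_onto_polyline(cf.apex, endo)
        assert np.hypot(*(out[96] - proj)) < 1e-9

    def test_length_preserved(self, smooth_frame):
        cf, endo, epi = smooth_frame
        for arc in (endo, epi):
            out = resample_layer(arc, cf.apex, 193)
            assert polyline_length(out) == pytest.approx(
                polyline_length(arc), rel=0.01
            )

    def test_wall_spacing_uniform(self, smooth_frame):
        cf, endo, _ = smooth_frame
        out = resample_layer(endo, cf.apex, 193)
        for wall in (out[:97], out[96:]):
            steps = np.hypot(*np.diff(wall, axis=0).T)
            assert steps.max() - steps.min() <= 0.01 * steps.mean() + 1e-9

    def test_idempotent_on_equally_spaced_arc(self, smooth_frame):
        cf, endo, _ = smooth_frame
        once = resample_layer(endo, cf.apex, 193)
        twice = resample_layer(once, once[96], 193)
        assert np.hypot(*(once - twice).T).max() < 0.5

    def test_refinement_stability(self, smooth_frame):
        """Doubling the arc's vertex density moves no resampled point by > 1 px."""
        cf, endo, _ = smooth_frame
        dense = np.empty((2 * len(endo) - 1, 2))
        dense[0::2] = endo
        dense[1::2] = 0.5 * (endo[:-1] + endo[1:])
        coarse = resample_layer(endo, cf.apex, 193)
        fine = resample_layer(dense, cf.apex, 193)
        assert np.hypot(*(coarse - fine).T).max() < 1.0

    def test_degenerate_arc_rejected(self):
        with pytest.raises(DegenerateArc):
            resample_layer(np.zeros((6, 2)), np.array([0.0, 0.0]), 193)

    def test_odd_count_required(self, smooth_frame):
        cf, endo, _ = smooth_frame
        with pytest.raises(ValueError):
            resample_layer(endo, cf.apex, 192)


class TestLayerGeometry:
    def test_endo_closer_to_cavity_all_frames(self, deforming_run):
        _, _, _, result = deforming_run
        for lc, cf in zip(result.layers, result.contours):
            cav = cavity_centroid(cf.mask)
            assert np.hypot(*(lc.endo - cav).T).mean() < np.hypot(*(lc.epi - cav).T).mean()

    def test_cavity_area_positive_and_cyclic(self, deforming_run):
        spec, _, _, result = deforming_run
        areas = result.cavity_areas
        assert np.all(areas > 0)
        # cavity shrinks toward mid-cycle and recovers
        assert areas[spec.n_frames // 2] < 0.9 * areas[0]
        assert areas[0] == areas.max()
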