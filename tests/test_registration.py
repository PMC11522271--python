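"""DTW alignment, unit construction and proportional-area block merging."""


import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtwstrain import build_units, define_block_targets, dtw_align
from dtwstrain.errors import PartitionFailure
from dtwstrain.geometry import shoelace_area
from dtwstrain.registration import _snap_borders, partition_wall
from dtwstrain.types import DTWAlignment


def brute_force_dtw_cost(a: np.ndarray, b: np.ndarray) -> float:
    """Minimal cost over all monotone paths, by exhaustive enumeration."""
    n, m = len(a), len(b)
    cost = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    best = [np.inf]

    def walk(i, j, acc):
        if acc >= best[0]:
            return
        if (i, j) == (n - 1, m - 1):
            best[0] = acc
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            if i + di < n and j + dj < m:
                walk(i + di, j + dj, acc + cost[i + di, j + dj])

    walk(0, 0, cost[0, 0])
    return best[0]


class TestDTWAlign:
    def test_identical_sequences_align_diagonally(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10)])
        align = dtw_align(pts, pts)
        assert align.cost == 0.0
        assert np.array_equal(align.path, np.column_stack([np.arange(10)] * 2))

    def test_three_point_parallel_walls(self):
        endo = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        epi = np.array([[0.0, 1.0], [1.0, 1.0], [2.0, 1.0]])
        align = dtw_align(endo, epi)
        assert np.array_equal(align.path, [[0, 0], [1, 1], [2, 2]])
        assert align.cost == pytest.approx(3.0)
        assert align.cost == pytest.approx(brute_force_dtw_cost(endo, epi))

    def test_path_pinned_at_both_ends(self, deforming_run):
        _, _, _, result = deforming_run
        lc = result.layers[0]
        for side in ("septal", "lateral"):
            align = dtw_align(lc.wall("endo", side), lc.wall("epi", side))
            assert tuple(align.path[0]) == (0, 0)
            assert tuple(align.path[-1]) == (96, 96)
            steps = np.diff(align.path, axis=0)
            assert set(map(tuple, steps)) <= {(1, 0), (0, 1), (1, 1)}

    @settings(max_examples=100, deadline=None)
    @given(
        st.integers(2, 8), st.integers(2, 8),
        st.randoms(use_true_random=False),
    )
    def test_cost_matches_brute_force(self, n, m, rnd):
        rng = np.random.default_rng(rnd.getrandbits(32))
        a = rng.uniform(0, 10, size=(n, 2))
        b = rng.uniform(0, 10, size=(m, 2))
        align = dtw_align(a, b)
        assert align.cost == pytest.approx(brute_force_dtw_cost(a, b), rel=1e-9)


class TestBuildUnits:
    def test_diagonal_path_gives_quadrilaterals(self):
        endo = np.column_stack([np.arange(5.0), np.zeros(5)])
        epi = np.column_stack([np.arange(5.0), np.ones(5)])
        align = dtw_align(endo, epi)
        polys, areas = build_units(align, endo, epi)
        assert len(polys) == 4
        assert all(len(p) == 4 for p in polys)
        assert areas == pytest.approx(np.ones(4))

    def test_vertical_step_gives_triangle(self):
        path = np.array([[0, 0], [0, 1], [1, 2]])
        endo = np.array([[0.0, 0.0], [1.0, 0.0]])
        epi = np.array([[0.0, 1.0], [0.5, 1.0], [1.0, 1.0]])
        polys, areas = build_units(DTWAlignment(path=path, cost=0.0), endo, epi)
        assert len(polys[0]) == 3
        assert areas[0] == pytest.approx(shoelace_area(polys[0]))

    def test_units_tile_the_wall_band(self, deforming_run):
        _, _, _, result = deforming_run
        lc = result.layers[0]
        for side in ("septal", "lateral"):
            endo_w = lc.wall("endo", side)
            epi_w = lc.wall("epi", side)
            align = dtw_align(endo_w, epi_w)
            _, areas = build_units(align, endo_w, epi_w)
            band = np.vstack([endo_w, epi_w[::-1]])
            assert areas.sum() == pytest.approx(shoelace_area(band), rel=0.01)


class TestBlockTargets:
    def test_fractions_strictly_increasing_to_one(self, deforming_run):
        _, _, _, result = deforming_run
        for wall in (result.partitions[0].septal, result.partitions[0].lateral):
            targets = define_block_targets(wall.unit_areas, 30)
            assert len(targets) == 31
            assert np.all(np.diff(targets) > 0)
            assert targets[0] == 0.0
            assert targets[-1] == pytest.approx(1.0)

    def test_uniform_units_merge_into_equal_blocks(self):
        # straight band, 90 identical units (divisible into 30 blocks)
        endo = np.column_stack([np.linspace(0, 90, 91), np.zeros(91)])
        epi = np.column_stack([np.linspace(0, 90, 91), np.ones(91)])
        align = dtw_align(endo, epi)
        _, areas = build_units(align, endo, epi)
        targets = define_block_targets(areas, 30)
        wall = partition_wall(align, areas, targets)
        assert len(wall.block_areas) == 30
        mean = wall.block_areas.mean()
        assert np.all(np.abs(wall.block_areas - mean) <= 0.05 * mean)

    def test_too_few_units_rejected(self):
        with pytest.raises(PartitionFailure):
            _snap_borders(np.ones(5), np.arange(1, 30) / 30)


class TestPartition:
    def test_sixty_blocks_sixtyone_borders(self, deforming_run):
        _, _, _, result = deforming_run
        for part in result.partitions:
            assert part.n_blocks == 60
            assert part.n_borders == 61
            assert len(part.block_polygons) == 60

    def test_ed_frame_reproduces_its_own_targets(self, deforming_run):
        _, _, _, result = deforming_run
        part = result.partitions[result.ed_frame]
        for wall in (part.septal, part.lateral):
            nominal = np.arange(31) / 30
            # achieved ED fractions are the nearest-node snaps of k/30
            assert np.abs(wall.cumulative_fractions - nominal).max() < 0.05

    def test_block_areas_sum_to_unit_areas(self, deforming_run):
        _, _, _, result = deforming_run
        for part in result.partitions:
            for wall in (part.septal, part.lateral):
                assert wall.block_areas.sum() == pytest.approx(
                    wall.unit_areas.sum(), rel=1e-9
                )

    def test_snapping_error_bounded_by_largest_unit(self, deforming_run):
        _, _, _, result = deforming_run
        ed = result.partitions[result.ed_frame]
        for part in result.partitions:
            for wall, ed_wall in ((part.septal, ed.septal), (part.lateral, ed.lateral)):
                max_unit_frac = wall.unit_areas.max() / wall.unit_areas.sum()
                dev = np.abs(wall.cumulative_fractions - ed_wall.cumulative_fractions)
                assert dev.max() <= max_unit_frac + 1e-12

    def test_static_sequence_partition_constant(self, static_run):
        _, _, _, result = static_run
        ref = result.partitions[0]
        for part in result.partitions[1:]:
            assert np.array_equal(part.borders, ref.borders)
            assert np.allclose(part.block_areas, ref.block_areas)

    def test_borders_strictly_ordered_along_path(self, deforming_run):
        _, _, _, result = deforming_run
        for part in result.partitions:
            for wall in (part.septal, part.lateral):
                assert np.all(np.diff(wall.border_nodes) > 0)
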