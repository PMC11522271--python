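"""DTW myocardial registration: align endo/epi walls, merge units into blocks.

Dynamic time warping is used *spatially* here: within each wall the 97
endocardial and 97 epicardial points are aligned by classic dynamic
programming (Euclidean local cost, steps (1,0)/(0,1)/(1,1), both ends
pinned). Consecutive alignment pairs bound small triangular or
quadrilateral units; the units are merged into a fixed number of blocks
per wall (default 30, i.e. 3 segments x 10 blocks) such that each
block's *share* of the wall area matches its share at end-diastole —
proportional, not absolute, area conservation. Because the septum is
usually thicker than the lateral wall, the proportional rule is applied
to each wall separately. Block serial numbers (1..60 from the septal
annulus over the apex to the lateral annulus) then provide temporal
correspondence between frames without any tracking.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .errors import PartitionFailure
from .geometry import shoelace_area
from .types import BlockPartition, DTWAlignment, LayerContours, WallPartition

_DIAG, _UP, _LEFT = 0, 1, 2  # predecessor codes, in tie-preference order


def dtw_align(endo_wall: np.ndarray, epi_wall: np.ndarray) -> DTWAlignment:
    """Optimal monotone alignment of two equal-orientation point sequences.

    Ends are pinned: the path starts at (0, 0) and ends at
    (len(endo)-1, len(epi)-1). Ties between predecessors prefer the
    diagonal step.
    """
    a = np.asarray(endo_wall, dtype=float)
    b = np.asarray(epi_wall, dtype=float)
    cost = cdist(a, b)
    n, m = cost.shape
    D = np.full((n, m), np.inf)
    ptr = np.zeros((n, m), dtype=np.uint8)
    D[0, 0] = cost[0, 0]
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + cost[0, j]
        ptr[0, j] = _LEFT
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + cost[i, 0]
        ptr[i, 0] = _UP
        row_prev = D[i - 1]
        row = D[i]
        for j in range(1, m):
            c_diag = row_prev[j - 1]
            c_up = row_prev[j]
            c_left = row[j - 1]
            best, code = c_diag, _DIAG
            if c_up < best:
                best, code = c_up, _UP
            if c_left < best:
                best, code = c_left, _LEFT
            row[j] = best + cost[i, j]
            ptr[i, j] = code

    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        code = ptr[i, j]
        if code == _DIAG:
            i, j = i - 1, j - 1
        elif code == _UP:
            i -= 1
        else:
            j -= 1
        path.append((i, j))
    path.reverse()
    return DTWAlignment(path=np.asarray(path, dtype=int), cost=float(D[-1, -1]))


def build_units(
    alignment: DTWAlignment, endo_wall: np.ndarray, epi_wall: np.ndarray
) -> tuple[list[np.ndarray], np.ndarray]:
    """Unit polygons and areas between consecutive alignment path nodes.

    For the step (i, j) -> (i', j') the unit is the polygon
    endo[i], endo[i'], epi[j'], epi[j] — a quadrilateral when both
    indices advance, a triangle otherwise. Duplicate vertices are
    dropped; degenerate (zero-area) units keep a slot in the area array
    so path-node bookkeeping stays aligned, but contribute no area.
    """
    path = alignment.path
    polys: list[np.ndarray] = []
    areas = np.zeros(len(path) - 1)
    for k in range(len(path) - 1):
        i, j = path[k]
        i2, j2 = path[k + 1]
        quad = np.array([endo_wall[i], endo_wall[i2], epi_wall[j2], epi_wall[j]])
        keep = np.ones(4, dtype=bool)
        for v in range(4):
            if np.array_equal(quad[v], quad[(v + 1) % 4]):
                keep[(v + 1) % 4] = False
        poly = quad[keep]
        polys.append(poly)
        areas[k] = shoelace_area(poly)
    return polys, areas


def define_block_targets(unit_areas: np.ndarray, n_blocks: int = 30) -> np.ndarray:
    """End-diastolic cumulative area fractions for one wall's block borders.

    Nominal targets are k/n_blocks (equal thirds x equal tenths by
    default); each is snapped to the nearest DTW path node by cumulative
    unit area, kept strictly increasing. The *achieved* post-snap
    fractions are returned (length ``n_blocks + 1``, starting at 0 and
    ending at 1) and become the binding targets for every other frame.
    """
    border_idx = _snap_borders(unit_areas, np.arange(1, n_blocks) / n_blocks)
    cum = np.concatenate([[0.0], np.cumsum(unit_areas)]) / unit_areas.sum()
    return cum[np.concatenate([[0], border_idx, [len(unit_areas)]])]


def _snap_borders(unit_areas: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Node indices (into cumulative-area vector) nearest each target fraction."""
    total = unit_areas.sum()
    if total <= 0:
        raise PartitionFailure("wall has zero area")
    cum = np.concatenate([[0.0], np.cumsum(unit_areas)]) / total
    n_nodes = len(cum)
    if n_nodes - 1 < len(targets) + 1:
        raise PartitionFailure(
            f"only {n_nodes} path nodes for {len(targets) + 1} blocks"
        )
    idx = np.empty(len(targets), dtype=int)
    prev = 0
    for k, t in enumerate(targets):
        lo = prev + 1
        hi = n_nodes - (len(targets) - k)  # leave room for remaining borders
        if lo > hi - 1:
            raise PartitionFailure("not enough path nodes to place all borders")
        j = lo + int(np.argmin(np.abs(cum[lo:hi] - t)))
        idx[k] = j
        prev = j
    return idx


def partition_wall(
    alignment: DTWAlignment,
    unit_areas: np.ndarray,
    ed_cumulative_fractions: np.ndarray,
) -> WallPartition:
    """Place block borders in one wall of one frame against the ED targets."""
    interior_targets = ed_cumulative_fractions[1:-1]
    border_idx = _snap_borders(unit_areas, interior_targets)
    border_nodes = np.concatenate([[0], border_idx, [len(unit_areas)]])
    cum = np.concatenate([[0.0], np.cumsum(unit_areas)]) / unit_areas.sum()
    block_areas = np.diff(np.concatenate([[0.0], np.cumsum(unit_areas)])[border_nodes])
    return WallPartition(
        alignment=alignment,
        unit_areas=unit_areas,
        border_nodes=border_nodes,
        block_areas=block_areas,
        cumulative_fractions=cum[border_nodes],
    )


def _wall_blocks(
    wall: WallPartition, endo_wall: np.ndarray, epi_wall: np.ndarray
) -> tuple[list[np.ndarray], np.ndarray]:
    """Block polygons (endo run + reversed epi run) and border transversals."""
    path = wall.alignment.path
    polys = []
    for a, b in zip(wall.border_nodes[:-1], wall.border_nodes[1:]):
        i_a, j_a = path[a]
        i_b, j_b = path[b]
        endo_run = endo_wall[i_a : i_b + 1]
        epi_run = epi_wall[j_a : j_b + 1][::-1]
        polys.append(np.vstack([endo_run, epi_run]))
    borders = np.array(
        [[endo_wall[path[n][0]], epi_wall[path[n][1]]] for n in wall.border_nodes]
    )
    return polys, borders


def partition_frame(
    layers: LayerContours,
    targets_septal: np.ndarray,
    targets_lateral: np.ndarray,
) -> BlockPartition:
    """Register one frame: per-wall DTW, units, and ED-anchored block merge.

    Returns the frame's :class:`BlockPartition` with blocks numbered from
    the septal annulus (serial 1) over the apex to the lateral annulus.
    Both walls share the apex border, so ``n_borders == n_blocks + 1``.
    """
    walls = {}
    for side in ("septal", "lateral"):
        endo_w = layers.wall("endo", side)
        epi_w = layers.wall("epi", side)
        align = dtw_align(endo_w, epi_w)
        _, areas = build_units(align, endo_w, epi_w)
        targets = targets_septal if side == "septal" else targets_lateral
        walls[side] = partition_wall(align, areas, targets)

    sep_polys, sep_borders = _wall_blocks(
        walls["septal"], layers.wall("endo", "septal"), layers.wall("epi", "septal")
    )
    lat_polys, lat_borders = _wall_blocks(
        walls["lateral"], layers.wall("endo", "lateral"), layers.wall("epi", "lateral")
    )
    borders = np.vstack([sep_borders, lat_borders[1:]])  # shared apex border once
    block_areas = np.concatenate(
        [walls["septal"].block_areas, walls["lateral"].block_areas]
    )
    return BlockPartition(
        frame_index=layers.frame_index,
        septal=walls["septal"],
        lateral=walls["lateral"],
        borders=borders,
        block_polygons=sep_polys + lat_polys,
        block_areas=block_areas,
    )


def define_frame_targets(
    layers: LayerContours, n_blocks_per_wall: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """ED-frame block targets for both walls (septal, lateral)."""
    out = []
    for side in ("septal", "lateral"):
        endo_w = layers.wall("endo", side)
        epi_w = layers.wall("epi", side)
        align = dtw_align(endo_w, epi_w)
        _, areas = build_units(align, endo_w, epi_w)
        out.append(define_block_targets(areas, n_blocks_per_wall))
    return out[0], out[1]
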