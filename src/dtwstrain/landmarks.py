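"""Boundary tracing and key-point detection on binary myocardium masks.

Per frame the pipeline needs three anatomical key points before the
contour can be split into walls and layers:

* the **septal** and **lateral annular endpoints** — the two open ends of
  the U-shaped band at the mitral base. They are found by skeletonizing
  the mask to a one-pixel curve, taking the convex hull of the skeleton
  points, and scanning adjacent hull vertices: the pair whose chord
  midpoint falls *outside* the foreground spans the cavity opening.
* the **apex** — found by least-squares ellipse fit to the boundary; the
  boundary point extremal along the ellipse major axis, on the side away
  from the annular midpoint.

End-diastole / end-systole are defined from the cavity-area series
(largest / smallest LV area).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage.measure import EllipseModel
from skimage.morphology import skeletonize

from .errors import KeypointFailure, NoForeground
from .geometry import shoelace_area

_STRUCT8 = np.ones((3, 3), dtype=bool)


def clean_mask(mask: np.ndarray, frame_index: int | None = None) -> np.ndarray:
    """Largest 8-connected component with holes filled."""
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise NoForeground(f"mask has no foreground pixels (frame {frame_index})")
    labels, n = ndimage.label(m, structure=_STRUCT8)
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        m = labels == (int(np.argmax(counts)) + 1)
    return ndimage.binary_fill_holes(m)


def trace_boundary(mask: np.ndarray, frame_index: int | None = None) -> np.ndarray:
    """Trace the pixel-region outline as one ordered closed polygon.

    The polygon runs along pixel *corners* (crack edges between
    foreground and background), so its shoelace area equals the pixel
    count exactly. Returned as (N, 2) float (x, y); implicitly closed.
    """
    m = clean_mask(mask, frame_index)
    return _trace_crack_boundary(m)


def _trace_crack_boundary(m: np.ndarray) -> np.ndarray:
    h, w = m.shape
    pad = np.zeros((h + 2, w + 2), dtype=bool)
    pad[1:-1, 1:-1] = m
    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}

    def add(starts_r, starts_c, drc):
        for r, c in zip(starts_r, starts_c):
            edges.setdefault((c, r), []).append(drc)

    fg = pad
    rr, cc = np.nonzero(fg & ~np.roll(fg, 1, axis=0))   # background above: east edge
    add(rr, cc, (1, 0))
    rr, cc = np.nonzero(fg & ~np.roll(fg, -1, axis=1))  # background right: south edge
    add(rr, cc + 1, (0, 1))
    rr, cc = np.nonzero(fg & ~np.roll(fg, -1, axis=0))  # background below: west edge
    add(rr + 1, cc + 1, (-1, 0))
    rr, cc = np.nonzero(fg & ~np.roll(fg, 1, axis=1))   # background left: north edge
    add(rr + 1, cc, (0, -1))

    # chain edges into loops; at pinch corners (two outgoing cracks)
    # prefer the continuation that crosses to the diagonal neighbour so a
    # single 8-connected component yields a single loop.
    visited: set[tuple[int, int, int, int]] = set()
    loops: list[np.ndarray] = []
    for start, dirs in edges.items():
        for d0 in dirs:
            if (start[0], start[1], d0[0], d0[1]) in visited:
                continue
            loop = []
            pos, d = start, d0
            while True:
                visited.add((pos[0], pos[1], d[0], d[1]))
                loop.append(pos)
                pos = (pos[0] + d[0], pos[1] + d[1])
                cand = [nd for nd in edges.get(pos, ())
                        if (pos[0], pos[1], nd[0], nd[1]) not in visited]
                if not cand:
                    break
                if len(cand) == 1:
                    d = cand[0]
                else:
                    # pick minimal cross(d, nd): the left-crossing branch
                    d = min(cand, key=lambda nd: d[0] * nd[1] - d[1] * nd[0])
            loops.append(np.asarray(loop, dtype=float))
    poly = max(loops, key=len)
    poly -= 1.0  # undo padding offset
    return poly


def find_annular_endpoints(
    mask: np.ndarray,
    septal_side: str = "left",
    frame_index: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Locate the two annular endpoints of the U-shaped band.

    Returns ``(septal, lateral, skeleton_points)`` with points as (x, y).
    Raises :class:`KeypointFailure` when no adjacent convex-hull pair of
    skeleton points has an exterior chord midpoint (e.g. a closed blob).
    """
    m = clean_mask(mask, frame_index)
    skel = skeletonize(m)
    pts = np.argwhere(skel)[:, ::-1].astype(float)  # (x, y)
    if len(pts) < 3:
        raise KeypointFailure(f"degenerate skeleton (frame {frame_index})")
    try:
        hull = ConvexHull(pts)
    except Exception as exc:  # collinear skeleton
        raise KeypointFailure(f"degenerate skeleton hull (frame {frame_index}): {exc}")
    verts = pts[hull.vertices]
    h, w = m.shape
    best = None
    for k in range(len(verts)):
        a, b = verts[k], verts[(k + 1) % len(verts)]
        mid = 0.5 * (a + b)
        col = int(round(mid[0]))
        row = int(round(mid[1]))
        outside = not (0 <= row < h and 0 <= col < w) or not m[row, col]
        if outside:
            chord = float(np.hypot(*(a - b)))
            if best is None or chord > best[0]:
                best = (chord, a, b)
    if best is None:
        raise KeypointFailure(
            f"no exterior hull-chord midpoint; mask has no cavity opening (frame {frame_index})"
        )
    _, a, b = best
    a = _refine_onto_medial(a, pts, m)
    b = _refine_onto_medial(b, pts, m)
    first_is_septal = a[0] < b[0] if septal_side == "left" else a[0] > b[0]
    septal, lateral = (a, b) if first_is_septal else (b, a)
    return septal, lateral, pts


def _refine_onto_medial(
    endpoint: np.ndarray, skeleton_points: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Snap a hull endpoint to the distal end of the medial line.

    The raw hull vertex may be a thinning-spur tip off the medial line,
    or a mid-wall skeleton point when the true band end is not a hull
    vertex. Both jitter between frames. The refinement walks the
    skeleton near the vertex, keeps the points that reach farthest along
    the outward wall direction (the band end), and among those returns
    the most medial one (largest distance-transform value).
    """
    edt = ndimage.distance_transform_edt(mask)
    skel_edt = edt[
        skeleton_points[:, 1].astype(int), skeleton_points[:, 0].astype(int)
    ]
    t_half = float(np.median(skel_edt))
    d = annulus_outward_direction(endpoint, skeleton_points, t_half)
    geo = _skeleton_geodesic_distances(endpoint, skeleton_points)
    near = geo <= 4.0 * t_half + 5.0
    if not near.any():
        return endpoint
    cand_pts = skeleton_points[near]
    cand_edt = skel_edt[near]
    # medial points carry near-maximal clearance; spur points decay
    # toward their tip, so this cut removes the spurs
    medial = cand_edt >= cand_edt.max() - 1.5
    cand_pts = cand_pts[medial]
    proj = cand_pts @ d
    best = cand_pts[int(np.argmax(proj))].astype(float)
    # thinning is directionally biased by up to ~2 px; re-center the
    # endpoint transversally on the centroid of the local band
    # cross-section, which is symmetric by construction
    t_loc = edt[int(round(best[1])), int(round(best[0]))]
    rows, cols = np.nonzero(mask)
    pix = np.column_stack([cols + 0.5, rows + 0.5]) - best
    along = pix @ d
    nearby = np.abs(along) <= 1.5
    if nearby.any():
        e = np.array([-d[1], d[0]])
        trans = pix[nearby] @ e
        trans = trans[np.abs(trans) <= 1.5 * max(t_loc, 1.0)]
        if len(trans):
            best = best + e * trans.mean()
    return best


def find_apex(
    boundary: np.ndarray,
    septal_annulus: np.ndarray,
    lateral_annulus: np.ndarray,
    frame_index: int | None = None,
) -> np.ndarray:
    """Apex = boundary point extremal along the fitted-ellipse major axis.

    The major-axis direction is signed to point away from the annular
    midpoint, so the extremal point is at the closed (apical) end of the
    U rather than at the base. Because the rasterized boundary is flat
    over several pixels at the apical pole, all boundary points within
    two pixels of the maximal projection are averaged and the boundary
    point nearest that centroid is returned; this keeps the result a
    boundary point while suppressing raster jitter along the flat top.
    """
    pts = np.asarray(boundary, dtype=float)
    model = EllipseModel.from_estimate(pts)
    if not model:
        raise KeypointFailure(f"degenerate ellipse fit (frame {frame_index})")
    xc, yc = model.center
    a, b = model.axis_lengths
    theta = model.theta
    axis = np.array([np.cos(theta), np.sin(theta)])
    if b > a:
        axis = np.array([-np.sin(theta), np.cos(theta)])
    base_mid = 0.5 * (np.asarray(septal_annulus) + np.asarray(lateral_annulus))
    if np.dot(axis, np.array([xc, yc]) - base_mid) < 0:
        axis = -axis
    proj = pts @ axis
    top = pts[proj >= proj.max() - 2.0]
    centroid = top.mean(axis=0)
    d2 = np.einsum("ij,ij->i", pts - centroid, pts - centroid)
    return pts[int(np.argmin(d2))]


def annulus_outward_direction(
    annulus: np.ndarray, skeleton_points: np.ndarray, half_thickness: float
) -> np.ndarray:
    """Unit direction pointing from the wall interior out through the base end.

    The local wall direction is the principal axis of the skeleton
    points in a distance window around the annular endpoint. Distances
    are geodesic along the skeleton: a Euclidean ball would swallow
    points of the opposite wall when the ventricle is strongly
    contracted and the two base ends come close. Points nearer than
    about one wall thickness are excluded because thinning leaves short
    branch spurs at the band end.
    """
    annulus = np.asarray(annulus, dtype=float)
    geo = _skeleton_geodesic_distances(annulus, skeleton_points)
    lo = 2.0 * half_thickness
    hi = lo + max(20.0, 2.0 * half_thickness)
    window = skeleton_points[(geo >= lo) & (geo <= hi)]
    if len(window) < 3:
        order = np.argsort(np.where(np.isfinite(geo), geo, np.inf))
        window = skeleton_points[order[: max(5, int(2 * half_thickness))]]
    centered = window - window.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    v = vt[0]
    if np.dot(v, annulus - window.mean(axis=0)) < 0:
        v = -v
    return v / np.hypot(*v)


def _skeleton_geodesic_distances(
    source: np.ndarray, skeleton_points: np.ndarray
) -> np.ndarray:
    """Geodesic distance from ``source`` to every skeleton point.

    Dijkstra over the 8-connected skeleton pixel graph (step costs 1 and
    sqrt(2)), started from the skeleton pixel nearest the source.
    Unreachable points get inf.
    """
    import heapq

    pts = skeleton_points.astype(int)
    index = {(int(x), int(y)): k for k, (x, y) in enumerate(pts)}
    start = int(np.argmin(np.hypot(*(skeleton_points - source).T)))
    dist = np.full(len(pts), np.inf)
    dist[start] = 0.0
    heap = [(0.0, start)]
    sqrt2 = np.sqrt(2.0)
    while heap:
        d0, k = heapq.heappop(heap)
        if d0 > dist[k]:
            continue
        x, y = int(pts[k, 0]), int(pts[k, 1])
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                if dx == 0 and dy == 0:
                    continue
                j = index.get((x + dx, y + dy))
                if j is None:
                    continue
                nd = d0 + (sqrt2 if dx and dy else 1.0)
                if nd < dist[j]:
                    dist[j] = nd
                    heapq.heappush(heap, (nd, j))
    return dist


def cavity_area_series(
    layer_list,
) -> tuple[np.ndarray, int, int]:
    """Cavity areas plus ED/ES indices from per-frame endocardial arcs.

    The cavity polygon is the endocardial arc closed with the chord
    between its two base ends. ED is the frame of largest area, ES the
    frame of smallest area; ties break toward the earliest frame.
    """
    areas = np.array([shoelace_area(lc.endo) for lc in layer_list])
    ed = int(np.argmax(areas))
    es = int(np.argmin(areas))
    return areas, ed, es
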