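"""Split the closed boundary into endo/epi arcs and resample each wall.

The closed pixel-corner boundary of the U-band contains four logical
pieces: the endocardial arc, the epicardial arc, and the two base
end-caps where the band terminates at the mitral annulus. The caps are
removed by cutting every boundary vertex that lies beyond an annular
skeleton endpoint along the local outward wall direction; of the two
remaining arcs the endocardial one is the arc closer to the cavity
centroid. Each arc is then split at the apex projection and resampled at
equal arc-length steps to a fixed odd point count (default 193: 96
intervals per wall plus the shared apex sample at index 96).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.morphology import convex_hull_image

from .errors import DegenerateArc, SplitFailure
from .geometry import (
    cumulative_arclength,
    project_point_onto_polyline,
    resample_polyline,
)
from .landmarks import annulus_outward_direction
from .types import ContourFrame, LayerContours


def cavity_centroid(mask: np.ndarray) -> np.ndarray:
    """Centroid (x, y) of the cavity region: convex hull minus foreground."""
    m = np.asarray(mask).astype(bool)
    cav = convex_hull_image(m) & ~m
    if not cav.any():
        raise SplitFailure("mask has no cavity region (convex hull == mask)")
    rows, cols = np.nonzero(cav)
    return np.array([cols.mean() + 0.5, rows.mean() + 0.5])


def split_contour_layers(
    contour: ContourFrame, cap_inset_frac: float = 0.2
) -> tuple[np.ndarray, np.ndarray]:
    """Cut the closed boundary into (endo, epi) arcs, each ordered septal→lateral.

    Skeleton thinning terminates about one half-thickness inside the
    flat band end, so a cut exactly through the annular skeleton
    endpoint would discard that much wall — and the discarded length
    grows as the wall thickens in systole, biasing the strain. The band
    end is instead estimated as the annular endpoint pushed outward by
    its distance-transform value (which also self-corrects when thinning
    places the endpoint off the medial line), and the cut plane sits
    ``cap_inset_frac`` of the local half-thickness inside that end so
    the cap is never empty; expressing the inset as a fraction keeps the
    strain invariant under image rescaling.
    """
    boundary = contour.boundary
    skel = contour.skeleton
    edt = ndimage.distance_transform_edt(contour.mask)
    h, w = contour.mask.shape
    cap = np.zeros(len(boundary), dtype=bool)
    for annulus in (contour.septal_annulus, contour.lateral_annulus):
        # bilinear EDT lookup: a nearest-pixel value would quantize the
        # cut position and jitter the arc ends between frames
        t_half = float(
            ndimage.map_coordinates(
                edt, [[annulus[1]], [annulus[0]]], order=1
            )[0]
        )
        t_half = max(t_half, 1.0)
        d = annulus_outward_direction(annulus, skel, t_half)
        inset = max(cap_inset_frac * t_half, 0.75)
        cut_point = annulus + max(t_half - inset, 0.0) * d
        cap |= (boundary - cut_point) @ d > 0
    if cap.all() or not cap.any():
        raise SplitFailure(
            f"cap removal left {0 if cap.all() else 1} arcs (frame {contour.frame_index})"
        )

    arcs = _contiguous_runs(~cap)
    if len(arcs) < 2:
        raise SplitFailure(
            f"cap removal yielded {len(arcs)} arcs (frame {contour.frame_index})"
        )
    arcs = sorted(arcs, key=len, reverse=True)[:2]
    arcs = [boundary[idx] for idx in arcs]

    cav = cavity_centroid(contour.mask)
    dists = [float(np.hypot(*(arc - cav).T).mean()) for arc in arcs]
    endo, epi = (arcs[0], arcs[1]) if dists[0] < dists[1] else (arcs[1], arcs[0])

    out = []
    for arc in (endo, epi):
        d_sep = np.hypot(*(arc[0] - contour.septal_annulus))
        d_lat = np.hypot(*(arc[0] - contour.lateral_annulus))
        out.append(arc if d_sep <= d_lat else arc[::-1])
    return out[0], out[1]


def _contiguous_runs(keep: np.ndarray) -> list[np.ndarray]:
    """Index runs of True values on a cyclic sequence."""
    n = len(keep)
    if keep.all():
        return [np.arange(n)]
    labels, n_runs = ndimage.label(keep)
    runs = [np.nonzero(labels == k)[0] for k in range(1, n_runs + 1)]
    # merge wrap-around run
    if n_runs >= 2 and keep[0] and keep[-1]:
        runs[0] = np.concatenate([runs[-1], runs[0]])
        runs.pop()
    return runs


def smooth_arc(arc: np.ndarray, window: int = 7) -> np.ndarray:
    """Suppress the pixel staircase of a crack-boundary arc.

    Along a staircase polyline the traversed length overstates the
    geometric length by up to sqrt(2), and unevenly so (it depends on
    the local direction), which would corrupt equal-arc-length
    resampling. The arc is re-sampled at ~1 px spacing and smoothed with
    a moving average; endpoints are preserved.
    """
    arc = np.asarray(arc, dtype=float)
    total = cumulative_arclength(arc)[-1]
    n = max(int(np.ceil(total)), 8)
    fine = resample_polyline(arc, np.linspace(0.0, total, n))
    k = np.ones(window) / window
    pad = window // 2
    padded = np.vstack([fine[0][None].repeat(pad, 0), fine, fine[-1][None].repeat(pad, 0)])
    out = np.column_stack(
        [np.convolve(padded[:, 0], k, mode="valid"), np.convolve(padded[:, 1], k, mode="valid")]
    )
    out[0] = arc[0]
    out[-1] = arc[-1]
    return out


def resample_layer(
    arc: np.ndarray, apex: np.ndarray, n_points: int = 193
) -> np.ndarray:
    """Resample one arc to ``n_points`` with the apex pinned at the middle index.

    The apex is projected to its nearest position on the arc polyline;
    the septal and lateral sub-arcs are then resampled independently at
    equal arc-length steps to ``(n_points + 1) / 2`` points each, sharing
    the apex sample.
    """
    if n_points % 2 != 1 or n_points < 5:
        raise ValueError("n_points must be odd and >= 5")
    arc = np.asarray(arc, dtype=float)
    if len(arc) < 4:
        raise DegenerateArc(f"arc has only {len(arc)} points")
    total = cumulative_arclength(arc)[-1]
    if total <= 0:
        raise DegenerateArc("arc has zero length")
    s_apex, _ = project_point_onto_polyline(apex, arc)
    if not (0.0 < s_apex < total):
        raise DegenerateArc("apex projects onto an arc endpoint")
    per_wall = (n_points + 1) // 2
    s_septal = np.linspace(0.0, s_apex, per_wall)
    s_lateral = np.linspace(s_apex, total, per_wall)
    pts = np.vstack(
        [resample_polyline(arc, s_septal), resample_polyline(arc, s_lateral)[1:]]
    )
    return pts


def build_layer_contours(contour: ContourFrame, n_points: int = 193) -> LayerContours:
    """Full per-frame layer extraction: split, smooth, resample both arcs."""
    endo_arc, epi_arc = split_contour_layers(contour)
    return LayerContours(
        frame_index=contour.frame_index,
        endo=resample_layer(smooth_arc(endo_arc), contour.apex, n_points),
        epi=resample_layer(smooth_arc(epi_arc), contour.apex, n_points),
        apex_index=(n_points - 1) // 2,
    )
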