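"""Registration-consistency ("hopscotch") metric.

Externally tracked points — speckle-tracking output on real data,
analytically advected points on the phantom — are overlaid on the DTW
blocks like pebbles on a hopscotch court. If the registration is
temporally consistent, each point stays in the block with the same
serial number in every frame. The score is the signed mean, over all
points and all frames after the first, of (serial in frame f) minus
(serial in frame 1); a value near zero indicates that the tracking-free
block registration agrees with the tracked points.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .errors import FrameMismatch
from .types import BlockPartition, HopscotchResult


def assign_block_serials(
    points: pd.DataFrame, partitions: list[BlockPartition]
) -> tuple[np.ndarray, np.ndarray]:
    """Block serial number (1-based) of every tracked point in every frame.

    ``points`` is a long-format table with columns
    ``frame, point_id, x, y``. Points on a shared border are assigned to
    the lower serial (blocks are tested in serial order); a point inside
    no block gets the serial of the nearest block and is flagged.
    Returns ``(serials, outside_flags)`` of shape (n_frames, n_points).
    """
    frames = np.sort(points["frame"].unique())
    if len(frames) != len(partitions):
        raise FrameMismatch(
            f"points table has {len(frames)} frames, partitions {len(partitions)}"
        )
    point_ids = np.sort(points["point_id"].unique())
    n_pts = len(point_ids)
    serials = np.zeros((len(partitions), n_pts), dtype=int)
    outside = np.zeros((len(partitions), n_pts), dtype=bool)
    for f, part in enumerate(partitions):
        polys = [Polygon(p) for p in part.block_polygons]
        sub = points[points["frame"] == frames[f]].set_index("point_id")
        for k, pid in enumerate(point_ids):
            pt = Point(float(sub.loc[pid, "x"]), float(sub.loc[pid, "y"]))
            serial = 0
            for s, poly in enumerate(polys, start=1):
                if poly.covers(pt):
                    serial = s
                    break
            if serial == 0:
                dists = [poly.exterior.distance(pt) for poly in polys]
                serial = int(np.argmin(dists)) + 1
                outside[f, k] = True
            serials[f, k] = serial
    return serials, outside


def hopscotch_score(serials: np.ndarray, outside: np.ndarray) -> HopscotchResult:
    """Mean serial-number drift relative to the first frame.

    Outside-flagged assignments are kept in the mean (they still carry a
    nearest-block serial), so the point count stays fixed across frames.
    """
    serials = np.asarray(serials, dtype=int)
    if serials.shape[0] < 2:
        raise FrameMismatch("hopscotch needs >= 2 frames")
    ref = serials[0]
    diff = serials[1:] - ref[None, :]
    return HopscotchResult(
        serials=serials,
        outside_flags=np.asarray(outside, dtype=bool),
        reference=ref,
        mean_difference=float(diff.mean()),
        mean_abs_difference=float(np.abs(diff).mean()),
        per_frame_mean=diff.mean(axis=1),
        max_abs_difference=float(np.abs(diff).max()),
    )


def run_hopscotch(
    points: pd.DataFrame, partitions: list[BlockPartition]
) -> HopscotchResult:
    """Assign serials and score in one call."""
    serials, outside = assign_block_serials(points, partitions)
    return hopscotch_score(serials, outside)
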