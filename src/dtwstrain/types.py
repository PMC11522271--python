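"""Shared data containers for the strain pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MaskSequence:
    """A temporally ordered sequence of binary LV-myocardium masks.

    Parameters
    ----------
    frames
        Boolean array of shape ``(n_frames, H, W)``; any nonzero source
        pixel is foreground.
    spacing
        Isotropic pixel spacing in mm/px (1.0 = report in pixels).
    frame_rate
        Optional acquisition frame rate in Hz; informational only.
    """

    frames: np.ndarray
    spacing: float = 1.0
    frame_rate: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames).astype(bool)
        if self.frames.ndim != 3 or len(self.frames) < 2:
            raise ValueError("MaskSequence needs >= 2 frames of identical shape")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class ContourFrame:
    """Traced boundary and key points of one frame.

    ``boundary`` is a closed polygon of pixel-corner coordinates (x, y);
    the three key points are the septal annular endpoint, the lateral
    annular endpoint and the apex. ``skeleton`` is kept as a diagnostic.
    """

    frame_index: int
    boundary: np.ndarray
    septal_annulus: np.ndarray
    lateral_annulus: np.ndarray
    apex: np.ndarray
    skeleton: np.ndarray
    mask: np.ndarray  # cleaned binary mask (largest component, holes filled)
    cavity_area: float = np.nan  # filled in once the endocardial arc is known


@dataclass
class LayerContours:
    """Endo- and epicardial arcs resampled to a fixed point count.

    Index 0 sits at the septal annulus side, the middle index at the apex
    projection, the last index at the lateral annulus side.
    """

    frame_index: int
    endo: np.ndarray  # (n_points, 2)
    epi: np.ndarray   # (n_points, 2)
    apex_index: int

    @property
    def n_points(self) -> int:
        return len(self.endo)

    def wall(self, layer: str, side: str) -> np.ndarray:
        """One wall of one layer, ordered annulus->apex (septal) or apex->annulus (lateral)."""
        arr = self.endo if layer == "endo" else self.epi
        if side == "septal":
            return arr[: self.apex_index + 1]
        return arr[self.apex_index:]


@dataclass
class DTWAlignment:
    """Optimal monotone alignment between one wall's endo and epi points."""

    path: np.ndarray  # (n_nodes, 2) int pairs (endo index, epi index), wall-local
    cost: float


@dataclass
class WallPartition:
    """Per-wall merged-block bookkeeping (wall-local node indices)."""

    alignment: DTWAlignment
    unit_areas: np.ndarray        # area of each path segment's polygon
    border_nodes: np.ndarray      # indices into path, len = n_blocks + 1
    block_areas: np.ndarray       # len = n_blocks
    cumulative_fractions: np.ndarray  # achieved cumulative area fraction at each border


@dataclass
class BlockPartition:
    """The 60 serial-numbered blocks and 61 transversal borders of one frame.

    Serial numbers run 1..60 from the septal annulus through the apex to
    the lateral annulus. ``borders[k]`` is the k-th transversal as a
    ``(2, 2)`` array ``[[endo_x, endo_y], [epi_x, epi_y]]``.
    """

    frame_index: int
    septal: WallPartition
    lateral: WallPartition
    borders: np.ndarray           # (n_borders, 2, 2)
    block_polygons: list[np.ndarray]
    block_areas: np.ndarray       # (n_blocks,)

    @property
    def n_blocks(self) -> int:
        return len(self.block_areas)

    @property
    def n_borders(self) -> int:
        return len(self.borders)


@dataclass
class StrainCurve:
    """Global strain curve with per-cycle re-zeroing.

    ``strain`` holds the signed Lagrangian strain (l_i - l_0) / l_0 where
    l_0 is the centerline length at the frame's own cycle's end-diastole.
    ``peak_strain`` is the maximal |strain| (magnitude); its sign is kept
    in ``peak_strain_signed``.
    """

    lengths: np.ndarray
    strain: np.ndarray
    ed_frames: np.ndarray
    cycle_id: np.ndarray
    l0_per_cycle: np.ndarray
    peak_strain: float
    peak_strain_signed: float
    peak_per_cycle: np.ndarray


@dataclass
class HopscotchResult:
    """Block-serial assignments of tracked points across frames."""

    serials: np.ndarray        # (n_frames, n_points) int, 1-based
    outside_flags: np.ndarray  # (n_frames, n_points) bool
    reference: np.ndarray      # first-frame serials, (n_points,)
    mean_difference: float     # signed mean over frames 2..N and points
    mean_abs_difference: float
    per_frame_mean: np.ndarray
    max_abs_difference: float


SEGMENT_NAMES = (
    "basal_septal",
    "mid_septal",
    "apical_septal",
    "apical_lateral",
    "mid_lateral",
    "basal_lateral",
)


@dataclass
class RunConfig:
    """Tunable knobs of a full pipeline run."""

    spacing: float = 1.0
    septal_side: str = "left"           # which image side holds the septum
    points_per_layer: int = 193          # odd; 96 intervals per wall + shared apex
    blocks_per_segment: int = 10
    segments_per_wall: int = 3
    cycle_prominence: float = 0.05       # fraction of cavity-area range
    cycle_min_separation_frac: float = 1 / 3  # of the dominant period
    seed: int = 0

    def __post_init__(self) -> None:
        n_min = 2 * self.blocks_per_segment * self.segments_per_wall + 1
        if self.points_per_layer % 2 != 1 or self.points_per_layer < n_min:
            raise ValueError(
                f"points_per_layer must be odd and >= {n_min}, got {self.points_per_layer}"
            )
        if self.septal_side not in ("left", "right"):
            raise ValueError("septal_side must be 'left' or 'right'")

    @property
    def blocks_per_wall(self) -> int:
        return self.blocks_per_segment * self.segments_per_wall

    @property
    def points_per_wall(self) -> int:
        return (self.points_per_layer + 1) // 2
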