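"""Synthetic deforming myocardial phantom with analytic ground truth.

The phantom emulates the apical four-chamber appearance of the LV
myocardium: a U-shaped band whose mid-curve is a half-ellipse running
from the septal base point, over the apex, down to the lateral base
point. Over a cardiac cycle the mid-curve is scaled longitudinally by

    lambda(tau) = 1 - a * sin^2(pi * tau / n_frames)

(frame 0 is end-diastole, mid-cycle is end-systole) while the local wall
thickness is scaled by 1/lambda, so the in-plane band area is conserved —
the same incompressibility assumption the strain method itself relies on.
The ground-truth Lagrangian strain at frame tau is exactly lambda(tau)-1.

Because the deformation is a similarity transform of the mid-curve about
the base midpoint, material points keep their arc-length fraction, which
makes analytically co-moving tracking points trivial to generate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import SelfIntersection
from .geometry import cumulative_arclength, resample_polyline
from .types import MaskSequence

# dense sampling step (px) along the mid-curve used for rasterization
_CURVE_STEP = 0.25


@dataclass
class PhantomSpec:
    """Geometry and deformation parameters of the synthetic phantom.

    All lengths are in pixels and refer to end-diastole. ``base_width``
    is the distance between the two annular wall centers, ``long_axis``
    the base-to-apex length of the mid-curve, ``shortening_amplitude``
    the peak fractional longitudinal shortening ``a`` (so peak strain is
    ``-a``). ``jitter_px`` adds an optional per-frame random translation
    (seeded) to emulate probe motion; it defaults to 0 (noise-free).
    """

    image_size: tuple[int, int] = (256, 256)  # (H, W)
    base_width: float = 110.0
    long_axis: float = 170.0
    thickness_septal: float = 14.0
    thickness_lateral: float = 11.0
    shortening_amplitude: float = 0.2
    n_frames: int = 32
    n_cycles: int = 1
    seed: int = 0
    spacing: float = 1.0
    septal_side: str = "left"
    jitter_px: float = 0.0

    def __post_init__(self) -> None:
        a = self.shortening_amplitude
        if not (0.0 <= a < 0.5):
            raise ValueError(f"shortening_amplitude must be in [0, 0.5), got {a}")
        if self.n_frames < 8:
            raise ValueError("n_frames must be >= 8")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if max(self.thickness_septal, self.thickness_lateral) >= self.long_axis / 3:
            raise ValueError("wall thickness must be < long_axis / 3")

    @property
    def total_frames(self) -> int:
        return self.n_frames * self.n_cycles


@dataclass
class GroundTruth:
    """Analytic truth accompanying a generated phantom sequence."""

    strain_per_frame: np.ndarray          # signed fraction, lambda(tau) - 1
    centerline_points_per_frame: np.ndarray  # (n_frames, n_samples, 2)
    area_per_frame: np.ndarray            # analytic band area, px^2 (constant)
    base_centers_per_frame: np.ndarray    # (n_frames, 2, 2): septal, lateral band ends
    annulus_per_frame: np.ndarray         # (n_frames, 2, 2): half-thickness-inset points
    apex_outer_per_frame: np.ndarray      # (n_frames, 2): epicardial apex
    ed_phase_frames: np.ndarray           # frame indices where lambda == 1


def _lambda_series(spec: PhantomSpec) -> np.ndarray:
    tau = np.arange(spec.total_frames) % spec.n_frames
    return 1.0 - spec.shortening_amplitude * np.sin(np.pi * tau / spec.n_frames) ** 2


def _ed_midcurve(spec: PhantomSpec, n_samples: int) -> np.ndarray:
    """ED mid-curve sampled at equal arc-length steps, septal end first."""
    h, w = spec.image_size
    rx = spec.base_width / 2.0
    ry = spec.long_axis
    cx = w / 2.0
    t_max = max(spec.thickness_septal, spec.thickness_lateral)
    y_base = min(h - 2.0 - t_max, (h + ry) / 2.0)
    # theta from pi (septal, image-left) over pi/2 (apex) to 0 (lateral)
    theta = np.linspace(np.pi, 0.0, 4096)
    pts = np.column_stack([cx + rx * np.cos(theta), y_base - ry * np.sin(theta)])
    if spec.septal_side == "right":
        pts[:, 0] = 2 * cx - pts[:, 0]
    total = cumulative_arclength(pts)[-1]
    return resample_polyline(pts, np.linspace(0.0, total, n_samples))


def _check_self_intersection(spec: PhantomSpec) -> None:
    # apex curvature radius of the half-ellipse is rx^2 / ry; under a
    # similarity scale by lambda it scales with lambda, while half
    # thickness grows as t / (2 lambda); band stays simple iff
    # t / (2 lambda) < lambda * rx^2 / ry at peak contraction.
    lam_min = 1.0 - spec.shortening_amplitude
    r_apex = (spec.base_width / 2.0) ** 2 / spec.long_axis
    t_half = max(spec.thickness_septal, spec.thickness_lateral) / (2.0 * lam_min)
    if t_half >= lam_min * r_apex:
        raise SelfIntersection(
            f"half thickness {t_half:.1f}px exceeds apex curvature radius "
            f"{lam_min * r_apex:.1f}px at peak contraction"
        )


def generate_phantom_sequence(spec: PhantomSpec) -> tuple[MaskSequence, GroundTruth]:
    """Rasterize the deforming band and return masks plus analytic truth.

    A pixel is foreground iff its center lies within the band: its
    nearest mid-curve point is interior (flat band ends at the base) and
    its distance is at most the local half-thickness. Thickness varies
    linearly in arc-length fraction from the septal to the lateral value.
    """
    _check_self_intersection(spec)
    h, w = spec.image_size
    lam = _lambda_series(spec)
    rng = np.random.default_rng(spec.seed)

    n_dense = max(512, int(np.ceil(spec.long_axis * 3 / _CURVE_STEP)))
    mid_ed = _ed_midcurve(spec, n_dense)
    total_len = cumulative_arclength(mid_ed)[-1]
    frac = np.linspace(0.0, 1.0, n_dense)
    t_ed = spec.thickness_septal + (spec.thickness_lateral - spec.thickness_septal) * frac
    if spec.septal_side == "right":
        t_ed = t_ed[::-1].copy()
    center = 0.5 * (mid_ed[0] + mid_ed[-1])  # base midpoint, scaling anchor

    yy, xx = np.mgrid[0:h, 0:w]
    pixel_centers = np.column_stack([xx.ravel() + 0.5, yy.ravel() + 0.5])

    frames = np.zeros((spec.total_frames, h, w), dtype=bool)
    centerlines = np.zeros((spec.total_frames, 201, 2))
    base_centers = np.zeros((spec.total_frames, 2, 2))
    annuli = np.zeros((spec.total_frames, 2, 2))
    apex_outer = np.zeros((spec.total_frames, 2))

    apex_idx = int(np.argmin(mid_ed[:, 1]))
    for f, lam_f in enumerate(lam):
        mid = center + lam_f * (mid_ed - center)
        if spec.jitter_px > 0:
            mid = mid + rng.normal(0.0, spec.jitter_px, size=2)
        half_t = t_ed / (2.0 * lam_f)
        tree = cKDTree(mid)
        dist, idx = tree.query(pixel_centers, workers=-1)
        inside = (dist <= half_t[idx]) & (idx > 0) & (idx < n_dense - 1)
        frames[f] = inside.reshape(h, w)

        centerlines[f] = resample_polyline(mid, np.linspace(0, lam_f * total_len, 201))
        base_centers[f, 0] = mid[0]
        base_centers[f, 1] = mid[-1]
        # skeleton thinning of a flat-ended band terminates about one
        # half-thickness inside the end; emit that point as the expected
        # annulus location.
        s_inset_s = half_t[0]
        s_inset_l = half_t[-1]
        annuli[f, 0] = resample_polyline(mid, [s_inset_s])[0]
        annuli[f, 1] = resample_polyline(mid, [lam_f * total_len - s_inset_l])[0]
        apex_mid = mid[apex_idx]
        apex_outer[f] = apex_mid - np.array([0.0, half_t[apex_idx]])

    area = float(np.trapezoid(t_ed, np.linspace(0, total_len, n_dense)))
    truth = GroundTruth(
        strain_per_frame=lam - 1.0,
        centerline_points_per_frame=centerlines,
        area_per_frame=np.full(spec.total_frames, area),
        base_centers_per_frame=base_centers,
        annulus_per_frame=annuli,
        apex_outer_per_frame=apex_outer,
        ed_phase_frames=np.arange(0, spec.total_frames, spec.n_frames),
    )
    return MaskSequence(frames=frames, spacing=spec.spacing), truth


def generate_comoving_points(
    spec: PhantomSpec, n_points: int = 50, layer: str = "mid"
) -> pd.DataFrame:
    """Analytically advected tracking points on the mid-curve.

    Points sit at equal arc-length fractions of the ED mid-curve
    (endpoints included) and keep their fraction under the deformation —
    the role speckle tracking plays on real data. Returns a long-format
    table with columns ``frame, point_id, x, y``.
    """
    if layer != "mid":
        raise ValueError("only the mid-myocardial layer is supported")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    _check_self_intersection(spec)
    lam = _lambda_series(spec)
    mid_ed = _ed_midcurve(spec, 4096)
    total_len = cumulative_arclength(mid_ed)[-1]
    center = 0.5 * (mid_ed[0] + mid_ed[-1])
    fractions = np.linspace(0.0, 1.0, n_points)
    pts_ed = resample_polyline(mid_ed, fractions * total_len)

    rows = []
    for f, lam_f in enumerate(lam):
        pts = center + lam_f * (pts_ed - center)
        rows.append(
            pd.DataFrame(
                {
                    "frame": f,
                    "point_id": np.arange(n_points),
                    "x": pts[:, 0],
                    "y": pts[:, 1],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
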