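"""End-to-end orchestration: masks in, strain curves out.

Stages, per the method's design:

1. per frame: clean mask, trace boundary, find annular endpoints and apex;
2. per frame: split endo/epi arcs, resample to 193 points each;
3. cavity-area series -> cycle (ED) detection;
4. per-wall DTW + unit construction; block targets at the global ED
   (frame of largest cavity area), proportional-area partition of every
   frame into 60 serial-numbered blocks;
5. centerline lengths -> global and segmental Lagrangian strain, with
   per-cycle re-zeroing for multi-beat input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import landmarks, registration, resample, strain
from .types import (
    BlockPartition,
    ContourFrame,
    LayerContours,
    MaskSequence,
    RunConfig,
    StrainCurve,
)


@dataclass
class StrainResult:
    """Everything a full run computes, from contours to segment curves."""

    config: RunConfig
    spacing: float
    contours: list[ContourFrame]
    layers: list[LayerContours]
    partitions: list[BlockPartition]
    cavity_areas: np.ndarray
    ed_frame: int            # global ED (largest cavity area)
    es_frame: int
    lengths: np.ndarray      # centerline length per frame (mm if spacing set)
    centerlines: list[np.ndarray]
    global_curve: StrainCurve
    segment_curves: dict[str, StrainCurve]


def extract_contours(masks: MaskSequence, config: RunConfig) -> list[ContourFrame]:
    """Stage 1: boundary + key points for every frame."""
    contours = []
    for k, frame in enumerate(masks.frames):
        cleaned = landmarks.clean_mask(frame, frame_index=k)
        boundary = landmarks.trace_boundary(cleaned, frame_index=k)
        septal, lateral, skel = landmarks.find_annular_endpoints(
            cleaned, septal_side=config.septal_side, frame_index=k
        )
        apex = landmarks.find_apex(boundary, septal, lateral, frame_index=k)
        contours.append(
            ContourFrame(
                frame_index=k,
                boundary=boundary,
                septal_annulus=septal,
                lateral_annulus=lateral,
                apex=apex,
                skeleton=skel,
                mask=cleaned,
            )
        )
    return contours


def analyze(masks: MaskSequence, config: RunConfig | None = None) -> StrainResult:
    """Run the full tracking-free strain pipeline on a mask sequence."""
    config = config or RunConfig()
    contours = extract_contours(masks, config)
    layers = [
        resample.build_layer_contours(cf, config.points_per_layer) for cf in contours
    ]
    cavity_areas, ed_frame, es_frame = landmarks.cavity_area_series(layers)
    for cf, area in zip(contours, cavity_areas):
        cf.cavity_area = float(area)

    targets_sep, targets_lat = registration.define_frame_targets(
        layers[ed_frame], config.blocks_per_wall
    )
    partitions = [
        registration.partition_frame(lc, targets_sep, targets_lat) for lc in layers
    ]

    centerlines = []
    lengths = np.zeros(len(layers))
    for k, part in enumerate(partitions):
        mids, length = strain.build_centerline(part)
        centerlines.append(mids)
        lengths[k] = length * masks.spacing

    ed_frames = strain.detect_cycles(
        cavity_areas,
        prominence_frac=config.cycle_prominence,
        min_separation_frac=config.cycle_min_separation_frac,
    )
    global_curve = strain.compute_strain_curve(lengths, ed_frames)
    segment_curves = strain.regional_strain(
        partitions,
        ed_frames,
        config.blocks_per_segment,
        targets_septal=targets_sep,
        targets_lateral=targets_lat,
    )
    return StrainResult(
        config=config,
        spacing=masks.spacing,
        contours=contours,
        layers=layers,
        partitions=partitions,
        cavity_areas=cavity_areas,
        ed_frame=int(ed_frame),
        es_frame=int(es_frame),
        lengths=lengths,
        centerlines=centerlines,
        global_curve=global_curve,
        segment_curves=segment_curves,
    )
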