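"""Reading mask sequences and tracking tables; writing curves and summaries.

Masks come in as a directory of single-frame raster images (PNG/TIFF,
natural-sorted by filename) or as one multi-page TIFF; any nonzero pixel
is foreground. Results go out as a per-frame CSV (``strain.csv``) and a
summary JSON, with a versioned schema so downstream consumers can detect
format changes.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import EmptyInput, ShapeMismatch
from .types import SEGMENT_NAMES, MaskSequence

SCHEMA_VERSION = 1

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".bmp")


def _natural_key(name: str):
    return [int(t) if t.isdigit() else t.lower() for t in re.split(r"(\d+)", name)]


def _to_binary(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 3:  # RGB(A): any nonzero channel
        frame = frame.max(axis=-1)
    return frame != 0


def read_mask_sequence(
    path: str | Path, spacing: float = 1.0, frame_rate: float | None = None
) -> MaskSequence:
    """Load an ordered binary mask sequence from a directory or multi-page TIFF."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES),
            key=lambda p: _natural_key(p.name),
        )
        if not files:
            raise EmptyInput(f"no mask images found in {path}")
        frames = []
        shape = None
        for p in files:
            img = _to_binary(iio.imread(p))
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise ShapeMismatch(
                    f"{p.name} has shape {img.shape}, expected {shape}"
                )
            frames.append(img)
        stack = np.stack(frames)
    elif path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            raise EmptyInput(f"{path} holds a single frame; need a sequence")
        stack = np.stack([_to_binary(f) for f in arr])
    else:
        raise EmptyInput(f"unsupported input {path}")
    return MaskSequence(frames=stack, spacing=spacing, frame_rate=frame_rate)


def write_mask_sequence(masks: MaskSequence, outdir: str | Path) -> list[Path]:
    """Write frames as frame_0000.png, ... (0/255 uint8)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, frame in enumerate(masks.frames):
        p = outdir / f"frame_{k:04d}.png"
        iio.imwrite(p, (frame.astype(np.uint8) * 255))
        paths.append(p)
    return paths


def read_points_table(path: str | Path) -> pd.DataFrame:
    """Tracking-point table with columns frame, point_id, x, y."""
    df = pd.read_csv(path)
    required = {"frame", "point_id", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise EmptyInput(f"points table {path} lacks columns {sorted(missing)}")
    return df


def write_outputs(result, outdir: str | Path) -> dict[str, Path]:
    """Write strain.csv and summary.json for a pipeline result."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = len(result.lengths)
    table = {
        "frame": np.arange(n),
        "cavity_area": result.cavity_areas,
        "centerline_length": result.lengths,
        "strain_global": result.global_curve.strain,
    }
    for name in result.segment_curves:
        table[f"strain_{name}"] = result.segment_curves[name].strain
    table["cycle_id"] = result.global_curve.cycle_id
    table["is_ed"] = np.isin(np.arange(n), result.global_curve.ed_frames)
    csv_path = outdir / "strain.csv"
    pd.DataFrame(table).to_csv(csv_path, index=False, float_format="%.10g")

    gc = result.global_curve
    summary = {
        "schema_version": SCHEMA_VERSION,
        "spacing_mm_per_px": result.spacing,
        "n_frames": n,
        "ed_frames": gc.ed_frames.tolist(),
        "es_frame": int(result.es_frame),
        "peak_strain": gc.peak_strain,
        "peak_strain_signed": gc.peak_strain_signed,
        "peak_strain_per_cycle": gc.peak_per_cycle.tolist(),
        "peak_strain_per_segment": {
            name: curve.peak_strain for name, curve in result.segment_curves.items()
        },
    }
    json_path = outdir / "summary.json"
    json_path.write_text(json.dumps(summary, indent=2) + "\n")
    return {"strain_csv": csv_path, "summary_json": json_path}


def write_diagnostics(result, outdir: str | Path) -> dict[str, Path]:
    """Key points / cavity areas per frame, and the 61 border transversals."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for cf, area in zip(result.contours, result.cavity_areas):
        rows.append(
            dict(
                frame=cf.frame_index,
                sx=cf.septal_annulus[0], sy=cf.septal_annulus[1],
                lx=cf.lateral_annulus[0], ly=cf.lateral_annulus[1],
                ax=cf.apex[0], ay=cf.apex[1],
                cavity_area=area,
            )
        )
    kp_path = outdir / "keypoints.csv"
    pd.DataFrame(rows).to_csv(kp_path, index=False, float_format="%.6g")

    rows = []
    for part in result.partitions:
        for b, border in enumerate(part.borders):
            rows.append(
                dict(
                    frame=part.frame_index, border_id=b,
                    endo_x=border[0, 0], endo_y=border[0, 1],
                    epi_x=border[1, 0], epi_y=border[1, 1],
                )
            )
    border_path = outdir / "borders.csv"
    pd.DataFrame(rows).to_csv(border_path, index=False, float_format="%.6g")
    return {"keypoints_csv": kp_path, "borders_csv": border_path}
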