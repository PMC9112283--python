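"""Per-ROI trace extraction and erosion-baseline ΔF/F0.

The baseline F0 is computed per timepoint as a one-dimensional grayscale
erosion (sliding minimum) of the raw trace, so F0 <= F everywhere and
ΔF/F0 = (F − F0)/F0 is nonnegative.  The erosion window defaults to 41
frames (~2 min at the 3 s volumetric frame interval), longer than the
longest spontaneous event, so events do not erode into the baseline.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging_io import PlaneSeries
from .model import Roi, Trace

__all__ = [
    "DEFAULT_EROSION_WINDOW",
    "extract_raw_trace",
    "erode_baseline",
    "compute_dff",
    "trace_from_plane",
    "trace_from_raw",
    "read_rois",
    "write_rois",
    "traces_to_frame",
]

DEFAULT_EROSION_WINDOW = 41


def _disk_mask(
    shape: tuple[int, int], x_px: float, y_px: float, radius_px: float
) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - y_px) ** 2 + (xx - x_px) ** 2 <= radius_px**2


def extract_raw_trace(plane: PlaneSeries, roi: Roi) -> np.ndarray:
    """Mean intensity per frame over the ROI disk.

    Membership uses pixel centers within the radius (inclusive).  The
    disk must lie fully inside the image.
    """
    radius_px = (roi.diameter_um / 2.0) / plane.pixel_spacing_um
    ny, nx = plane.data.shape[1:]
    if (
        roi.x_px - radius_px < -0.5
        or roi.y_px - radius_px < -0.5
        or roi.x_px + radius_px > nx - 0.5
        or roi.y_px + radius_px > ny - 0.5
    ):
        raise ValueError(
            f"ROI {roi.cell_id}:{roi.compartment} (center "
            f"({roi.x_px:.1f}, {roi.y_px:.1f}), radius {radius_px:.1f} px) "
            f"extends outside the {ny}x{nx} image"
        )
    mask = _disk_mask((ny, nx), roi.x_px, roi.y_px, radius_px)
    if not mask.any():
        # radius smaller than half a pixel: fall back to the nearest pixel
        mask = np.zeros((ny, nx), dtype=bool)
        mask[int(round(roi.y_px)), int(round(roi.x_px))] = True
    return plane.data[:, mask].mean(axis=1)


def erode_baseline(F: np.ndarray, window_frames: int) -> np.ndarray:
    """Grayscale erosion (centered sliding minimum) of a raw trace.

    ``window_frames`` must be odd; borders are handled by replication.
    """
    if window_frames <= 0 or window_frames % 2 == 0:
        raise ValueError(
            f"erosion window must be a positive odd frame count, got "
            f"{window_frames}"
        )
    F = np.asarray(F, dtype=float)
    if window_frames > len(F):
        raise ValueError(
            f"erosion window {window_frames} exceeds trace length {len(F)}"
        )
    return ndimage.grey_erosion(F, size=window_frames, mode="nearest")


def compute_dff(F: np.ndarray, F0: np.ndarray) -> np.ndarray:
    """ΔF/F0 per frame; requires a strictly positive baseline."""
    F = np.asarray(F, dtype=float)
    F0 = np.asarray(F0, dtype=float)
    bad = np.flatnonzero(F0 <= 0)
    if bad.size:
        raise ValueError(
            f"baseline is non-positive at frame {bad[0]}; cannot divide"
        )
    return (F - F0) / F0


def trace_from_raw(
    F: np.ndarray,
    frame_interval_s: float,
    window_frames: int = DEFAULT_EROSION_WINDOW,
    roi: Roi | None = None,
) -> Trace:
    F0 = erode_baseline(F, window_frames)
    return Trace(roi, np.asarray(F, float), F0, compute_dff(F, F0),
                 frame_interval_s)


def trace_from_plane(
    plane: PlaneSeries,
    roi: Roi,
    window_frames: int = DEFAULT_EROSION_WINDOW,
) -> Trace:
    """Extract, baseline and normalize one ROI from a projected plane."""
    F = extract_raw_trace(plane, roi)
    return trace_from_raw(F, plane.frame_interval_s, window_frames, roi)


# --------------------------------------------------------------------------
# ROI table I/O
# --------------------------------------------------------------------------

_ROI_COLUMNS = [
    "neuromast_id",
    "cell_id",
    "cell_type",
    "compartment",
    "x_px",
    "y_px",
    "diameter_um",
]


def write_rois(rois: Sequence[Roi], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [[getattr(r, c) for c in _ROI_COLUMNS] for r in rois],
        columns=_ROI_COLUMNS,
    ).to_csv(path, index=False, float_format="%.9g")
    return path


def read_rois(path: str | Path) -> list[Roi]:
    df = pd.read_csv(path)
    missing = [c for c in _ROI_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ROI table lacks columns: {', '.join(missing)}")
    return [
        Roi(
            str(row.neuromast_id),
            str(row.cell_id),
            str(row.cell_type),
            str(row.compartment),
            float(row.x_px),
            float(row.y_px),
            float(row.diameter_um),
        )
        for row in df.itertuples()
    ]


def traces_to_frame(traces: Iterable[Trace]) -> pd.DataFrame:
    """Tidy trace table: one row per ROI per frame."""
    rows = []
    for tr in traces:
        n = len(tr.F)
        roi = tr.roi
        rows.append(
            pd.DataFrame(
                {
                    "neuromast_id": roi.neuromast_id if roi else "",
                    "cell_id": roi.cell_id if roi else "",
                    "compartment": roi.compartment if roi else "",
                    "frame": np.arange(n),
                    "time_s": tr.time_s,
                    "F": tr.F,
                    "F0": tr.F0,
                    "dff": tr.dff,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
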