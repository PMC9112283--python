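"""Volumetric time-series I/O and pre-processing.

Covers the standard pre-analysis steps applied to fast-acquisition 3D
time series before trace extraction: rigid 3D drift correction against a
reference frame, conversion to 2D time series by sub-volume maximum
intensity projection, and residual 2D translation registration.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.registration import phase_cross_correlation

__all__ = [
    "VolumeSeries",
    "PlaneSeries",
    "read_volume_series",
    "write_volume_series",
    "correct_drift_3d",
    "max_project",
    "register_translation_2d",
]


@dataclass
class VolumeSeries:
    """A T,Z,Y,X intensity stack with acquisition metadata."""

    data: np.ndarray
    frame_interval_s: float
    voxel_spacing_um: tuple[float, float, float]  # (z, y, x)
    channel: str = "GCaMP6s"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"VolumeSeries data must be T,Z,Y,X; got shape {self.data.shape}"
            )
        if self.data.shape[0] < 1:
            raise ValueError("need at least one time point")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if any(s <= 0 for s in self.voxel_spacing_um):
            raise ValueError("voxel spacings must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]


@dataclass
class PlaneSeries:
    """A T,Y,X series, typically a sub-volume maximum projection."""

    data: np.ndarray
    frame_interval_s: float
    pixel_spacing_um: float
    z_range: tuple[int, int] = (0, 1)  # half-open slice range projected
    channel: str = "GCaMP6s"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"PlaneSeries data must be T,Y,X; got shape {self.data.shape}"
            )
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.pixel_spacing_um <= 0:
            raise ValueError("pixel_spacing_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


# --------------------------------------------------------------------------
# I/O: TIFF + JSON sidecar
# --------------------------------------------------------------------------

_SIDECAR_FIELDS = ("frame_interval_s", "voxel_spacing_um", "channels")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume_series(
    series: VolumeSeries | list[VolumeSeries], path: str | Path
) -> Path:
    """Write one channel (T,Z,Y,X) or a channel list (T,C,Z,Y,X) as TIFF.

    Metadata goes to a JSON sidecar next to the TIFF.  Float data is
    stored as float32; integer data as uint16.
    """
    path = Path(path)
    channels = [series] if isinstance(series, VolumeSeries) else list(series)
    first = channels[0]
    for ch in channels[1:]:
        if ch.data.shape != first.data.shape:
            raise ValueError("all channels must share one shape")
    stack = np.stack([ch.data for ch in channels], axis=1)  # T,C,Z,Y,X
    if len(channels) == 1:
        stack = stack[:, 0]
    if np.issubdtype(stack.dtype, np.integer):
        stack = stack.astype(np.uint16)
    else:
        stack = stack.astype(np.float32)
    tifffile.imwrite(path, stack)
    sidecar = {
        "frame_interval_s": first.frame_interval_s,
        "voxel_spacing_um": list(first.voxel_spacing_um),
        "channels": [ch.channel for ch in channels],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_volume_series(
    path: str | Path, channel: Optional[str] = None
) -> VolumeSeries | list[VolumeSeries]:
    """Read a TIFF written by :func:`write_volume_series`.

    Single-channel files return a :class:`VolumeSeries`; two-color
    (T,C,Z,Y,X) files return one series per channel unless ``channel``
    selects one by name.
    """
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(
            f"missing metadata sidecar {side.name}; required fields: "
            f"{', '.join(_SIDECAR_FIELDS)}"
        )
    meta = json.loads(side.read_text())
    missing = [f for f in _SIDECAR_FIELDS if f not in meta]
    if missing:
        raise ValueError(
            f"metadata sidecar {side.name} lacks required fields: "
            f"{', '.join(missing)}"
        )
    data = tifffile.imread(path)
    names = meta["channels"]
    spacing = tuple(meta["voxel_spacing_um"])
    dt = float(meta["frame_interval_s"])
    if data.ndim == 4:
        if len(names) != 1:
            raise ValueError("4D data but sidecar lists multiple channels")
        arrays = [data]
    elif data.ndim == 5:
        if data.shape[1] != len(names):
            raise ValueError(
                f"channel axis {data.shape[1]} does not match sidecar "
                f"channel list {names}"
            )
        arrays = [data[:, i] for i in range(data.shape[1])]
    else:
        raise ValueError(f"expected 4D or 5D TIFF, got shape {data.shape}")
    out = [
        VolumeSeries(arr.astype(float), dt, spacing, name)
        for arr, name in zip(arrays, names)
    ]
    if channel is not None:
        for s in out:
            if s.channel == channel:
                return s
        raise ValueError(f"channel {channel!r} not in {names}")
    return out[0] if len(out) == 1 else out


# --------------------------------------------------------------------------
# drift correction and registration
# --------------------------------------------------------------------------

def _estimate_and_apply_shifts(
    frames: np.ndarray,
    reference: str,
    upsample_factor: int,
    max_shift_px: float,
    ndim_labels: tuple[str, ...],
) -> tuple[np.ndarray, pd.DataFrame, bool]:
    T = frames.shape[0]
    corrected = np.empty_like(frames, dtype=float)
    corrected[0] = frames[0]
    shifts = np.zeros((T, frames.ndim - 1))
    ref_img = frames[0].astype(float)
    degenerate_warned = False
    for ti in range(1, T):
        moving = frames[ti].astype(float)
        if moving.std() == 0 or ref_img.std() == 0:
            if not degenerate_warned:
                warnings.warn(
                    "constant frame encountered; assuming zero shift",
                    stacklevel=3,
                )
                degenerate_warned = True
            shift = np.zeros(frames.ndim - 1)
        else:
            shift, _err, _phase = phase_cross_correlation(
                ref_img, moving, upsample_factor=upsample_factor,
                normalization=None,
            )
        shifts[ti] = shift
        fill = float(np.median(moving))
        corrected[ti] = ndimage.shift(
            moving, shift, order=1, mode="constant", cval=fill
        )
        if reference == "running":
            ref_img = corrected[ti]
    discard = bool(np.any(np.abs(shifts) > max_shift_px))
    table = pd.DataFrame(shifts, columns=[f"d{ax}" for ax in ndim_labels])
    table.insert(0, "frame", np.arange(T))
    table["discard_flag"] = discard
    return corrected, table, discard


def correct_drift_3d(
    series: VolumeSeries,
    max_drift_px: float = 10.0,
    reference: str = "first",
    upsample_factor: int = 10,
) -> tuple[VolumeSeries, pd.DataFrame, bool]:
    """Rigid 3D drift correction by per-frame phase cross-correlation.

    Each volume is registered against the reference (first frame by
    default, or the running corrected previous frame), shifted with
    linear interpolation and edge fill equal to the frame's median
    background.  The discard flag is raised when any per-frame shift
    magnitude exceeds ``max_drift_px`` — recordings with excessive X-Y or
    Z drift are excluded from analysis rather than trusted.
    """
    if series.n_frames < 2:
        raise ValueError("drift correction needs at least 2 frames")
    if reference not in ("first", "running"):
        raise ValueError("reference must be 'first' or 'running'")
    corrected, table, discard = _estimate_and_apply_shifts(
        series.data, reference, upsample_factor, max_drift_px, ("z", "y", "x")
    )
    out = replace(series, data=corrected)
    return out, table, discard


def max_project(
    series: VolumeSeries, partition_um: float | str = "all"
) -> list[PlaneSeries]:
    """Sub-volume maximum intensity projections along z.

    ``partition_um`` tiles the stack apically from z = 0 into sub-volumes
    of that thickness (the final partial sub-volume is kept); ``"all"``
    projects the whole stack.  Typical partitions: 6 µm for hair-cell
    channels, 4 µm for supporting cells, the entire volume for efferent
    terminals.
    """
    z_spacing = series.voxel_spacing_um[0]
    nz = series.n_slices
    if partition_um == "all":
        step = nz
    else:
        partition_um = float(partition_um)
        if partition_um <= 0:
            raise ValueError("partition_um must be positive or 'all'")
        if partition_um > nz * z_spacing:
            raise ValueError(
                f"partition {partition_um} um exceeds stack depth "
                f"{nz * z_spacing} um"
            )
        step = max(1, int(round(partition_um / z_spacing)))
    out = []
    for z0 in range(0, nz, step):
        z1 = min(z0 + step, nz)
        out.append(
            PlaneSeries(
                data=series.data[:, z0:z1].max(axis=1),
                frame_interval_s=series.frame_interval_s,
                pixel_spacing_um=series.voxel_spacing_um[2],
                z_range=(z0, z1),
                channel=series.channel,
            )
        )
    return out


def register_translation_2d(
    plane: PlaneSeries,
    max_shift_px: float = 10.0,
    upsample_factor: int = 10,
    reference: str = "first",
) -> tuple[PlaneSeries, pd.DataFrame, bool]:
    """Residual sub-pixel 2D translation correction after projection."""
    if plane.n_frames < 2:
        raise ValueError("registration needs at least 2 frames")
    corrected, table, discard = _estimate_and_apply_shifts(
        plane.data, reference, upsample_factor, max_shift_px, ("y", "x")
    )
    out = replace(plane, data=corrected)
    return out, table, discard
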