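"""Spatial views of spontaneous activity and profile width estimation.

Pixelwise mean-ΔF/F0 activity maps (the per-trace erosion baseline and
normalization applied at every pixel), signed ΔF snapshot sequences
against a pre-event reference frame, apex-to-base onset-latency
estimation for intracellular calcium waves, and a generic
full-width-at-half-maximum estimator for bead/PSF profiles.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .imaging_io import PlaneSeries
from .model import DFF_THRESHOLD
from .traces import DEFAULT_EROSION_WINDOW

__all__ = [
    "ActivityMap",
    "mean_dff_map",
    "delta_f_series",
    "onset_latency",
    "fwhm_profile",
    "save_activity_map",
]


@dataclass
class ActivityMap:
    """Mean ΔF/F0 per pixel over an interval, with a reference image."""

    mean_dff: np.ndarray
    reference: np.ndarray
    interval_s: float
    n_masked_pixels: int = 0

    def __post_init__(self) -> None:
        if self.mean_dff.shape != self.reference.shape:
            raise ValueError("map and reference shapes must match")


def mean_dff_map(
    plane: PlaneSeries,
    window_frames: int = DEFAULT_EROSION_WINDOW,
    theta: Optional[float] = None,
) -> ActivityMap:
    """Pixel-by-pixel mean ΔF/F0 over the recording.

    Every pixel gets the same treatment as an ROI trace: an erosion
    (sliding-minimum) baseline over ``window_frames`` and ΔF/F0 against
    it, then a temporal mean.  With ``theta`` set, the mean is the
    thresholded mean (sum of ΔF/F0 > θ over total frames), matching the
    per-trace average-magnitude statistic.  Pixels whose baseline
    touches zero are masked to 0 and counted.
    """
    if window_frames <= 0 or window_frames % 2 == 0:
        raise ValueError("window_frames must be a positive odd count")
    data = plane.data.astype(float)
    f0 = ndimage.grey_erosion(data, size=(window_frames, 1, 1), mode="nearest")
    valid = (f0 > 0).all(axis=0)
    n_masked = int((~valid).sum())
    dff = np.zeros_like(data)
    np.divide(data - f0, f0, out=dff, where=f0 > 0)
    if theta is None:
        mean = dff.mean(axis=0)
    else:
        mean = np.where(dff > theta, dff, 0.0).sum(axis=0) / data.shape[0]
    mean = np.where(valid, mean, 0.0)
    reference = np.median(data, axis=0)
    return ActivityMap(
        mean_dff=mean,
        reference=reference,
        interval_s=plane.n_frames * plane.frame_interval_s,
        n_masked_pixels=n_masked,
    )


def delta_f_series(plane: PlaneSeries, reference_frame: int) -> np.ndarray:
    """Signed ΔF image sequence against a chosen reference frame.

    The reference is typically the frame just prior to the rise of the
    event of interest; output keeps sign so decreases stay visible.
    """
    if not 0 <= reference_frame < plane.n_frames:
        raise ValueError(
            f"reference frame {reference_frame} outside 0..{plane.n_frames - 1}"
        )
    data = plane.data.astype(float)
    return data - data[reference_frame]


def _onset_time(
    dff: np.ndarray, onset_fraction: float, frame_interval_s: float
) -> float:
    """First upward crossing of onset_fraction x peak, interpolated."""
    dff = np.asarray(dff, dtype=float)
    peak = float(dff.max())
    if peak <= 0:
        raise ValueError("trace contains no event (non-positive peak)")
    level = onset_fraction * peak
    above = dff >= level
    idx = int(np.argmax(above))
    if idx == 0:
        return 0.0
    lo, hi = dff[idx - 1], dff[idx]
    frac = (level - lo) / (hi - lo) if hi != lo else 0.0
    return (idx - 1 + frac) * frame_interval_s


def onset_latency(
    dff_top: np.ndarray,
    dff_bottom: np.ndarray,
    frame_interval_s: float,
    onset_fraction: float = 0.2,
) -> float:
    """Apex-to-base onset latency in seconds (positive = top leads).

    Each trace's onset is the first frame crossing ``onset_fraction`` of
    that trace's own peak, linearly interpolated between frames; the
    latency is onset(bottom) − onset(top).  Antisymmetric by
    construction.
    """
    if not 0 < onset_fraction < 1:
        raise ValueError("onset_fraction must be in (0, 1)")
    t_top = _onset_time(dff_top, onset_fraction, frame_interval_s)
    t_bot = _onset_time(dff_bottom, onset_fraction, frame_interval_s)
    return t_bot - t_top


def fwhm_profile(profile: np.ndarray, spacing_um: float) -> float:
    """Full width at half maximum of a unimodal intensity profile.

    Background (the profile minimum) is subtracted, the half-maximum
    crossings on either side of the peak are located by linear
    interpolation, and the width is their separation times the sample
    spacing.  Raises if either side never drops to half maximum.
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1 or len(p) < 3:
        raise ValueError("profile must be a 1-D array of length >= 3")
    if spacing_um <= 0:
        raise ValueError("spacing must be positive")
    bg = float(p.min())
    peak_idx = int(np.argmax(p))
    peak = float(p[peak_idx])
    if peak <= bg:
        raise ValueError("profile has no positive peak above background")
    half = bg + 0.5 * (peak - bg)

    def cross(side: np.ndarray, reversed_: bool) -> float:
        # distance (in samples) from the peak to the half-max crossing
        below = np.flatnonzero(side < half)
        if below.size == 0:
            raise ValueError(
                "no half-maximum crossing on the "
                + ("left" if reversed_ else "right")
                + " side"
            )
        i = below[0]  # first sample below half, moving away from the peak
        hi, lo = side[i - 1] if i > 0 else peak, side[i]
        frac = (hi - half) / (hi - lo) if hi != lo else 0.0
        return (i - 1) + frac

    right = cross(p[peak_idx + 1 :], reversed_=False) + 1.0
    left = cross(p[peak_idx - 1 :: -1], reversed_=True) + 1.0
    return float((left + right) * spacing_um)


def save_activity_map(
    amap: ActivityMap,
    out_tiff,
    out_png=None,
    overlay_alpha: float = 0.6,
) -> None:
    """Save the map as float TIFF, optionally with a PNG overlay.

    The overlay colorizes mean ΔF/F0 from 0 to its maximum on top of the
    grayscale reference (temporal median) image — a presentation choice,
    not an analysis step.
    """
    import tifffile

    tifffile.imwrite(out_tiff, amap.mean_dff.astype(np.float32))
    if out_png is None:
        return
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.imshow(amap.reference, cmap="gray")
    vmax = amap.mean_dff.max() or 1.0
    im = ax.imshow(
        amap.mean_dff, cmap="inferno", alpha=overlay_alpha, vmin=0.0, vmax=vmax
    )
    fig.colorbar(im, ax=ax, label="mean dF/F0")
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(out_png, dpi=150)
    plt.close(fig)
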