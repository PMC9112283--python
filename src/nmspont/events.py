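"""Spontaneous-event detection and summary statistics.

Signals must exceed θ = 0.10 ΔF/F0 (strictly) to count as true indicator
signal; everything below is treated as noise.  Three per-ROI statistics
follow the standard quantification:

average magnitude
    Sum of ΔF/F0 over the frames where ΔF/F0 > θ, divided by the *total*
    frame count of the recording.
frequency
    Detected peak count divided by the recording duration.
duration
    Contiguous time above θ around each detected peak (threshold-crossing
    width, counted in whole frames); merged events are split at the
    troughs between their peaks.

Per-neuromast values are the means of the per-ROI values.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .model import DFF_THRESHOLD

__all__ = [
    "AnalysisConfig",
    "average_magnitude",
    "detect_events",
    "summarize",
    "compare_groups",
    "GroupComparison",
]

RoiKey = tuple[str, str, str]  # (neuromast_id, cell_id, compartment)

EVENT_COLUMNS = [
    "neuromast_id",
    "cell_id",
    "compartment",
    "peak_frame",
    "peak_time_s",
    "peak_magnitude_dff",
    "duration_s",
    "start_frame",
    "end_frame",
]


@dataclass
class AnalysisConfig:
    """Detection parameters.

    ``threshold_dff`` is the true-signal threshold θ; ``min_prominence_dff``
    and ``min_peak_distance_s`` parameterize peak picking (defaults: θ and
    two frame intervals).  ``duration_mode`` selects the event-duration
    definition: ``"threshold_width"`` (contiguous time above θ) or
    ``"half_prominence"``.
    """

    threshold_dff: float = DFF_THRESHOLD
    min_prominence_dff: float = DFF_THRESHOLD
    min_peak_distance_s: Optional[float] = None
    duration_mode: str = "threshold_width"

    def __post_init__(self) -> None:
        if self.threshold_dff <= 0:
            raise ValueError("threshold_dff must be positive")
        if self.min_prominence_dff <= 0:
            raise ValueError("min_prominence_dff must be positive")
        if self.duration_mode not in ("threshold_width", "half_prominence"):
            raise ValueError(f"unknown duration_mode {self.duration_mode!r}")

    def distance_frames(self, frame_interval_s: float) -> int:
        if self.min_peak_distance_s is None:
            return 2
        return max(1, int(round(self.min_peak_distance_s / frame_interval_s)))


def average_magnitude(dff: np.ndarray, theta: float = DFF_THRESHOLD) -> float:
    """Mean above-threshold ΔF/F0 per frame over the whole recording.

    Frames with dff <= θ contribute zero to the sum but still count in
    the denominator (strict inequality at θ).
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    dff = np.asarray(dff, dtype=float)
    if dff.size == 0:
        raise ValueError("empty trace")
    return float(dff[dff > theta].sum() / dff.size)


def _threshold_segments(above: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True in a boolean series."""
    padded = np.concatenate([[False], above, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts, ends))


def detect_events(
    dff: np.ndarray,
    config: AnalysisConfig | None = None,
    frame_interval_s: float = 1.0,
    roi_key: RoiKey = ("", "", ""),
) -> pd.DataFrame:
    """Detect spontaneous peaks in a ΔF/F0 trace.

    Peak picking is local-maxima selection with a minimum height of θ
    (strict), a minimum separation and a minimum topographic prominence.
    When several peaks share one above-θ segment the segment is split at
    the trough between consecutive peaks, so each event owns a disjoint
    stretch of above-threshold time.
    """
    if config is None:
        config = AnalysisConfig()
    dff = np.asarray(dff, dtype=float)
    theta = config.threshold_dff
    peaks, _props = signal.find_peaks(
        dff,
        height=theta,
        distance=config.distance_frames(frame_interval_s),
        prominence=config.min_prominence_dff,
    )
    peaks = peaks[dff[peaks] > theta]  # strict inequality at the threshold
    rows = []
    if len(peaks) > 0:
        segments = _threshold_segments(dff > theta)
        seg_of_peak = {}
        for si, (s, e) in enumerate(segments):
            for p in peaks[(peaks >= s) & (peaks < e)]:
                seg_of_peak[p] = si
        # split shared segments at the trough between consecutive peaks
        bounds: dict[int, tuple[int, int]] = {}
        for si, (s, e) in enumerate(segments):
            ps = [p for p in peaks if seg_of_peak.get(p) == si]
            if not ps:
                continue
            cuts = [s]
            for left, right in zip(ps[:-1], ps[1:]):
                trough = left + int(np.argmin(dff[left : right + 1]))
                cuts.append(trough)
            cuts.append(e)
            for p, lo, hi in zip(ps, cuts[:-1], cuts[1:]):
                bounds[p] = (lo, hi)
        if config.duration_mode == "half_prominence":
            widths, _, _, _ = signal.peak_widths(dff, peaks, rel_height=0.5)
            half_width = dict(zip(peaks, widths))
        for p in peaks:
            lo, hi = bounds[p]
            if config.duration_mode == "threshold_width":
                duration = (hi - lo) * frame_interval_s
            else:
                duration = half_width[p] * frame_interval_s
            rows.append(
                (
                    *roi_key,
                    int(p),
                    p * frame_interval_s,
                    float(dff[p]),
                    float(duration),
                    int(lo),
                    int(hi),
                )
            )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def summarize(
    events: pd.DataFrame,
    dffs: Mapping[RoiKey, np.ndarray],
    recording_s: float,
    theta: float = DFF_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate detected events into per-ROI and per-neuromast tables.

    ROIs with no events contribute 0 to frequency and average magnitude
    but are excluded from the per-event means (peak, duration) — keeping
    silent ROIs in the denominator avoids survivorship bias.  Each
    neuromast value is the mean of its ROI values.
    """
    if recording_s <= 0:
        raise ValueError("recording_s must be positive")
    per_roi_rows = []
    for key, dff in dffs.items():
        nm, cell, comp = key
        if len(events):
            sel = events[
                (events.neuromast_id == nm)
                & (events.cell_id == cell)
                & (events.compartment == comp)
            ]
        else:
            sel = events
        n_ev = len(sel)
        per_roi_rows.append(
            {
                "neuromast_id": nm,
                "cell_id": cell,
                "compartment": comp,
                "n_events": n_ev,
                "frequency_per_s": n_ev / recording_s,
                "mean_peak_dff": sel.peak_magnitude_dff.mean() if n_ev else np.nan,
                "mean_duration_s": sel.duration_s.mean() if n_ev else np.nan,
                "average_magnitude": average_magnitude(dff, theta),
            }
        )
    per_roi = pd.DataFrame(per_roi_rows)
    per_nm = (
        per_roi.groupby("neuromast_id")
        .agg(
            n_rois=("cell_id", "size"),
            frequency_per_s=("frequency_per_s", "mean"),
            mean_peak_dff=("mean_peak_dff", "mean"),
            mean_duration_s=("mean_duration_s", "mean"),
            average_magnitude=("average_magnitude", "mean"),
        )
        .reset_index()
    )
    return per_roi, per_nm


@dataclass
class GroupComparison:
    statistic: float
    pvalue: float
    test: str  # which path was taken
    normal_a: bool
    normal_b: bool


def _is_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    # D'Agostino-Pearson needs n >= 8; smaller samples fall back to
    # Shapiro-Wilk
    if np.std(x) == 0:
        return False
    if len(x) >= 8:
        return stats.normaltest(x).pvalue > alpha
    return stats.shapiro(x).pvalue > alpha


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    paired: bool = False,
) -> GroupComparison:
    """Two-group comparison with a normality-gated test choice.

    Normal groups get a (paired or unpaired) t-test; otherwise a
    rank-based test (Wilcoxon signed-rank when paired, Mann-Whitney U
    when not).  Degenerate zero-variance groups take the rank path with a
    warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 values per group")
    if paired and len(a) != len(b):
        raise ValueError("paired comparison needs equal-length groups")
    if np.array_equal(a, b):
        return GroupComparison(0.0, 1.0, "identical", _is_normal(a), _is_normal(b))
    degenerate = np.std(a) == 0 or np.std(b) == 0
    if degenerate:
        warnings.warn(
            "zero-variance group; using the rank-based test", stacklevel=2
        )
    na, nb = (not degenerate) and _is_normal(a), (not degenerate) and _is_normal(b)
    if na and nb:
        if paired:
            res = stats.ttest_rel(a, b)
            name = "paired t-test"
        else:
            res = stats.ttest_ind(a, b)
            name = "unpaired t-test"
    else:
        if paired:
            res = stats.wilcoxon(a, b)
            name = "wilcoxon signed-rank"
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            name = "mann-whitney u"
    return GroupComparison(float(res.statistic), float(res.pvalue), name, na, nb)
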