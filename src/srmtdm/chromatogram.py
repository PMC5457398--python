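"""Peak detection and integration for scheduled-SRM chromatograms.

Each SRM trace is a short time/intensity series acquired around the
expected elution time of one transition.  Peaks are picked as the maximum
of a lightly smoothed trace inside a retention-time window, bounded where
the signal falls back to 5% of the apex height above the local background,
and integrated by the trapezoid rule after subtracting a linear baseline
anchored at the robust off-peak background level.  Detection requires the
apex to rise at least 3x above the background noise (MAD-based estimate);
quantification limits are enforced later via the LLOQ rules, not here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .assay import TransitionDef

__all__ = ["Chromatogram", "Peak", "detect_peak", "integrate_peak", "estimate_noise"]

#: Boundary threshold as a fraction of (apex height above baseline).
BOUNDARY_FRACTION = 0.05
#: Minimum apex height in noise units for a peak to count as found.
SN_FLOOR = 3.0
#: Moving-average width (points) applied before apex picking.
SMOOTH_POINTS = 5


@dataclass
class Chromatogram:
    """Time/intensity trace of a single SRM transition for one sample."""

    sample_id: str
    transition: TransitionDef
    times: np.ndarray  # minutes, strictly increasing
    intensities: np.ndarray  # arbitrary counts, >= 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.size != self.intensities.size:
            raise ValueError("times and intensities must have equal length")
        if self.times.size < 2:
            raise ValueError("a chromatogram needs at least 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class Peak:
    """An integrated chromatographic peak (or the record of not finding one)."""

    apex_rt: float  # minutes
    area: float  # intensity * minutes, baseline-subtracted
    left_bound: float
    right_bound: float
    height: float  # apex intensity above baseline
    signal_to_noise: float
    found: bool
    baseline: float = 0.0  # local background level used for bounds/integration

    def __post_init__(self):
        if self.found and not (self.left_bound <= self.apex_rt <= self.right_bound):
            raise ValueError("peak bounds must bracket the apex")
        if not self.found:
            self.area = 0.0


def estimate_noise(
    chrom: Chromatogram, exclusion: Sequence[tuple[float, float]] = ()
) -> float:
    """Robust noise scale of the trace outside the exclusion windows.

    Returns 1.4826 x the median absolute deviation of off-peak intensities,
    which estimates the standard deviation for Gaussian noise while being
    insensitive to stray spikes.  Requires >= 10 off-peak points.
    """
    mask = np.ones(chrom.times.size, dtype=bool)
    for lo, hi in exclusion:
        mask &= ~((chrom.times >= lo) & (chrom.times <= hi))
    vals = chrom.intensities[mask]
    if vals.size < 10:
        raise ValueError(
            f"need at least 10 points outside exclusion zones, have {vals.size}"
        )
    return float(1.4826 * np.median(np.abs(vals - np.median(vals))))


def _background(chrom: Chromatogram, lo: float, hi: float) -> tuple[float, float]:
    """(level, noise) of the trace outside [lo, hi]; falls back gracefully."""
    mask = (chrom.times < lo) | (chrom.times > hi)
    vals = chrom.intensities[mask]
    if vals.size >= 10:
        level = float(np.median(vals))
        noise = float(1.4826 * np.median(np.abs(vals - level)))
    elif vals.size > 0:
        level, noise = float(np.median(vals)), 0.0
    else:
        level, noise = float(np.min(chrom.intensities)), 0.0
    return level, noise


def detect_peak(chrom: Chromatogram, expected_rt: float, window: float) -> Peak:
    """Locate the transition's peak within ``expected_rt ± window``.

    The apex is the maximum of a 5-point moving average inside the window
    (earliest point on plateaus).  A peak is *found* when its apex rises at
    least 3x the off-window noise above the background; otherwise a
    zero-area record is returned.  Found peaks are integrated immediately.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    t = chrom.times
    if not (t[0] <= expected_rt <= t[-1]):
        raise ValueError(
            f"expected_rt {expected_rt} outside chromatogram span [{t[0]}, {t[-1]}]"
        )
    lo, hi = expected_rt - window, expected_rt + window
    smooth = uniform_filter1d(chrom.intensities, SMOOTH_POINTS, mode="nearest")
    in_win = np.flatnonzero((t >= lo) & (t <= hi))
    if in_win.size == 0:
        raise ValueError("search window contains no data points")
    baseline, noise = _background(chrom, lo, hi)

    apex_local = int(np.argmax(smooth[in_win]))  # argmax -> earliest on ties
    apex_idx = int(in_win[apex_local])
    height = float(smooth[apex_idx] - baseline)
    apex_rt = float(t[apex_idx])

    found = height > 0 and height >= SN_FLOOR * noise
    sn = float(height / noise) if noise > 0 else (np.inf if height > 0 else 0.0)
    if not found:
        return Peak(apex_rt, 0.0, apex_rt, apex_rt, max(height, 0.0), sn, False, baseline)

    threshold = baseline + BOUNDARY_FRACTION * height
    li = apex_idx
    while li > in_win[0] and smooth[li - 1] > threshold:
        li -= 1
    ri = apex_idx
    while ri < in_win[-1] and smooth[ri + 1] > threshold:
        ri += 1
    peak = Peak(
        apex_rt=apex_rt,
        area=0.0,
        left_bound=float(t[li]),
        right_bound=float(t[ri]),
        height=height,
        signal_to_noise=sn,
        found=True,
        baseline=baseline,
    )
    peak.area = integrate_peak(chrom, peak)
    return peak


def integrate_peak(chrom: Chromatogram, peak: Peak) -> float:
    """Trapezoidal area between the peak bounds, baseline-subtracted.

    The baseline is a straight line across the peak at the local background
    level (estimated robustly from the trace outside the peak region, padded
    by one peak-width); for a flat background this is a constant offset.
    Area is floored at zero.
    """
    if not peak.found:
        raise ValueError("cannot integrate a peak that was not found")
    t = chrom.times
    if peak.left_bound < t[0] or peak.right_bound > t[-1]:
        raise ValueError("peak bounds outside the chromatogram time span")
    li = int(np.searchsorted(t, peak.left_bound))
    ri = int(np.searchsorted(t, peak.right_bound, side="right")) - 1
    if ri <= li:
        return 0.0
    pad = peak.right_bound - peak.left_bound
    level, _ = _background(chrom, peak.left_bound - pad, peak.right_bound + pad)
    seg_t = t[li : ri + 1]
    seg_y = chrom.intensities[li : ri + 1] - level
    return max(float(np.trapezoid(seg_y, seg_t)), 0.0)
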