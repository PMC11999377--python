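"""Step detection from the trunk-acceleration norm.

The wearable's own pedometer algorithm is proprietary, so this module
provides a transparent stand-in with the same qualitative behaviour:
peak-over-adaptive-baseline detection with a refractory period and a bout
filter that suppresses isolated jolts (commercial pedometers typically ignore
a handful of steps in isolation).  It operates on the orientation-free norm
rather than the vertical axis for robustness to garment placement.

All parameters are exposed so the detector can be deliberately degraded
(e.g. raised threshold) to emulate missed steps in slow or irregular gait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .signal_core import NormSeries

logger = logging.getLogger(__name__)


@dataclass
class StepDetectorConfig:
    smoothing_window_s: float = 0.2      #: moving-average width applied first
    peak_threshold_g: float = 0.1        #: required height above local baseline
    refractory_s: float = 0.25           #: minimum inter-step interval
    max_step_interval_s: float = 2.0     #: gaps beyond this end a bout
    min_bout_steps: int = 4              #: bouts shorter than this are dropped
    baseline_window_s: float = 2.0       #: moving-median window for the baseline

    def __post_init__(self) -> None:
        if not (self.peak_threshold_g > 0 and self.smoothing_window_s > 0):
            raise ValueError("thresholds and windows must be positive")
        if not self.refractory_s < self.max_step_interval_s:
            raise ValueError("refractory_s must be < max_step_interval_s")
        if self.min_bout_steps < 1:
            raise ValueError("min_bout_steps must be >= 1")


@dataclass
class StepEvents:
    """Strictly increasing step-event times, seconds from recording start."""

    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")

    @property
    def count(self) -> int:
        return int(self.times.size)

    def __len__(self) -> int:
        return self.count


def _box_smooth(x: np.ndarray, k: int) -> np.ndarray:
    """Centered moving average with edge shrinkage, via cumulative sums."""
    if k <= 1:
        return x
    n = len(x)
    s = np.empty(n + 1)
    s[0] = 0
    np.cumsum(x, out=s[1:])
    half = k // 2
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + (k - half), 0, n)
    return (s[hi] - s[lo]) / (hi - lo)


def detect_steps(norm: NormSeries, cfg: StepDetectorConfig | None = None
                 ) -> StepEvents:
    """Detect step events in a trunk-acceleration norm series.

    Pipeline: moving-average smoothing; adaptive baseline as a moving median;
    local maxima exceeding baseline + ``peak_threshold_g``; refractory
    enforcement; removal of bouts with fewer than ``min_bout_steps`` peaks
    spaced <= ``max_step_interval_s`` apart.  Quiet signals yield no events.
    """
    cfg = cfg or StepDetectorConfig()
    if len(norm) == 0:
        raise ValueError("cannot detect steps in an empty series")
    fs = norm.sampling_rate_hz

    vals = norm.values
    if not norm.valid.all():
        fill = float(np.median(vals[norm.valid])) if norm.valid.any() else 1.0
        vals = np.where(norm.valid, vals, fill)

    k = max(1, int(round(cfg.smoothing_window_s * fs)))
    smooth = _box_smooth(vals, k)

    b = int(round(cfg.baseline_window_s * fs)) | 1  # odd window
    if len(smooth) > 200_000:
        # the baseline varies on the scale of seconds, so for long
        # recordings the moving median is evaluated on a 4x-decimated grid
        # and held constant in between
        d = 4
        dec = smooth[::d]
        bd = max(3, int(round(b / d)) | 1)
        base_dec = ndimage.median_filter(dec, size=min(bd, len(dec)),
                                         mode="nearest")
        baseline = np.repeat(base_dec, d)[:len(smooth)]
    else:
        baseline = ndimage.median_filter(smooth, size=min(b, len(smooth)),
                                         mode="nearest")
    height = baseline + cfg.peak_threshold_g

    interior = np.zeros(len(smooth), dtype=bool)
    if len(smooth) >= 3:
        interior[1:-1] = (smooth[1:-1] >= smooth[:-2]) & (smooth[1:-1] > smooth[2:])
    cand = np.flatnonzero(interior & (smooth > height) & norm.valid)

    if cand.size == 0:
        return StepEvents(np.empty(0))

    # refractory: greedy left-to-right suppression
    refr = cfg.refractory_s * fs
    kept = [int(cand[0])]
    for i in cand[1:]:
        if i - kept[-1] >= refr:
            kept.append(int(i))
    times = np.asarray(kept, dtype=float) / fs

    # bout filter: split at long gaps, drop short bouts
    if times.size:
        breaks = np.flatnonzero(np.diff(times) > cfg.max_step_interval_s) + 1
        bouts = np.split(times, breaks)
        times = np.concatenate(
            [b for b in bouts if len(b) >= cfg.min_bout_steps] or [np.empty(0)])
    logger.debug("detected %d steps", times.size)
    return StepEvents(times)
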