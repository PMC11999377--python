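"""Raw trunk acceleration -> minute-level MSDA series.

MSDA (moving standard deviation of acceleration) is a threshold-free,
continuous physical-activity metric: the standard deviation of the Euclidean
norm of chest-worn triaxial acceleration, computed over a short sliding
window (2 s / 50 samples at the 25 Hz device rate) and aggregated to
minute-of-day values.

Axis convention for the chest-worn sensor: x = vertical, y = lateral,
z = anterior/posterior, all in units of g.  Gravity is deliberately *not*
removed before windowing: within a window the constant component does not
affect the standard deviation, so no high-pass filtering is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime
from typing import Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: number of minutes in a day / slots in a daily series
MINUTES_PER_DAY = 1440


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RawRecording:
    """Uniformly sampled triaxial acceleration stream for one subject.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    start_time : datetime
        Wall-clock time of the first sample.
    sampling_rate_hz : float
        Sampling rate; the device default is 25 Hz.
    samples : (n, 3) ndarray
        Acceleration in g; columns are (vertical, lateral, anterior/posterior).
    gap_mask : (n,) bool ndarray
        True where the sample is valid.  Gaps (device off, garment change)
        are False.
    """

    subject_id: str
    start_time: datetime
    samples: np.ndarray
    sampling_rate_hz: float = 25.0
    gap_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array of x, y, z in g")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.gap_mask is None:
            self.gap_mask = np.ones(len(self.samples), dtype=bool)
        else:
            self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
            if self.gap_mask.shape != (len(self.samples),):
                raise ValueError("gap_mask length must match samples")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass
class NormSeries:
    """Per-sample acceleration norm, timing inherited from the recording."""

    values: np.ndarray
    valid: np.ndarray
    start_time: datetime
    sampling_rate_hz: float

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class MsdaConfig:
    """Windowing configuration for the MSDA computation.

    ``window_samples`` takes precedence when set explicitly; otherwise the
    window is resolved as ``round(window_seconds * sampling_rate_hz)``.
    The device convention is a 2-second window, i.e. 50 samples at 25 Hz.
    """

    window_seconds: float = 2.0
    window_samples: int | None = None
    stride_samples: int = 1
    sd_denominator: Literal["sample", "population"] = "sample"
    minute_min_valid_fraction: float = 0.5
    norm_variant: Literal["euclidean", "squared"] = "euclidean"

    def __post_init__(self) -> None:
        if self.window_seconds is not None and not self.window_seconds > 0:
            raise ValueError("window_seconds must be positive")
        if self.window_samples is not None and self.window_samples < 1:
            raise ValueError("window_samples must be a positive integer")
        if self.stride_samples < 1:
            raise ValueError("stride_samples must be a positive integer")
        if self.sd_denominator not in ("sample", "population"):
            raise ValueError("sd_denominator must be 'sample' or 'population'")
        if not 0.0 <= self.minute_min_valid_fraction <= 1.0:
            raise ValueError("minute_min_valid_fraction must be in [0, 1]")

    def resolve_window_samples(self, sampling_rate_hz: float) -> int:
        """Window length in samples at the given rate (2 s @ 25 Hz -> 50)."""
        from_seconds = int(round(self.window_seconds * sampling_rate_hz))
        if self.window_samples is None:
            if from_seconds < 1:
                raise ValueError("window shorter than one sample")
            return from_seconds
        if self.window_samples != from_seconds:
            raise ValueError(
                f"window_samples={self.window_samples} inconsistent with "
                f"window_seconds={self.window_seconds} at "
                f"{sampling_rate_hz} Hz (expects {from_seconds})"
            )
        return self.window_samples


@dataclass
class MsdaStream:
    """Per-sample MSDA stream, right-aligned to the window end.

    ``values[i]`` is the SD of the window ending at sample ``i``; NaN where no
    full window of valid samples ends at ``i`` (or off the stride grid).
    ``sample_valid`` carries the raw per-sample validity for minute
    aggregation.
    """

    values: np.ndarray
    sample_valid: np.ndarray
    start_time: datetime
    sampling_rate_hz: float
    window_samples: int
    stride_samples: int = 1


@dataclass
class MinuteSeries:
    """Minute-by-minute MSDA and step counts for one calendar day.

    Exactly 1440 slots (0-based, half-open minutes).  ``msda``/``steps`` are
    NaN exactly where ``valid`` is False.
    """

    day_index: int
    msda: np.ndarray
    steps: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        for name in ("msda", "steps", "valid"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (MINUTES_PER_DAY,):
                raise ValueError(f"{name} must have exactly {MINUTES_PER_DAY} slots")
        self.msda = np.asarray(self.msda, dtype=float)
        self.steps = np.asarray(self.steps, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def acceleration_norm(rec: RawRecording,
                      variant: Literal["euclidean", "squared"] = "euclidean",
                      ) -> NormSeries:
    """Per-sample norm of the triaxial acceleration vector.

    The standard (and default) reading is the Euclidean norm
    sqrt(x² + y² + z²).  ``variant="squared"`` (x² + y² + z²) exists only for
    sensitivity checks.  Non-finite samples are marked invalid and logged;
    samples already flagged as gaps stay invalid.
    """
    if rec.n_samples == 0:
        raise ValueError("cannot compute the norm of an empty recording")
    s = rec.samples
    if s.flags.f_contiguous and not s.flags.c_contiguous:
        # transposed view of a contiguous (3, n) buffer: row access is cheap
        t = s.T
        sq = t[0] * t[0] + t[1] * t[1] + t[2] * t[2]
    else:
        sq = np.einsum("ij,ij->i", s, s)
    values = sq if variant == "squared" else np.sqrt(sq)
    finite = np.isfinite(values)
    n_bad = int(np.count_nonzero(~finite & rec.gap_mask))
    if n_bad:
        logger.warning("%s: %d non-finite samples marked invalid",
                       rec.subject_id, n_bad)
    valid = rec.gap_mask & finite
    values = np.where(finite, values, 0.0)
    return NormSeries(values=values, valid=valid, start_time=rec.start_time,
                      sampling_rate_hz=rec.sampling_rate_hz)


def moving_sd(norm: NormSeries, cfg: MsdaConfig | None = None) -> MsdaStream:
    """Sliding-window standard deviation of the acceleration norm.

    Emits, for every position where a *full* window of valid samples ends,
    the SD of that window; other positions are NaN.  The computation centers
    the series on its global mean before forming cumulative sums, which keeps
    the sum-of-squares cancellation benign at recording length.
    """
    cfg = cfg or MsdaConfig()
    w = cfg.resolve_window_samples(norm.sampling_rate_hz)
    n = len(norm)
    out = np.full(n, np.nan)
    if w > n:
        logger.warning("window of %d samples longer than series of %d; "
                       "empty MSDA stream", w, n)
        return MsdaStream(out, norm.valid.copy(), norm.start_time,
                          norm.sampling_rate_hz, w, cfg.stride_samples)

    valid = norm.valid
    all_valid = bool(valid.all())
    n_valid = n if all_valid else int(np.count_nonzero(valid))
    if n_valid == 0:
        logger.warning("no valid samples; empty MSDA stream")
        return MsdaStream(out, valid.copy(), norm.start_time,
                          norm.sampling_rate_hz, w, cfg.stride_samples)
    center = (norm.values.sum() if all_valid
              else norm.values[valid].sum()) / n_valid

    # centered cumulative sums, computed with minimal temporaries
    c = norm.values - center
    if not all_valid:
        c[~valid] = 0.0
    s1 = np.empty(n + 1)
    s1[0] = 0.0
    np.cumsum(c, out=s1[1:])
    np.multiply(c, c, out=c)
    s2 = np.empty(n + 1)
    s2[0] = 0.0
    np.cumsum(c, out=s2[1:])

    win_sum = s1[w:] - s1[:-w]
    var = s2[w:] - s2[:-w]
    np.multiply(win_sum, win_sum, out=win_sum)
    win_sum /= w
    var -= win_sum
    var /= (w - 1) if cfg.sd_denominator == "sample" else w
    np.maximum(var, 0.0, out=var)
    sd = np.sqrt(var, out=var)
    if not all_valid:
        sv = np.empty(n + 1, dtype=np.int64)
        sv[0] = 0
        np.cumsum(valid, out=sv[1:])
        sd[(sv[w:] - sv[:-w]) < w] = np.nan

    out[w - 1:] = sd
    if cfg.stride_samples > 1:
        on_grid = np.zeros(n, dtype=bool)
        on_grid[w - 1::cfg.stride_samples] = True
        out[~on_grid] = np.nan
    return MsdaStream(out, valid.copy(), norm.start_time,
                      norm.sampling_rate_hz, w, cfg.stride_samples)


def _global_minute_index(offset_s: float, sample_idx: np.ndarray,
                         fs: float) -> np.ndarray:
    """Minute index counted from midnight of the recording's first day."""
    spm = fs * 60.0
    if abs(spm - round(spm)) < 1e-9:
        # exact integer path: avoids float boundary flips
        off = int(round(offset_s * fs))
        return (off + sample_idx) // int(round(spm))
    return np.floor((offset_s + sample_idx / fs) / 60.0).astype(np.int64)


def minute_aggregate(stream: MsdaStream,
                     step_times_s: Sequence[float] | np.ndarray | None,
                     cfg: MsdaConfig | None = None) -> list[MinuteSeries]:
    """Aggregate an MSDA stream and step events into per-day minute series.

    Per minute-of-day slot: ``msda`` is the mean of window SDs whose window
    end falls in that minute, ``steps`` the number of step events in it.  A
    slot is valid only when the fraction of valid raw samples (against a full
    minute's worth) is >= ``minute_min_valid_fraction`` (inclusive) and at
    least one window SD was emitted.  Minutes not covered by the recording
    are missing.  Returns one :class:`MinuteSeries` per calendar day touched.
    """
    cfg = cfg or MsdaConfig()
    fs = stream.sampling_rate_hz
    n = len(stream.values)
    st = stream.start_time
    offset_s = st.hour * 3600 + st.minute * 60 + st.second + st.microsecond / 1e6

    idx = np.arange(n, dtype=np.int64)
    gm = _global_minute_index(offset_s, idx, fs)
    gm0, gm1 = int(gm[0]), int(gm[-1])
    nm = gm1 - gm0 + 1
    rel = (gm - gm0).astype(np.intp)

    samples_per_minute = fs * 60.0
    valid_count = np.bincount(rel, weights=stream.sample_valid, minlength=nm)
    emitted = np.isfinite(stream.values)
    msda_sum = np.bincount(rel, weights=np.where(emitted, stream.values, 0.0),
                           minlength=nm)
    msda_cnt = np.bincount(rel, weights=emitted, minlength=nm)

    frac_valid = valid_count / samples_per_minute
    slot_valid = (frac_valid >= cfg.minute_min_valid_fraction) & (msda_cnt > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        msda_val = np.where(slot_valid, msda_sum / np.maximum(msda_cnt, 1), np.nan)

    steps_val = np.zeros(nm)
    if step_times_s is not None and len(np.atleast_1d(step_times_s)):
        t = np.asarray(step_times_s, dtype=float)
        sgm = np.floor((offset_s + t) / 60.0).astype(np.int64)
        in_range = (sgm >= gm0) & (sgm <= gm1)
        steps_val += np.bincount((sgm[in_range] - gm0).astype(np.intp),
                                 minlength=nm)
    steps_val = np.where(slot_valid, steps_val, np.nan)

    days: list[MinuteSeries] = []
    minute_ids = np.arange(gm0, gm1 + 1)
    day_ids = minute_ids // MINUTES_PER_DAY
    slots = minute_ids % MINUTES_PER_DAY
    for day in np.unique(day_ids):
        sel = day_ids == day
        msda_day = np.full(MINUTES_PER_DAY, np.nan)
        steps_day = np.full(MINUTES_PER_DAY, np.nan)
        valid_day = np.zeros(MINUTES_PER_DAY, dtype=bool)
        msda_day[slots[sel]] = msda_val[sel]
        steps_day[slots[sel]] = steps_val[sel]
        valid_day[slots[sel]] = slot_valid[sel]
        days.append(MinuteSeries(day_index=int(day), msda=msda_day,
                                 steps=steps_day, valid=valid_day))
    return days
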