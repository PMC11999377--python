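"""Synthetic 48-hour trunk-accelerometry cohort with ground-truth steps.

Emulates chest-worn recordings from a convalescent rehabilitation ward:
a 1 g gravity baseline on the vertical axis plus rest noise, activity bouts
scheduled in waking hours, and one missing block per day (bathing, garment
change).  Gait bouts superpose a cadence-locked train of heel-strike
transients (raised-cosine bumps on the vertical axis) plus trunk sway on the
anterior/posterior axis; wheelchair-propulsion bouts superpose bounded
narrowband oscillation on the horizontal axes, which moves the MSDA but
produces no step-like impulses.  Every synthetic step time is recorded as
ground truth, so detector recall/precision and the step "floor effect" can be
measured exactly.

Subgroup intensity profiles are graded by the FIM-mobility strata
(FIM1-4 lowest activity ... FIM7 highest).  Between-subject spread comes from
a lognormal activity factor; a small ``inactive_prob`` lets walking-capable
subjects record no gait at all during the window (their bouts become
non-walking activity), which is what produces occasional zero-step subjects
outside the wheelchair stratum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .signal_core import RawRecording

#: default recording start: before noon on the first assessment day
DEFAULT_START = datetime(2024, 1, 1, 10, 0, 0)

#: waking hours within which activity bouts are scheduled (clock hours)
WAKING_HOURS = (7.0, 21.0)

_IMPULSE_WIDTH_S = 0.12   # heel-strike transient width
_SWAY_RATIO = 0.25        # AP sway amplitude relative to impulse amplitude


@dataclass
class SubgroupProfile:
    """Activity-intensity profile for one mobility subgroup."""

    label: str
    n_subjects: int
    mobility_mode: str                    # "walking" or "wheelchair"
    fim_levels: tuple[int, ...]           # FIM-mobility scores drawn uniformly
    bouts_per_day: float                  # mean activity bouts per 24 h
    bout_duration_s: tuple[float, float]  # (mean, sd) of bout length
    walk_fraction: float                  # fraction of bouts that are gait
    gait_cadence_hz: tuple[float, float]  # per-subject uniform range, steps/s
    gait_impulse_g: float                 # heel-strike transient amplitude
    wc_osc_g: float                       # propulsion oscillation amplitude
    rest_noise_g: float                   # baseline noise sigma
    missing_per_day: int = 1              # missing blocks per day (bathing)
    missing_duration_s: float = 1800.0
    subject_sigma: float = 0.4            # lognormal sigma of activity factor
    gait_sigma: float = 0.8               # lognormal sigma of gait propensity
    cadence_jitter: float = 0.05          # per-step timing jitter fraction
    inactive_prob: float = 0.0            # chance a subject records no gait

    def __post_init__(self) -> None:
        if self.mobility_mode not in ("walking", "wheelchair"):
            raise ValueError("mobility_mode must be 'walking' or 'wheelchair'")
        for name in ("gait_impulse_g", "wc_osc_g", "rest_noise_g"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.walk_fraction <= 1.0:
            raise ValueError("walk_fraction must be in [0, 1]")
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be nonnegative")


@dataclass
class GroundTruth:
    """Simulation ground truth for one subject."""

    step_times: np.ndarray                       # seconds from recording start
    bouts: list[tuple[float, float, str]]        # (start_s, duration_s, kind)
    label: str
    activity_factor: float = 1.0


def default_profiles(scale: float = 1.0) -> list[SubgroupProfile]:
    """The six study subgroups with calibrated intensity defaults.

    Subgroup sizes follow the study cohort (94/23/15/19/18/28 in display
    order, 197 subjects in total); ``scale`` shrinks every subgroup
    proportionally (minimum 1 subject) for cheaper experiments.
    """
    base = [
        SubgroupProfile("FIM1-4", 94, "wheelchair", (1, 2, 3, 4),
                        bouts_per_day=6.0, bout_duration_s=(40.0, 15.0),
                        walk_fraction=0.35, gait_cadence_hz=(0.9, 1.2),
                        gait_impulse_g=0.45, wc_osc_g=0.18,
                        rest_noise_g=0.0060, inactive_prob=0.04),
        SubgroupProfile("FIM5-WC", 23, "wheelchair", (5,),
                        bouts_per_day=8.0, bout_duration_s=(100.0, 30.0),
                        walk_fraction=0.25, gait_cadence_hz=(1.0, 1.3),
                        gait_impulse_g=0.45, wc_osc_g=0.22,
                        rest_noise_g=0.0069, inactive_prob=0.02),
        SubgroupProfile("FIM5-walk", 15, "walking", (5,),
                        bouts_per_day=8.0, bout_duration_s=(210.0, 50.0),
                        walk_fraction=0.80, gait_cadence_hz=(1.2, 1.5),
                        gait_impulse_g=0.50, wc_osc_g=0.22,
                        rest_noise_g=0.0081, inactive_prob=0.03),
        SubgroupProfile("FIM6-WC", 19, "wheelchair", (6,),
                        bouts_per_day=10.0, bout_duration_s=(110.0, 35.0),
                        walk_fraction=0.30, gait_cadence_hz=(1.2, 1.5),
                        gait_impulse_g=0.50, wc_osc_g=0.26,
                        rest_noise_g=0.0102, inactive_prob=0.0),
        SubgroupProfile("FIM6-walk", 18, "walking", (6,),
                        bouts_per_day=12.0, bout_duration_s=(230.0, 55.0),
                        walk_fraction=0.85, gait_cadence_hz=(1.4, 1.7),
                        gait_impulse_g=0.50, wc_osc_g=0.26,
                        rest_noise_g=0.0103, inactive_prob=0.02),
        SubgroupProfile("FIM7", 28, "walking", (7,),
                        bouts_per_day=14.0, bout_duration_s=(250.0, 60.0),
                        walk_fraction=0.95, gait_cadence_hz=(1.6, 1.9),
                        gait_impulse_g=0.55, wc_osc_g=0.26,
                        rest_noise_g=0.0105, inactive_prob=0.01),
    ]
    if scale == 1.0:
        return base
    return [replace(p, n_subjects=max(1, round(p.n_subjects * scale)))
            for p in base]


# ---------------------------------------------------------------------------
# scheduling helpers
# ---------------------------------------------------------------------------

def _waking_intervals(start: datetime, duration_s: float
                      ) -> list[tuple[float, float]]:
    """Waking-hour intervals in recording time (seconds from start)."""
    offset = start.hour * 3600 + start.minute * 60 + start.second
    lo, hi = WAKING_HOURS[0] * 3600, WAKING_HOURS[1] * 3600
    out = []
    day0 = -(offset // 86400)  # first calendar day index relative to start
    for day in range(int(day0), int((offset + duration_s) // 86400) + 1):
        a = day * 86400 + lo - offset
        b = day * 86400 + hi - offset
        a, b = max(a, 0.0), min(b, duration_s)
        if b > a:
            out.append((a, b))
    return out


def _subtract_intervals(intervals: list[tuple[float, float]],
                        holes: list[tuple[float, float]]
                        ) -> list[tuple[float, float]]:
    for h0, h1 in holes:
        nxt = []
        for a, b in intervals:
            if h1 <= a or h0 >= b:
                nxt.append((a, b))
            else:
                if a < h0:
                    nxt.append((a, h0))
                if h1 < b:
                    nxt.append((h1, b))
        intervals = nxt
    return intervals


def _sample_bout_slots(rng: np.random.Generator, free: list[tuple[float, float]],
                       n_bouts: int, dur_mean: float, dur_sd: float,
                       ) -> list[tuple[float, float]]:
    """Place non-overlapping bouts uniformly in the free intervals."""
    placed: list[tuple[float, float]] = []
    for _ in range(n_bouts):
        dur = float(np.clip(rng.normal(dur_mean, dur_sd), 20.0, 4 * dur_mean))
        lengths = np.array([max(b - a - dur, 0.0) for a, b in free])
        for _try in range(50):
            total = lengths.sum()
            if total <= 0:
                break
            i = rng.choice(len(free), p=lengths / total)
            a, b = free[i]
            t0 = a + rng.uniform(0.0, b - a - dur)
            t1 = t0 + dur
            if all(t1 <= p0 or t0 >= p1 for p0, p1 in placed):
                placed.append((t0, t1))
                break
    placed.sort()
    return placed


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def _gait_bout(rng: np.random.Generator, x: np.ndarray, z: np.ndarray,
               t0: float, t1: float, fs: float, cadence: float,
               impulse_g: float, jitter: float) -> np.ndarray:
    """Add a gait bout to the signal in place; return scheduled step times.

    The step count is exactly floor(duration * cadence); jitter perturbs the
    individual step times without changing the count.
    """
    dur = t1 - t0
    n_steps = int(math.floor(dur * cadence))
    if n_steps == 0:
        return np.empty(0)
    base = (np.arange(n_steps) + 0.5) / cadence
    if jitter > 0:
        base = base + rng.uniform(-jitter, jitter, n_steps) / cadence
    base = np.clip(base, 0.02, dur - 0.02)
    base.sort()
    step_times = t0 + base

    i0, i1 = int(round(t0 * fs)), min(int(round(t1 * fs)), len(x))
    seg = np.zeros(i1 - i0)
    idx = np.round(step_times * fs).astype(int) - i0
    idx = np.clip(idx, 0, len(seg) - 1)
    amps = impulse_g * rng.uniform(0.92, 1.08, n_steps)
    np.add.at(seg, idx, amps)
    k = max(1, int(round(_IMPULSE_WIDTH_S * fs)))
    kernel = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(1, k + 1) / (k + 1)))
    x[i0:i1] += np.convolve(seg, kernel, mode="same")

    tt = np.arange(i1 - i0) / fs
    z[i0:i1] += (_SWAY_RATIO * impulse_g
                 * np.sin(2.0 * np.pi * cadence * tt + rng.uniform(0, 2 * np.pi)))
    return step_times


def _wc_bout(rng: np.random.Generator, y: np.ndarray, z: np.ndarray,
             t0: float, t1: float, fs: float, osc_g: float) -> None:
    """Add a wheelchair-propulsion bout: bounded narrowband trunk oscillation."""
    i0, i1 = int(round(t0 * fs)), min(int(round(t1 * fs)), len(y))
    tt = np.arange(i1 - i0) / fs
    f = rng.uniform(0.8, 1.2)
    env = 1.0 + 0.25 * np.sin(2.0 * np.pi * 0.07 * tt + rng.uniform(0, 2 * np.pi))
    y[i0:i1] += osc_g * env * np.sin(2.0 * np.pi * f * tt + rng.uniform(0, 2 * np.pi))
    z[i0:i1] += 0.8 * osc_g * env * np.sin(
        2.0 * np.pi * 1.03 * f * tt + rng.uniform(0, 2 * np.pi))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def generate_subject(profile: SubgroupProfile, seed: int | np.random.SeedSequence,
                     *, duration_h: float = 48.0, sampling_rate_hz: float = 25.0,
                     start_time: datetime = DEFAULT_START,
                     subject_id: str = "S0000",
                     ) -> tuple[RawRecording, GroundTruth]:
    """Simulate one subject's recording and its ground truth.

    Deterministic for a fixed seed.  The recording is gravity (1 g on the
    vertical axis) + rest noise + scheduled bouts, with ``missing_per_day``
    gap blocks per day; ground truth lists every synthetic step time.
    """
    rng = np.random.default_rng(seed)
    fs = sampling_rate_hz
    dur_s = duration_h * 3600.0
    n = int(round(dur_s * fs))
    n_days = max(1, int(math.ceil(duration_h / 24.0)))

    # per-subject characteristics; gait propensity is deliberately only
    # weakly tied to overall activity so that subjects who move a lot but
    # hardly walk (the wheelchair floor-effect mechanism) do occur
    act = float(np.clip(rng.lognormal(0.0, profile.subject_sigma), 0.15, 4.0))
    cadence = rng.uniform(*profile.gait_cadence_hz)
    amp_factor = float(rng.lognormal(0.0, 0.10))
    gait_prop = float(rng.lognormal(0.0, profile.gait_sigma))
    walks = (profile.walk_fraction > 0) and (rng.random() >= profile.inactive_prob)
    p_gait = min(1.0, profile.walk_fraction * gait_prop) if walks else 0.0
    day_jitter = rng.uniform(0.9, 1.1, n_days)  # day-to-day intensity

    rest_sd = profile.rest_noise_g * act ** 0.3
    # one contiguous (3, n) buffer; the recording holds its (n, 3) view
    signals = rng.standard_normal((3, n))
    signals *= rest_sd
    x, y, z = signals
    x += 1.0

    # missing blocks (bathing analog), late afternoon with jitter
    offset = start_time.hour * 3600 + start_time.minute * 60 + start_time.second
    gaps: list[tuple[float, float]] = []
    for day in range(n_days):
        for _ in range(profile.missing_per_day):
            clock = 17.0 * 3600 + rng.uniform(0.0, 7200.0)
            g0 = day * 86400 + clock - offset
            g1 = g0 + profile.missing_duration_s
            g0, g1 = max(g0, 0.0), min(g1, dur_s)
            if g1 > g0:
                gaps.append((g0, g1))

    free = _subtract_intervals(_waking_intervals(start_time, dur_s), gaps)
    n_bouts = int(rng.poisson(profile.bouts_per_day * act * duration_h / 24.0))
    slots = _sample_bout_slots(rng, free, n_bouts,
                               *profile.bout_duration_s)

    step_times: list[np.ndarray] = []
    bouts: list[tuple[float, float, str]] = []
    for t0, t1 in slots:
        day = min(int((t0 // 86400)), n_days - 1)
        jd = day_jitter[day]
        is_gait = rng.random() < p_gait
        if is_gait:
            st = _gait_bout(rng, x, z, t0, t1, fs, cadence,
                            profile.gait_impulse_g * amp_factor * jd,
                            profile.cadence_jitter)
            step_times.append(st)
            bouts.append((t0, t1 - t0, "gait"))
        else:
            _wc_bout(rng, y, z, t0, t1, fs, profile.wc_osc_g * amp_factor * jd)
            bouts.append((t0, t1 - t0, "wheelchair"))

    gap_mask = np.ones(n, dtype=bool)
    for g0, g1 in gaps:
        i0, i1 = int(round(g0 * fs)), min(int(round(g1 * fs)), n)
        gap_mask[i0:i1] = False
        x[i0:i1] = y[i0:i1] = z[i0:i1] = 0.0

    all_steps = (np.sort(np.concatenate(step_times)) if step_times
                 else np.empty(0))
    rec = RawRecording(subject_id=subject_id, start_time=start_time,
                       samples=signals.T, sampling_rate_hz=fs,
                       gap_mask=gap_mask)
    truth = GroundTruth(step_times=all_steps, bouts=bouts,
                        label=profile.label, activity_factor=act)
    return rec, truth


@dataclass
class Cohort:
    """Lazy cohort: metadata up front, recordings generated on iteration."""

    metadata: pd.DataFrame
    profiles: list[SubgroupProfile]
    _seeds: list[np.random.SeedSequence] = field(repr=False, default_factory=list)
    _subject_kwargs: dict = field(repr=False, default_factory=dict)

    def iter_subjects(self) -> Iterator[tuple[pd.Series, RawRecording, GroundTruth]]:
        """Yield (metadata row, recording, ground truth) per subject."""
        by_label = {p.label: p for p in self.profiles}
        for (_, row), seed in zip(self.metadata.iterrows(), self._seeds):
            rec, truth = generate_subject(by_label[row.subgroup], seed,
                                          subject_id=row.subject_id,
                                          **self._subject_kwargs)
            yield row, rec, truth


def generate_cohort(profiles: Sequence[SubgroupProfile] | None = None,
                    seed: int = 0, **subject_kwargs) -> Cohort:
    """Build a cohort from subgroup profiles, reproducibly seeded.

    Per-subject seeds are spawned from the master seed, so the same master
    seed always yields the identical cohort.  The metadata table (subject_id,
    subgroup, mobility_mode, fim_mobility) is materialized immediately;
    recordings are generated lazily by :meth:`Cohort.iter_subjects`.
    """
    profiles = list(profiles) if profiles is not None else default_profiles()
    if any(p.n_subjects < 1 for p in profiles):
        raise ValueError("every included profile needs n_subjects >= 1")
    ss = np.random.SeedSequence(seed)
    meta_rng = np.random.default_rng(ss.spawn(1)[0])
    total = sum(p.n_subjects for p in profiles)
    seeds = ss.spawn(total)

    rows = []
    i = 0
    for p in profiles:
        for _ in range(p.n_subjects):
            fim = int(meta_rng.choice(p.fim_levels))
            rows.append({"subject_id": f"S{i:04d}", "subgroup": p.label,
                         "mobility_mode": p.mobility_mode, "fim_mobility": fim})
            i += 1
    meta = pd.DataFrame(rows)
    return Cohort(metadata=meta, profiles=profiles, _seeds=seeds,
                  _subject_kwargs=subject_kwargs)
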