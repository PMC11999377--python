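"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

from datetime import datetime

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import msda

settings.register_profile(
    "suite", derandomize=True, max_examples=30, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

MIDNIGHT = datetime(2024, 1, 1, 0, 0, 0)


def make_norm(values, fs: float = 25.0, valid=None,
              start=MIDNIGHT) -> msda.NormSeries:
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(len(values), dtype=bool)
    return msda.NormSeries(values=values, valid=np.asarray(valid, bool),
                           start_time=start, sampling_rate_hz=fs)


def make_recording(samples, fs: float = 25.0, gap_mask=None,
                   start=MIDNIGHT, subject_id="T0") -> msda.RawRecording:
    return msda.RawRecording(subject_id=subject_id, start_time=start,
                             samples=np.asarray(samples, float),
                             sampling_rate_hz=fs, gap_mask=gap_mask)


def minute_series(day=0, msda_fill=np.nan, steps_fill=np.nan, valid_fill=False,
                  ) -> msda.MinuteSeries:
    n = msda.MINUTES_PER_DAY
    return msda.MinuteSeries(
        day_index=day,
        msda=np.full(n, msda_fill, dtype=float),
        steps=np.full(n, steps_fill, dtype=float),
        valid=np.full(n, valid_fill, dtype=bool))


def impulse_train(n_steps: int, cadence_hz: float, amplitude: float,
                  fs: float = 25.0, noise_sd: float = 0.02,
                  width_s: float = 0.12, pad_s: float = 5.0, seed: int = 0,
                  ) -> tuple[msda.NormSeries, np.ndarray]:
    """A gravity+noise norm trace carrying a train of step-like bumps."""
    rng = np.random.default_rng(seed)
    dur = n_steps / cadence_hz + 2 * pad_s
    n = int(round(dur * fs))
    sig = rng.normal(1.0, noise_sd, n)
    times = pad_s + (np.arange(n_steps) + 0.5) / cadence_hz
    k = max(1, int(round(width_s * fs)))
    kernel = 0.5 * (1 - np.cos(2 * np.pi * np.arange(1, k + 1) / (k + 1)))
    spikes = np.zeros(n)
    spikes[np.round(times * fs).astype(int)] = amplitude
    sig += np.convolve(spikes, kernel, mode="same")
    return make_norm(sig, fs=fs), times


@pytest.fixture(scope="session")
def pooled_summaries():
    """Subject summaries pooled over 10 synthetic cohort replicates.

    Ten cohort seeds at 0.15x the default subgroup sizes; this is the shared
    basis for the qualitative-reproduction checks (correlation structure,
    floor effect, subgroup ordering).
    """
    return msda.pooled_cohort_summaries(n_seeds=10, scale=0.15, seed=1)
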