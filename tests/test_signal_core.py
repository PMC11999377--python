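"""Norm computation, sliding-window SD, and minute aggregation."""

from datetime import datetime

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import msda
from msda.signal_core import MsdaConfig, minute_aggregate, moving_sd

from conftest import MIDNIGHT, make_norm, make_recording


# ---------------------------------------------------------------------------
# acceleration norm
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("xyz, expected", [
    ((0.0, 0.0, 0.0), 0.0),
    ((1.0, 0.0, 0.0), 1.0),
    ((0.6, 0.8, 0.0), 1.0),
    ((0.0, -1.0, 0.0), 1.0),
])
def test_acceleration_norm_examples(xyz, expected):
    rec = make_recording([xyz])
    norm = msda.acceleration_norm(rec)
    assert norm.values[0] == pytest.approx(expected)


def test_acceleration_norm_empty_recording_errors():
    rec = make_recording(np.empty((0, 3)))
    with pytest.raises(ValueError, match="empty"):
        msda.acceleration_norm(rec)


def test_acceleration_norm_nonfinite_marked_invalid(caplog):
    samples = [(1.0, 0, 0), (np.nan, 0, 0), (0, np.inf, 0), (0.6, 0.8, 0)]
    with caplog.at_level("WARNING"):
        norm = msda.acceleration_norm(make_recording(samples))
    assert list(norm.valid) == [True, False, False, True]
    assert "non-finite" in caplog.text


def test_acceleration_norm_squared_variant():
    norm = msda.acceleration_norm(make_recording([(0.6, 0.8, 0.0)]),
                                  variant="squared")
    assert norm.values[0] == pytest.approx(1.0)
    norm2 = msda.acceleration_norm(make_recording([(1.0, 1.0, 1.0)]),
                                   variant="squared")
    assert norm2.values[0] == pytest.approx(3.0)


def test_acceleration_norm_respects_gap_mask():
    rec = make_recording([(1, 0, 0)] * 4, gap_mask=[True, False, True, True])
    norm = msda.acceleration_norm(rec)
    assert list(norm.valid) == [True, False, True, True]


# ---------------------------------------------------------------------------
# moving SD
# ---------------------------------------------------------------------------

def brute_force_sd(values, valid, w, ddof, stride=1):
    """Independent loop oracle for the windowed SD."""
    n = len(values)
    out = np.full(n, np.nan)
    for end in range(w - 1, n):
        if (end - (w - 1)) % stride:
            continue
        window_valid = valid[end - w + 1: end + 1]
        if not window_valid.all():
            continue
        out[end] = np.std(values[end - w + 1: end + 1], ddof=ddof)
    return out


def test_moving_sd_constant_is_zero():
    norm = make_norm(np.full(200, 0.73))
    stream = moving_sd(norm, MsdaConfig())
    assert np.all(np.isnan(stream.values[:49]))
    assert np.allclose(stream.values[49:], 0.0, atol=1e-12)


def test_moving_sd_alternating_closed_form():
    # window of 50 alternating +a/-a: mean 0, sample SD = a * sqrt(50/49)
    a = 0.3
    norm = make_norm(a * (-1.0) ** np.arange(150))
    stream = moving_sd(norm, MsdaConfig(sd_denominator="sample"))
    expected = a * np.sqrt(50.0 / 49.0)
    assert np.allclose(stream.values[49:], expected, rtol=1e-12)


def test_moving_sd_sinusoid_population_amplitude():
    # whole periods per 2 s window: population SD ~= A / sqrt(2)
    A, f, fs = 0.4, 1.0, 25.0
    t = np.arange(500) / fs
    norm = make_norm(1.0 + A * np.sin(2 * np.pi * f * t), fs=fs)
    stream = moving_sd(norm, MsdaConfig(sd_denominator="population"))
    got = stream.values[49:]
    assert np.all(np.abs(got - A / np.sqrt(2)) < 0.01 * A / np.sqrt(2))


@pytest.mark.parametrize("ddof_mode, stride", [
    ("sample", 1), ("population", 1), ("sample", 7), ("sample", 50)])
def test_moving_sd_matches_bruteforce(ddof_mode, stride):
    rng = np.random.default_rng(99)
    values = rng.normal(1.0, 0.2, 400)
    valid = rng.random(400) > 0.05
    norm = make_norm(values, valid=valid)
    cfg = MsdaConfig(sd_denominator=ddof_mode, stride_samples=stride)
    got = moving_sd(norm, cfg).values
    want = brute_force_sd(values, valid, 50, 1 if ddof_mode == "sample" else 0,
                          stride)
    assert np.allclose(got, want, atol=1e-10, equal_nan=True)


def test_moving_sd_matches_pandas_rolling():
    # independent cross-check against a well-tested rolling implementation
    import pandas as pd
    rng = np.random.default_rng(7)
    values = rng.lognormal(0.0, 0.5, 3000)
    got = moving_sd(make_norm(values), MsdaConfig()).values
    want = pd.Series(values).rolling(50).std(ddof=1).to_numpy()
    assert np.allclose(got, want, atol=1e-10, equal_nan=True)


@given(hnp.arrays(np.float64, st.integers(60, 200),
                  elements=st.floats(-5, 5, allow_nan=False)),
       st.floats(-100, 100, allow_nan=False))
def test_moving_sd_translation_invariant(values, shift):
    base = moving_sd(make_norm(values), MsdaConfig()).values
    shifted = moving_sd(make_norm(values + shift), MsdaConfig()).values
    assert np.allclose(base, shifted, atol=1e-7, equal_nan=True)


@given(hnp.arrays(np.float64, st.integers(60, 200),
                  elements=st.floats(-5, 5, allow_nan=False)),
       st.floats(0.01, 50, allow_nan=False))
def test_moving_sd_scales_linearly_and_nonnegative(values, c):
    base = moving_sd(make_norm(values), MsdaConfig()).values
    scaled = moving_sd(make_norm(c * values), MsdaConfig()).values
    assert np.nanmin(base) >= 0.0 if np.any(np.isfinite(base)) else True
    # atol scales with c: round-off at the zero-variance floor is ~1e-9 * c
    assert np.allclose(scaled, c * base, rtol=1e-6, atol=1e-8 * max(1.0, c),
                       equal_nan=True)


def test_moving_sd_window_longer_than_series_warns(caplog):
    with caplog.at_level("WARNING"):
        stream = moving_sd(make_norm(np.ones(30)), MsdaConfig())
    assert np.all(np.isnan(stream.values))
    assert "longer than series" in caplog.text


def test_moving_sd_requires_full_valid_window():
    values = np.ones(120)
    valid = np.ones(120, bool)
    valid[60] = False
    stream = moving_sd(make_norm(values, valid=valid), MsdaConfig())
    # every window containing sample 60 is missing
    assert np.all(np.isnan(stream.values[60:110]))
    assert np.isfinite(stream.values[59]) and np.isfinite(stream.values[110])


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def test_window_resolution_at_device_rate():
    assert MsdaConfig().resolve_window_samples(25.0) == 50


def test_window_resolution_other_rates_and_conflicts():
    assert MsdaConfig().resolve_window_samples(50.0) == 100
    assert MsdaConfig(window_samples=50).resolve_window_samples(25.0) == 50
    with pytest.raises(ValueError, match="inconsistent"):
        MsdaConfig(window_samples=40).resolve_window_samples(25.0)
    with pytest.raises(ValueError):
        MsdaConfig(stride_samples=0)
    with pytest.raises(ValueError):
        MsdaConfig(minute_min_valid_fraction=1.5)


# ---------------------------------------------------------------------------
# minute aggregation
# ---------------------------------------------------------------------------

def run_minutes(values, fs=25.0, valid=None, steps=None, start=MIDNIGHT,
                cfg=None):
    norm = make_norm(values, fs=fs, valid=valid, start=start)
    stream = moving_sd(norm, cfg or MsdaConfig())
    return minute_aggregate(stream, steps, cfg or MsdaConfig())


def test_minute_aggregate_constant_signal():
    days = run_minutes(np.ones(3 * 60 * 25))
    assert len(days) == 1
    d = days[0]
    assert d.day_index == 0
    assert d.valid[:3].all() and not d.valid[3:].any()
    assert np.allclose(d.msda[:3], 0.0, atol=1e-12)
    assert np.all(d.steps[:3] == 0.0)
    assert np.all(np.isnan(d.msda[3:]))


def test_minute_validity_boundary_is_inclusive():
    # minute 1 has exactly half its samples valid -> valid at threshold 0.5
    n = 2 * 1500
    valid = np.ones(n, bool)
    valid[1500:2250] = False  # first half of minute 1
    days = run_minutes(np.ones(n), valid=valid)
    assert days[0].valid[1]
    strict = run_minutes(np.ones(n), valid=valid,
                         cfg=MsdaConfig(minute_min_valid_fraction=0.51))
    assert not strict[0].valid[1]
    assert np.isnan(strict[0].msda[1])


def test_minute_aggregate_counts_step_events():
    steps = [5.0, 10.0, 59.9, 60.0, 100.0, 119.99]
    days = run_minutes(np.ones(3 * 1500), steps=steps)
    assert days[0].steps[0] == 3
    assert days[0].steps[1] == 3
    assert days[0].steps[2] == 0


def test_minute_aggregate_spans_midnight():
    start = datetime(2024, 1, 1, 23, 59, 0)
    days = run_minutes(np.ones(2 * 1500), start=start)
    assert [d.day_index for d in days] == [0, 1]
    assert days[0].valid[1439] and days[1].valid[0]
    assert days[0].valid.sum() == 1 and days[1].valid.sum() == 1


def test_minute_aggregate_msda_value_is_window_mean():
    rng = np.random.default_rng(5)
    values = rng.normal(1, 0.1, 1500)
    days = run_minutes(values)
    stream = moving_sd(make_norm(values), MsdaConfig())
    assert days[0].msda[0] == pytest.approx(np.nanmean(stream.values))
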