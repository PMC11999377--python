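"""Configuration, delimited-text formats, and pipeline drivers.

Everything here is plumbing around the library modules: a single structured
run configuration (YAML on disk, CLI overrides), readers/writers for the
text formats, and the drivers that chain
raw recording -> MSDA minute series -> ensemble profile -> subject summary
-> validation report.  Every output file embeds the master seed and a hash
of the configuration in a comment header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ensemble as ens
from . import signal_core as sc
from . import step_detection as sd
from . import synth_cohort as synth

logger = logging.getLogger(__name__)

TIME_FORMAT = "%Y-%m-%dT%H:%M:%S.%f"


@dataclass
class ScenarioConfig:
    """Synthetic-cohort scenario: which profiles, how long, at what rate."""

    scale: float = 1.0
    duration_h: float = 48.0
    sampling_rate_hz: float = 25.0
    start_time: str = synth.DEFAULT_START.strftime(TIME_FORMAT)

    def profiles(self) -> list[synth.SubgroupProfile]:
        return synth.default_profiles(self.scale)

    def subject_kwargs(self) -> dict:
        return {"duration_h": self.duration_h,
                "sampling_rate_hz": self.sampling_rate_hz,
                "start_time": datetime.strptime(self.start_time, TIME_FORMAT)}


@dataclass
class RunConfig:
    """Top-level run configuration with the device defaults baked in."""

    seed: int = 0
    msda: sc.MsdaConfig = field(default_factory=sc.MsdaConfig)
    steps: sd.StepDetectorConfig = field(default_factory=sd.StepDetectorConfig)
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    error_threshold: float = ens.ERROR_THRESHOLD
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs = {}
        if "msda" in d:
            kwargs["msda"] = sc.MsdaConfig(**d.pop("msda"))
        if "steps" in d:
            kwargs["steps"] = sd.StepDetectorConfig(**d.pop("steps"))
        if "scenario" in d:
            kwargs["scenario"] = ScenarioConfig(**d.pop("scenario"))
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# delimited-text formats
# ---------------------------------------------------------------------------

def _header_lines(cfg: RunConfig | None) -> str:
    if cfg is None:
        return ""
    return f"# seed={cfg.seed} config={cfg.config_hash()}\n"


def write_raw_recording(rec: sc.RawRecording, path: str | Path,
                        cfg: RunConfig | None = None) -> None:
    """Write a recording as `timestamp,x,y,z` rows; gap samples are omitted."""
    n = rec.n_samples
    t = (pd.Timestamp(rec.start_time)
         + pd.to_timedelta(np.arange(n) / rec.sampling_rate_hz, unit="s"))
    frame = pd.DataFrame({"timestamp": t, "x": rec.samples[:, 0],
                          "y": rec.samples[:, 1], "z": rec.samples[:, 2]})
    frame = frame[rec.gap_mask]
    with open(path, "w") as fh:
        fh.write(_header_lines(cfg))
        fh.write(f"# subject_id={rec.subject_id} "
                 f"sampling_rate_hz={rec.sampling_rate_hz}\n")
        frame.to_csv(fh, index=False, float_format="%.6f",
                     date_format=TIME_FORMAT)


def read_raw_recording(path: str | Path, subject_id: str | None = None,
                       sampling_rate_hz: float | None = None,
                       max_malformed_fraction: float = 0.05,
                       ) -> sc.RawRecording:
    """Read a `timestamp,x,y,z` file back onto a uniform sample grid.

    Absent rows become invalid (gap) samples.  Malformed rows are skipped
    with a logged count; more than ``max_malformed_fraction`` of them is an
    error.  Metadata comment lines (`# key=value`) supply subject id and
    sampling rate unless overridden.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
    fs = sampling_rate_hz or float(meta.get("sampling_rate_hz", 25.0))
    sid = subject_id or meta.get("subject_id", path.stem)

    raw = pd.read_csv(path, comment="#", dtype=str)
    for col in ("timestamp", "x", "y", "z"):
        if col not in raw.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    ts = pd.to_datetime(raw["timestamp"], format="ISO8601", errors="coerce")
    xyz = raw[["x", "y", "z"]].apply(pd.to_numeric, errors="coerce")
    ok = ts.notna().to_numpy() & xyz.notna().all(axis=1).to_numpy()
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s: skipped %d malformed rows", path, n_bad)
        if n_bad > max_malformed_fraction * len(raw):
            raise ValueError(f"{path}: {n_bad}/{len(raw)} malformed rows")
    ts, xyz = ts[ok], xyz[ok]
    if len(ts) == 0:
        raise ValueError(f"{path}: no parseable samples")

    t0 = ts.iloc[0]
    idx = np.round((ts - t0).dt.total_seconds().to_numpy() * fs).astype(np.int64)
    n = int(idx[-1]) + 1
    samples = np.zeros((n, 3))
    gap_mask = np.zeros(n, dtype=bool)
    samples[idx] = xyz.to_numpy(float)
    gap_mask[idx] = True
    return sc.RawRecording(subject_id=sid, start_time=t0.to_pydatetime(),
                           samples=samples, sampling_rate_hz=fs,
                           gap_mask=gap_mask)


def write_minute_series(days: list[sc.MinuteSeries], path: str | Path,
                        cfg: RunConfig | None = None) -> None:
    """Write per-day minute series as `day,minute,msda,steps,valid`."""
    rows = []
    for d in days:
        rows.append(pd.DataFrame({
            "day": d.day_index, "minute": np.arange(sc.MINUTES_PER_DAY),
            "msda": d.msda, "steps": d.steps, "valid": d.valid.astype(int)}))
    with open(path, "w") as fh:
        fh.write(_header_lines(cfg))
        pd.concat(rows).to_csv(fh, index=False, float_format="%.8g")


def read_minute_series(path: str | Path) -> list[sc.MinuteSeries]:
    frame = pd.read_csv(path, comment="#")
    days = []
    for day, sub in frame.groupby("day"):
        msda = np.full(sc.MINUTES_PER_DAY, np.nan)
        steps = np.full(sc.MINUTES_PER_DAY, np.nan)
        valid = np.zeros(sc.MINUTES_PER_DAY, dtype=bool)
        m = sub.minute.to_numpy(int)
        msda[m] = sub.msda.to_numpy(float)
        steps[m] = sub.steps.to_numpy(float)
        valid[m] = sub.valid.to_numpy(int).astype(bool)
        days.append(sc.MinuteSeries(int(day), msda, steps, valid))
    return days


def write_profile(profile: ens.EnsembleProfile, path: str | Path,
                  cfg: RunConfig | None = None) -> None:
    """Write an ensemble profile as `minute,msda,steps,n_days`."""
    frame = pd.DataFrame({"minute": np.arange(sc.MINUTES_PER_DAY),
                          "msda": profile.msda, "steps": profile.steps,
                          "n_days": profile.n_days})
    with open(path, "w") as fh:
        fh.write(_header_lines(cfg))
        frame.to_csv(fh, index=False, float_format="%.8g")


def write_step_events(events: sd.StepEvents, path: str | Path,
                      cfg: RunConfig | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(cfg))
        pd.DataFrame({"time_s": events.times}).to_csv(
            fh, index=False, float_format="%.3f")


def write_summaries(frame: pd.DataFrame, path: str | Path,
                    cfg: RunConfig | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(cfg))
        frame.to_csv(fh, index=False, float_format="%.8g")


def read_summaries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# pipeline drivers
# ---------------------------------------------------------------------------

def process_recording(rec: sc.RawRecording,
                      msda_cfg: sc.MsdaConfig | None = None,
                      step_cfg: sd.StepDetectorConfig | None = None,
                      ) -> tuple[list[sc.MinuteSeries], sd.StepEvents]:
    """Raw recording -> per-day minute series (plus the detected steps)."""
    msda_cfg = msda_cfg or sc.MsdaConfig()
    norm = sc.acceleration_norm(rec, variant=msda_cfg.norm_variant)
    stream = sc.moving_sd(norm, msda_cfg)
    events = sd.detect_steps(norm, step_cfg)
    days = sc.minute_aggregate(stream, events.times, msda_cfg)
    return days, events


def summarize_subject(rec: sc.RawRecording, mobility_mode: str,
                      fim_mobility: int,
                      msda_cfg: sc.MsdaConfig | None = None,
                      step_cfg: sd.StepDetectorConfig | None = None,
                      error_threshold: float = ens.ERROR_THRESHOLD,
                      ) -> ens.SubjectSummary | None:
    """Full per-subject pipeline; None when the error-exclusion rule fires."""
    days, _ = process_recording(rec, msda_cfg, step_cfg)
    profile = ens.ensemble_average(days)
    if not ens.apply_error_exclusion(profile, error_threshold):
        logger.info("%s excluded: error fraction %.3f >= %.3f",
                    rec.subject_id, profile.error_fraction, error_threshold)
        return None
    daily_msda, daily_steps = ens.daily_summary(profile)
    return ens.SubjectSummary(subject_id=rec.subject_id, daily_msda=daily_msda,
                              daily_steps=daily_steps,
                              mobility_mode=mobility_mode,
                              fim_mobility=fim_mobility)


def run_cohort(profiles=None, seed: int = 0,
               msda_cfg: sc.MsdaConfig | None = None,
               step_cfg: sd.StepDetectorConfig | None = None,
               error_threshold: float = ens.ERROR_THRESHOLD,
               collect_truth: bool = False,
               **subject_kwargs) -> pd.DataFrame:
    """Simulate a cohort and push every subject through the pipeline.

    Returns the subject-summary table; excluded subjects are dropped (and
    logged).  With ``collect_truth`` the table gains ground-truth columns
    (true step count, activity factor) for calibration checks.
    """
    cohort = synth.generate_cohort(profiles, seed, **subject_kwargs)
    rows = []
    for meta, rec, truth in cohort.iter_subjects():
        summary = summarize_subject(rec, meta.mobility_mode,
                                    int(meta.fim_mobility),
                                    msda_cfg, step_cfg, error_threshold)
        if summary is None:
            continue
        row = {"subject_id": summary.subject_id,
               "daily_msda": summary.daily_msda,
               "daily_steps": summary.daily_steps,
               "mobility_mode": summary.mobility_mode,
               "fim_mobility": summary.fim_mobility,
               "subgroup": summary.subgroup}
        if collect_truth:
            row["true_steps"] = len(truth.step_times)
            row["activity_factor"] = truth.activity_factor
        rows.append(row)
    return pd.DataFrame(rows)


def pooled_cohort_summaries(n_seeds: int = 10, scale: float = 0.2,
                            seed: int = 0, **kwargs) -> pd.DataFrame:
    """Summaries pooled over several cohort replicates (distinct seeds)."""
    frames = []
    for i in range(n_seeds):
        f = run_cohort(synth.default_profiles(scale), seed=seed + i, **kwargs)
        f = f.assign(cohort_seed=seed + i,
                     subject_id=[f"c{i}_{s}" for s in f.subject_id])
        frames.append(f)
    return pd.concat(frames, ignore_index=True)
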