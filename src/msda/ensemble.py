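"""24-hour ensemble averaging, error exclusion, and per-subject summaries.

Multi-day recordings (the measurement protocol uses 48 h) are fused into a
single 1440-slot diurnal profile: measurements recorded at the same minute of
the day are averaged together.  Subjects whose fused profile still has >= 5%
of slots with no data ("measurement error") are excluded from analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .signal_core import MINUTES_PER_DAY, MinuteSeries

logger = logging.getLogger(__name__)

#: the six mobility subgroups, ordered by increasing functional independence
SUBGROUP_ORDER = ("FIM1-4", "FIM5-WC", "FIM5-walk", "FIM6-WC", "FIM6-walk", "FIM7")

#: default exclusion threshold: >= 5% empty slots after ensemble averaging
ERROR_THRESHOLD = 0.05


def subgroup_label(fim_mobility: int, mobility_mode: str) -> str:
    """Map (FIM-mobility item score, walking/wheelchair) to the subgroup label.

    FIM mobility 1-4 forms a single (wheelchair) group; levels 5 and 6 are
    split by mobility mode; level 7 implies independent walking.
    """
    if not 1 <= fim_mobility <= 7:
        raise ValueError("FIM mobility score must be in 1..7")
    if mobility_mode not in ("walking", "wheelchair"):
        raise ValueError("mobility_mode must be 'walking' or 'wheelchair'")
    if fim_mobility <= 4:
        return "FIM1-4"
    if fim_mobility == 7:
        if mobility_mode != "walking":
            raise ValueError("FIM mobility 7 implies walking")
        return "FIM7"
    mode = "walk" if mobility_mode == "walking" else "WC"
    return f"FIM{fim_mobility}-{mode}"


@dataclass
class EnsembleProfile:
    """1440-slot ensemble-averaged diurnal profile with per-slot coverage."""

    msda: np.ndarray
    steps: np.ndarray
    n_days: np.ndarray

    def __post_init__(self) -> None:
        for name in ("msda", "steps", "n_days"):
            if np.asarray(getattr(self, name)).shape != (MINUTES_PER_DAY,):
                raise ValueError(f"{name} must have {MINUTES_PER_DAY} slots")
        self.msda = np.asarray(self.msda, dtype=float)
        self.steps = np.asarray(self.steps, dtype=float)
        self.n_days = np.asarray(self.n_days, dtype=int)

    @property
    def error_fraction(self) -> float:
        """Fraction of slots to which no day contributed."""
        return float(np.count_nonzero(self.n_days == 0)) / MINUTES_PER_DAY


@dataclass
class SubjectSummary:
    """One analysis row per subject: daily MSDA, daily steps, mobility strata."""

    subject_id: str
    daily_msda: float
    daily_steps: float
    mobility_mode: str
    fim_mobility: int
    subgroup: str = field(default="")

    def __post_init__(self) -> None:
        expected = subgroup_label(self.fim_mobility, self.mobility_mode)
        if not self.subgroup:
            self.subgroup = expected
        elif self.subgroup != expected:
            raise ValueError(
                f"subgroup {self.subgroup!r} inconsistent with FIM "
                f"{self.fim_mobility} / {self.mobility_mode}")


def ensemble_average(days: Sequence[MinuteSeries]) -> EnsembleProfile:
    """Average minute series slot-wise across days.

    Per slot, the mean over the days with valid data there; a slot with no
    contributing day stays missing.  MSDA and step channels are handled
    identically (the single validity flag governs both).
    """
    if len(days) == 0:
        raise ValueError("ensemble_average requires at least one day")
    valid = np.stack([d.valid for d in days])
    msda = np.stack([d.msda for d in days])
    steps = np.stack([d.steps for d in days])
    n_days = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        msda_avg = np.where(n_days > 0,
                            np.nansum(np.where(valid, msda, 0.0), axis=0)
                            / np.maximum(n_days, 1), np.nan)
        steps_avg = np.where(n_days > 0,
                             np.nansum(np.where(valid, steps, 0.0), axis=0)
                             / np.maximum(n_days, 1), np.nan)
    return EnsembleProfile(msda=msda_avg, steps=steps_avg, n_days=n_days)


def apply_error_exclusion(profile: EnsembleProfile,
                          threshold: float = ERROR_THRESHOLD) -> bool:
    """Whether a profile is retained for analysis.

    Profiles with a measurement-error fraction at or above the threshold
    (default 5% of slots empty after ensemble averaging) are excluded, i.e.
    exactly 72 empty slots of 1440 is already out.
    """
    return profile.error_fraction < threshold


def daily_summary(profile: EnsembleProfile) -> tuple[float, float]:
    """(daily MSDA, daily steps) from a retained ensemble profile.

    Daily MSDA is the mean over contributing slots.  Daily steps is the slot
    sum rescaled by 1440 / #contributing slots, so short gaps do not deflate
    the count; a gap-free profile reduces to the plain sum.
    """
    contributing = profile.n_days > 0
    n = int(np.count_nonzero(contributing))
    if n == 0:
        raise ValueError("profile has no contributing slots")
    daily_msda = float(np.mean(profile.msda[contributing]))
    daily_steps = float(np.sum(profile.steps[contributing]) * MINUTES_PER_DAY / n)
    return daily_msda, daily_steps


def summaries_to_frame(summaries: Iterable[SubjectSummary]) -> pd.DataFrame:
    """Stack subject summaries into the analysis table."""
    rows = [{"subject_id": s.subject_id, "daily_msda": s.daily_msda,
             "daily_steps": s.daily_steps, "mobility_mode": s.mobility_mode,
             "fim_mobility": s.fim_mobility, "subgroup": s.subgroup}
            for s in summaries]
    return pd.DataFrame(rows, columns=["subject_id", "daily_msda", "daily_steps",
                                       "mobility_mode", "fim_mobility", "subgroup"])
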