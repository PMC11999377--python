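"""Nonparametric validation battery for MSDA vs step count.

Reproduces the study-style analysis on a subject-summary table: Spearman rank
correlations (overall and per mobility stratum, with and without zero-step
subjects), distribution diagnostics (Fisher-Pearson skewness g1, Fisher
kurtosis g2, Shapiro-Wilk normality), Kruskal-Wallis omnibus comparison
across the six FIM-mobility subgroups with Bonferroni-corrected pairwise
Mann-Whitney tests, and the step-count floor effect (fraction of exact
zeros).

g1 and g2 use plain-n central moments: g1 = m3 / m2^1.5, g2 = m4 / m2².
g2 is *not* excess kurtosis — a normal distribution has g2 = 3 and g1 = 0.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble import SUBGROUP_ORDER

logger = logging.getLogger(__name__)

ALPHA = 0.05


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN (with a warning) when either variable is constant, where the
    coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant input: Spearman correlation undefined")
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def _central_moments(sample, orders=(2, 3, 4)) -> tuple[int, dict[int, float]]:
    a = np.asarray(sample, dtype=float)
    if a.ndim != 1 or len(a) < 3:
        raise ValueError("need a 1-D sample with n >= 3")
    d = a - a.mean()
    return len(a), {k: float(np.mean(d ** k)) for k in orders}


def skewness_g1(sample) -> float:
    """Fisher-Pearson skewness g1 = m3 / m2^(3/2) (biased moments, n denominators)."""
    _, m = _central_moments(sample)
    if m[2] == 0:
        raise ValueError("zero variance: skewness undefined")
    return m[3] / m[2] ** 1.5


def kurtosis_g2(sample) -> float:
    """Fisher kurtosis g2 = m4 / m2² (non-excess; normal reference is 3)."""
    _, m = _central_moments(sample)
    if m[2] == 0:
        raise ValueError("zero variance: kurtosis undefined")
    return m[4] / m[2] ** 2


def normality_test(sample) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value; defined for 3 <= n <= 5000."""
    a = np.asarray(sample, dtype=float)
    if not 3 <= len(a) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.shapiro(a)
    return float(res.statistic), float(res.pvalue)


def floor_effect(sample) -> float:
    """Percentage of exactly-zero values, to one decimal (e.g. 20/197 -> 10.2)."""
    a = np.asarray(sample, dtype=float)
    if len(a) == 0:
        raise ValueError("need at least one value")
    return round(100.0 * float(np.count_nonzero(a == 0.0)) / len(a), 1)


# ---------------------------------------------------------------------------
# composite results
# ---------------------------------------------------------------------------

@dataclass
class DistributionDiagnostics:
    n: int
    skewness_g1: float
    kurtosis_g2: float
    normality_p: float
    zero_fraction: float  # as a fraction in [0, 1]

    @classmethod
    def from_sample(cls, sample) -> "DistributionDiagnostics":
        a = np.asarray(sample, dtype=float)
        return cls(n=len(a), skewness_g1=skewness_g1(a), kurtosis_g2=kurtosis_g2(a),
                   normality_p=normality_test(a)[1],
                   zero_fraction=float(np.count_nonzero(a == 0.0)) / len(a))


@dataclass
class SubgroupComparison:
    """Kruskal-Wallis omnibus plus Bonferroni-corrected pairwise results."""

    channel: str
    h_statistic: float
    p_value: float
    medians: dict[str, float]
    pairwise: pd.DataFrame  # columns: group1, group2, u_statistic, p_raw, p_adj


def subgroup_comparison(summaries: pd.DataFrame, channel: str
                        ) -> SubgroupComparison:
    """Compare a channel ('msda' or 'steps') across the mobility subgroups.

    Kruskal-Wallis across all usable subgroups, then two-sample Mann-Whitney U
    for every pair with Bonferroni-multiplied p-values (capped at 1).
    Subgroups with fewer than 2 subjects are excluded with a warning.
    """
    col = {"msda": "daily_msda", "steps": "daily_steps"}[channel]
    groups: dict[str, np.ndarray] = {}
    for label in SUBGROUP_ORDER:
        vals = summaries.loc[summaries.subgroup == label, col].to_numpy(float)
        if len(vals) < 2:
            if len(vals):
                logger.warning("subgroup %s has <2 subjects; excluded", label)
            continue
        groups[label] = vals
    if len(groups) < 2:
        raise ValueError("need >= 2 subgroups with >= 2 subjects each")

    h, p = stats.kruskal(*groups.values())
    medians = {k: float(np.median(v)) for k, v in groups.items()}

    pairs = list(itertools.combinations(groups, 2))
    m = len(pairs)
    rows = []
    for g1, g2 in pairs:
        u, praw = stats.mannwhitneyu(groups[g1], groups[g2],
                                     alternative="two-sided")
        rows.append({"group1": g1, "group2": g2, "u_statistic": float(u),
                     "p_raw": float(praw), "p_adj": min(1.0, float(praw) * m)})
    return SubgroupComparison(channel=channel, h_statistic=float(h),
                              p_value=float(p), medians=medians,
                              pairwise=pd.DataFrame(rows))


@dataclass
class ValidationReport:
    """Full validation battery for one subject-summary table."""

    n_subjects: int
    correlations: dict[str, dict[str, float]]
    diagnostics: dict[str, dict[str, DistributionDiagnostics]]
    comparisons: dict[str, SubgroupComparison]
    floor_effect_pct: float
    schema_version: str = "1"
    meta: dict = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        def enc(o):
            if isinstance(o, DistributionDiagnostics):
                return o.__dict__
            if isinstance(o, SubgroupComparison):
                d = o.__dict__.copy()
                d["pairwise"] = o.pairwise.to_dict(orient="records")
                return d
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o).__name__)
        payload = {"schema_version": self.schema_version,
                   "n_subjects": self.n_subjects,
                   "correlations": self.correlations,
                   "diagnostics": self.diagnostics,
                   "comparisons": self.comparisons,
                   "floor_effect_pct": self.floor_effect_pct,
                   "meta": self.meta}
        return json.dumps(payload, default=enc, indent=indent, allow_nan=True)

    def to_text(self) -> str:
        """Human-readable summary with a per-subgroup diagnostics table."""
        lines = [f"Validation report (n={self.n_subjects})", ""]
        lines.append("Spearman correlations, MSDA vs steps:")
        for stratum, d in self.correlations.items():
            parts = [f"{k}={v:.3f}" if np.isfinite(v) else f"{k}=NA"
                     for k, v in d.items()]
            lines.append(f"  {stratum:12s} " + "  ".join(parts))
        lines.append("")
        lines.append(f"Step-count floor effect: {self.floor_effect_pct}% of "
                     "subjects with zero steps")
        lines.append("")
        header = (f"{'subgroup':12s} {'n':>4s} "
                  f"{'g2 MSDA':>8s} {'g1 MSDA':>8s} {'p(SW)':>7s} "
                  f"{'g2 steps':>9s} {'g1 steps':>9s} {'p(SW)':>7s}")
        lines.append("Distribution diagnostics per subgroup:")
        lines.append(header)
        for label in self.diagnostics.get("msda", {}):
            dm = self.diagnostics["msda"][label]
            ds = self.diagnostics["steps"][label]
            lines.append(f"{label:12s} {dm.n:4d} "
                         f"{dm.kurtosis_g2:8.2f} {dm.skewness_g1:8.2f} "
                         f"{dm.normality_p:7.3f} "
                         f"{ds.kurtosis_g2:9.2f} {ds.skewness_g1:9.2f} "
                         f"{ds.normality_p:7.3f}")
        lines.append("")
        for channel, comp in self.comparisons.items():
            lines.append(f"Kruskal-Wallis ({channel}): H={comp.h_statistic:.2f}, "
                         f"p={comp.p_value:.3g}")
            lines.append("  medians: " + "  ".join(
                f"{k}={v:.4g}" for k, v in comp.medians.items()))
            sig = comp.pairwise[comp.pairwise.p_adj < ALPHA]
            lines.append(f"  pairwise (Bonferroni): {len(sig)}/{len(comp.pairwise)}"
                         f" significant at alpha={ALPHA}")
        return "\n".join(lines)


def _correlation_block(frame: pd.DataFrame) -> dict[str, float]:
    out: dict[str, float] = {}
    if len(frame) < 3:
        logger.warning("stratum with <3 subjects; correlation omitted")
        out["rho"] = float("nan")
        out["rho_excl_zero_steps"] = float("nan")
        return out
    out["rho"] = spearman_rho(frame.daily_msda, frame.daily_steps)
    nz = frame[frame.daily_steps > 0]
    if len(nz) >= 3:
        out["rho_excl_zero_steps"] = spearman_rho(nz.daily_msda, nz.daily_steps)
    else:
        logger.warning("fewer than 3 nonzero-step subjects; "
                       "zero-excluded correlation omitted")
        out["rho_excl_zero_steps"] = float("nan")
    return out


def build_report(summaries: pd.DataFrame, meta: dict | None = None
                 ) -> ValidationReport:
    """Assemble the full validation battery from a subject-summary table.

    Expects columns subject_id, daily_msda, daily_steps, mobility_mode,
    subgroup.  Correlations are computed for all subjects and separately for
    the walking and wheelchair strata, each also with zero-step subjects
    excluded (the floor-effect sensitivity variant).
    """
    required = {"subject_id", "daily_msda", "daily_steps", "mobility_mode",
                "subgroup"}
    missing = required - set(summaries.columns)
    if missing:
        raise ValueError(f"summary table missing columns: {sorted(missing)}")
    if len(summaries) == 0:
        raise ValueError("empty summary table")

    correlations = {
        "all": _correlation_block(summaries),
        "walking": _correlation_block(summaries[summaries.mobility_mode == "walking"]),
        "wheelchair": _correlation_block(
            summaries[summaries.mobility_mode == "wheelchair"]),
    }

    diagnostics: dict[str, dict[str, DistributionDiagnostics]] = {
        "msda": {}, "steps": {}}
    for label in SUBGROUP_ORDER:
        sub = summaries[summaries.subgroup == label]
        if len(sub) < 3:
            continue
        try:
            diagnostics["msda"][label] = DistributionDiagnostics.from_sample(
                sub.daily_msda)
            diagnostics["steps"][label] = DistributionDiagnostics.from_sample(
                sub.daily_steps)
        except ValueError as exc:  # degenerate subgroup (e.g. zero variance)
            logger.warning("diagnostics skipped for %s: %s", label, exc)

    comparisons = {}
    if summaries.subgroup.nunique() >= 2:
        for channel in ("msda", "steps"):
            try:
                comparisons[channel] = subgroup_comparison(summaries, channel)
            except ValueError as exc:
                logger.warning("subgroup comparison (%s) skipped: %s",
                               channel, exc)

    return ValidationReport(
        n_subjects=len(summaries),
        correlations=correlations,
        diagnostics=diagnostics,
        comparisons=comparisons,
        floor_effect_pct=floor_effect(summaries.daily_steps),
        meta=meta or {},
    )
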