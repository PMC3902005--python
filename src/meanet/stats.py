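"""Longitudinal batch statistics: averaging over days in vitro and ANOVA.

Cultures dissociated from the same tissue ("batch") are averaged per day
with standard errors; one-way fixed-effects ANOVA quantifies metric
variability within and across batches, and a Tukey-Kramer multiple
comparison contrasts the observation-window durations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "AnovaResult",
    "batch_average",
    "anova_one_way",
    "batch_variability_tests",
    "window_comparison",
]


@dataclass
class AnovaResult:
    """One-way ANOVA outcome, optionally with pairwise multiple comparison.

    ``comparisons`` (when present) has one row per group pair with the mean
    difference, its 95% confidence interval and a ``significant`` flag
    (interval excludes zero, the CI-overlap convention).
    """

    design: str
    group_labels: list
    group_sizes: list[int]
    group_means: list[float]
    f_stat: float
    p_value: float
    comparisons: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0) or self.f_stat < 0:
            raise ValueError("invalid ANOVA result")


def anova_one_way(groups: dict[str, np.ndarray], design: str = "one-way") -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    Requires at least two groups with at least two observations each.  The
    degenerate all-values-identical case (zero between- and within-group
    variance) is reported as F = 0, p = 1.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(arrays) < 2:
        raise ValueError("one-way ANOVA needs at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least two observations")
    allv = np.concatenate(arrays)
    if np.ptp(allv) == 0:
        f, p = 0.0, 1.0
    else:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p = sps.f_oneway(*arrays)
        if not np.isfinite(f):  # zero within-group variance, nonzero between
            f, p = float("inf"), 0.0
    return AnovaResult(
        design=design,
        group_labels=labels,
        group_sizes=[len(a) for a in arrays],
        group_means=[float(a.mean()) for a in arrays],
        f_stat=float(f),
        p_value=float(p),
    )


def batch_average(metrics: pd.DataFrame, manifest=None) -> pd.DataFrame:
    """Per-batch daily means and standard errors of each metric.

    One row per (batch, window, metric, day) between the batch's first and
    last recorded day; days without recordings appear as gap rows
    (``recorded_flag`` False, no fabricated values).  SE = sd/sqrt(n) over
    the cultures contributing that day; 0 for a single culture.
    """
    rows = []
    metrics = metrics.dropna(subset=["value"])
    for (batch, window, metric), grp in metrics.groupby(["batch_id", "window_ms", "metric_name"]):
        days = grp["day_in_vitro"]
        for day in range(int(days.min()), int(days.max()) + 1):
            sub = grp.loc[days == day, "value"]
            base = {
                "batch_id": batch,
                "window_ms": window,
                "metric_name": metric,
                "day_in_vitro": day,
            }
            if len(sub) == 0:
                rows.append({**base, "mean": np.nan, "standard_error": np.nan, "n": 0, "recorded_flag": False})
            else:
                se = float(sub.std(ddof=1) / np.sqrt(len(sub))) if len(sub) > 1 else 0.0
                rows.append(
                    {**base, "mean": float(sub.mean()), "standard_error": se, "n": len(sub), "recorded_flag": True}
                )
    out = pd.DataFrame(rows)
    if manifest is not None:
        dens = manifest.cultures[["batch_id", "density_class"]].drop_duplicates("batch_id")
        out = out.merge(dens, on="batch_id", how="left")
    return out


def _metric_frame(metrics: pd.DataFrame, metric_name: str, window_ms: Optional[float]) -> pd.DataFrame:
    df = metrics[metrics["metric_name"] == metric_name].dropna(subset=["value"])
    if window_ms is not None:
        df = df[df["window_ms"] == window_ms]
    if df.empty:
        raise ValueError(f"no observations for metric {metric_name!r}")
    return df


def batch_variability_tests(
    metrics: pd.DataFrame,
    metric_name: str = "mean_connection_length_um",
    window_ms: Optional[float] = None,
) -> dict:
    """Metric variability within and across batches.

    ACROSS design: one observation per culture (its time-averaged metric),
    factor = batch.  WITHIN design: per batch, observations are the
    per-day values, factor = culture; one result per batch.  Returns
    ``{"across": AnovaResult, "within": {batch_id: AnovaResult}}``.
    """
    df = _metric_frame(metrics, metric_name, window_ms)
    per_culture = df.groupby(["batch_id", "culture_id"])["value"].mean().reset_index()
    across_groups = {
        str(b): g["value"].to_numpy() for b, g in per_culture.groupby("batch_id")
    }
    if len(across_groups) < 2:
        raise ValueError("across-batch ANOVA needs at least two batches")
    across = anova_one_way(across_groups, design=f"across-batch ({metric_name})")

    within: dict[str, AnovaResult] = {}
    for b, g in df.groupby("batch_id"):
        groups = {str(c): s["value"].to_numpy() for c, s in g.groupby("culture_id")}
        groups = {c: v for c, v in groups.items() if len(v) >= 2}
        if len(groups) >= 2:
            within[str(b)] = anova_one_way(groups, design=f"within-batch {b} ({metric_name})")
    return {"across": across, "within": within}


def window_comparison(
    metrics: pd.DataFrame,
    batch_id: str,
    metric_name: str = "mean_connection_length_um",
    alpha: float = 0.05,
) -> AnovaResult:
    """One-way ANOVA across observation windows for one batch, followed by a
    Tukey-Kramer pairwise comparison at 95% confidence.

    Observations are the batch's per-day mean metric values in each window.
    A pair of windows is flagged different when the Tukey interval for their
    mean difference excludes zero.
    """
    df = _metric_frame(metrics, metric_name, None)
    df = df[df["batch_id"] == batch_id]
    if df.empty:
        raise ValueError(f"no observations for batch {batch_id!r}")
    daily = df.groupby(["window_ms", "day_in_vitro"])["value"].mean().reset_index()
    groups = {f"{w:g}ms": g["value"].to_numpy() for w, g in daily.groupby("window_ms")}
    if len(groups) < 2:
        raise ValueError("window comparison needs at least two windows")
    result = anova_one_way(groups, design=f"window comparison, batch {batch_id} ({metric_name})")

    endog = np.concatenate([groups[g] for g in groups])
    labels = np.concatenate([[g] * len(groups[g]) for g in groups])
    if np.ptp(endog) == 0:  # Tukey is degenerate on constant data
        pairs = [(a, b) for i, a in enumerate(groups) for b in list(groups)[i + 1 :]]
        comp = pd.DataFrame(
            {
                "group1": [a for a, _ in pairs],
                "group2": [b for _, b in pairs],
                "mean_diff": 0.0,
                "ci_lower": 0.0,
                "ci_upper": 0.0,
                "significant": False,
            }
        )
    else:
        tk = pairwise_tukeyhsd(endog, labels, alpha=alpha)
        frame = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        comp = pd.DataFrame(
            {
                "group1": frame["group1"].astype(str),
                "group2": frame["group2"].astype(str),
                "mean_diff": tk.meandiffs,
                "ci_lower": tk.confint[:, 0],
                "ci_upper": tk.confint[:, 1],
                "significant": tk.reject,
            }
        )
    result.comparisons = comp
    return result
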