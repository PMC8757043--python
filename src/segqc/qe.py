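"""Robust outlier thresholds, alarm flags, and per-case risk scores.

The quality-estimation procedure: for each (algorithm, class, metric) series
across the cohort, a robust threshold is derived as

    threshold = median - MAD * alpha

over the *oriented* metric values (metrics where lower is better, such as
Hausdorff distance, enter as their additive inverse so that "below threshold"
uniformly means "suspiciously poor agreement with the fusion").  MAD is the
unscaled median absolute deviation — no 1.4826 normal-consistency factor,
since any scaling is absorbed by the tunable alpha.  A cell raises an alarm
flag when its oriented value falls strictly below the threshold, or when it
is NaN or infinite.  Per case, the flags accumulate into a risk score used
to rank cases for human review.

Alpha tunes sensitivity: alpha = 0 puts the threshold at the median (about
half the cells of each series alarm), larger alpha flags only stronger
outliers.  Alpha can be set globally or overridden per (source, class,
metric).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import METRIC_ORIENTATION, MetricTable

__all__ = [
    "AlphaConfig",
    "DegenerateCohortError",
    "robust_threshold",
    "orient",
    "orient_value",
    "compute_thresholds",
    "raise_alarms",
    "risk_scores",
    "rank_cases",
]


class DegenerateCohortError(ValueError):
    """A metric series has fewer than 2 finite values — no robust spread."""


@dataclass(frozen=True)
class AlphaConfig:
    """Alpha resolution: a global default plus optional overrides.

    Overrides are keyed by (source_id, class_name, metric); ``None`` in a key
    slot is a wildcard, and the most specific matching override wins (ties in
    specificity resolve source > class > metric).
    """

    alpha: float = 0.1
    overrides: Mapping[tuple[str | None, str | None, str | None], float] = field(
        default_factory=dict
    )

    def resolve(self, source_id: str, class_name: str, metric: str) -> float:
        best, best_score = None, -1
        for (src, cls, met), a in self.overrides.items():
            if src not in (None, source_id):
                continue
            if cls not in (None, class_name):
                continue
            if met not in (None, metric):
                continue
            score = (src is not None) * 4 + (cls is not None) * 2 + (met is not None)
            if score > best_score:
                best, best_score = a, score
        return self.alpha if best is None else float(best)


def robust_threshold(
    values: Sequence[float], alpha: float
) -> tuple[float, float, float]:
    """(threshold, median, mad) of one oriented metric series.

    NaN and infinite values are excluded from the estimation — they always
    alarm on their own, and letting a single empty prediction drag the median
    down would poison the threshold for everyone else.  At least 2 finite
    values must remain, otherwise the cohort is degenerate for this series.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 2:
        raise DegenerateCohortError(
            f"need >= 2 finite values to estimate a robust threshold, "
            f"got {finite.size}"
        )
    med = float(np.median(finite))
    mad = float(np.median(np.abs(finite - med)))
    return med - mad * alpha, med, mad


def orient_value(value: float, metric: str) -> float:
    """Orient one metric value so that higher is uniformly better."""
    if METRIC_ORIENTATION.get(metric, "higher_better") == "lower_better":
        return -value  # +inf becomes -inf; NaN stays NaN
    return value


def orient(values: Sequence[float], metric: str) -> np.ndarray:
    """Vectorized :func:`orient_value`."""
    arr = np.asarray(values, dtype=float)
    if METRIC_ORIENTATION.get(metric, "higher_better") == "lower_better":
        return -arr
    return arr


def compute_thresholds(table: MetricTable, alpha: AlphaConfig | float) -> pd.DataFrame:
    """Per-(source, class, metric) thresholds across the cohort.

    Returns a frame with columns source_id, class_name, metric, alpha,
    median, mad, threshold (all in oriented units) and threshold_natural
    (back on the metric's native scale, e.g. a positive upper bound for
    Hausdorff distance, matching how such thresholds are usually reported).
    """
    if not isinstance(alpha, AlphaConfig):
        alpha = AlphaConfig(alpha=float(alpha))
    rows = []
    for (src, cls, met), grp in table.values.groupby(
        ["source_id", "class_name", "metric"], sort=True
    ):
        a = alpha.resolve(src, cls, met)
        oriented = orient(grp["value"].to_numpy(), met)
        thr, med, mad = robust_threshold(oriented, a)
        rows.append(
            {
                "source_id": src,
                "class_name": cls,
                "metric": met,
                "alpha": a,
                "median": med,
                "mad": mad,
                "threshold": thr,
                "threshold_natural": orient_value(thr, met),
            }
        )
    return pd.DataFrame(rows)


def raise_alarms(table: MetricTable, thresholds: pd.DataFrame) -> pd.DataFrame:
    """Flag every table cell against its threshold.

    A cell alarms when its oriented value is strictly below the threshold
    ("below" read strictly: equality does not alarm) or is NaN/-inf.
    Returns the tidy flag frame with columns case_id, source_id, class_name,
    metric, value, threshold, flag.
    """
    df = table.values.merge(
        thresholds[["source_id", "class_name", "metric", "threshold"]],
        on=["source_id", "class_name", "metric"],
        how="left",
        validate="many_to_one",
    )
    if df["threshold"].isna().any():
        missing = df.loc[
            df["threshold"].isna(), ["source_id", "class_name", "metric"]
        ].drop_duplicates()
        raise ValueError(f"thresholds missing for cells:\n{missing}")
    oriented = np.array(
        [orient_value(v, m) for v, m in zip(df["value"], df["metric"])]
    )
    df["flag"] = np.isnan(oriented) | (oriented == -np.inf) | (
        oriented < df["threshold"].to_numpy()
    )
    return df[
        ["case_id", "source_id", "class_name", "metric", "value", "threshold", "flag"]
    ]


def risk_scores(alarms: pd.DataFrame) -> pd.DataFrame:
    """Per-case risk score (total flag count) with per-metric subtotals."""
    total = alarms.groupby("case_id", sort=True)["flag"].sum().astype(int)
    out = total.rename("risk_score").reset_index()
    for met in sorted(alarms["metric"].unique()):
        sub = (
            alarms[alarms["metric"] == met]
            .groupby("case_id", sort=True)["flag"]
            .sum()
            .astype(int)
        )
        out[f"{met}_flags"] = out["case_id"].map(sub).fillna(0).astype(int)
    return out


def rank_cases(scores: pd.DataFrame) -> list[str]:
    """Triage order: descending risk score, ties by case_id (stable)."""
    ordered = scores.sort_values(
        ["risk_score", "case_id"], ascending=[False, True], kind="mergesort"
    )
    return ordered["case_id"].tolist()
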