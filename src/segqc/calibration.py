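"""Alpha calibration: sweep the sensitivity parameter and characterize it.

For each alpha on a grid, thresholds and alarms are recomputed over a fixed
metric table and summarized as (a) the alarm-count histogram over the cohort
and its Shannon entropy in nats, and (b) — when ground truth is available —
the Pearson correlation between per-case risk scores and true segmentation
quality (Dice of the fusion against ground truth, and analogously Hausdorff).

A spread-out histogram (high entropy) means risk scores actually rank cases
rather than lumping them into one bin; a strongly negative r:dice means high
risk scores do mark poor segmentations.  Either quantity — or a rank-sum
combination — can drive the automatic choice of alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import MetricTable
from .qe import AlphaConfig, compute_thresholds, raise_alarms, risk_scores

__all__ = [
    "DEFAULT_ALPHA_GRID",
    "CalibrationRow",
    "alarm_histogram",
    "shannon_entropy",
    "pearson_r",
    "sweep_alpha",
    "calibration_frame",
    "recommend_alpha",
]

#: Default sweep grid, dense near 0 where sensitivity changes fastest.
DEFAULT_ALPHA_GRID: tuple[float, ...] = (
    -3.0, -2.0, -1.0, -0.75, -0.5, -0.25, -0.1,
    0.0, 0.1, 0.25, 0.5, 0.75, 1.0, 2.0, 3.0,
)


@dataclass(frozen=True)
class CalibrationRow:
    """One sweep row: alpha, histogram of risk scores over bins 0..max,
    its entropy (nats), and quality correlations (NaN when unavailable)."""

    alpha: float
    histogram: tuple[int, ...]
    entropy: float
    r_dice: float
    r_hd: float


def alarm_histogram(scores: Sequence[int], max_alarms: int) -> np.ndarray:
    """counts[k] = number of cases with risk score k, for k = 0..max_alarms."""
    scores = np.asarray(scores, dtype=int)
    if scores.size and (scores.min() < 0 or scores.max() > max_alarms):
        raise ValueError(
            f"risk scores outside [0, {max_alarms}]: "
            f"range [{scores.min()}, {scores.max()}]"
        )
    return np.bincount(scores, minlength=max_alarms + 1)


def shannon_entropy(counts: Sequence[int]) -> float:
    """Shannon entropy (nats) of a category-count histogram.

    H = -sum p_k ln p_k over non-empty categories; a single-bin histogram
    has exactly 0 entropy, a uniform K-bin one exactly ln K.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("entropy of an all-zero histogram is undefined")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum()) + 0.0  # normalize -0.0


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation with NA semantics.

    Pairs whose y is NaN or infinite are dropped (e.g. cases with an
    infinite ground-truth Hausdorff distance).  Returns NaN ("NA") when
    fewer than 3 valid pairs remain or either series has zero variance —
    the correlation is simply undefined there, as in a sweep row where
    every case saturates at the maximum alarm count.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(y) & np.isfinite(x)
    x, y = x[keep], y[keep]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def sweep_alpha(
    table: MetricTable,
    gt_quality: pd.DataFrame | None = None,
    alphas: Sequence[float] = DEFAULT_ALPHA_GRID,
    max_alarms: int | None = None,
) -> list[CalibrationRow]:
    """Recompute thresholds/alarms/summary for each alpha on the grid.

    ``gt_quality``, when given, is a per-case frame with columns ``case_id``
    and any of ``gt_dice`` / ``gt_hd`` (quality of the *fusion* against
    ground truth); r:dice and r:hd correlate it with the risk scores.
    ``max_alarms`` defaults to the structural maximum
    n_sources x n_metrics x n_classes of the table.
    """
    if max_alarms is None:
        max_alarms = (
            len(table.sources) * len(table.metrics) * len(table.class_names)
        )
    gt = None
    if gt_quality is not None:
        gt = gt_quality.set_index("case_id")
    rows = []
    for a in sorted(float(a) for a in alphas):
        thresholds = compute_thresholds(table, AlphaConfig(alpha=a))
        scores = risk_scores(raise_alarms(table, thresholds))
        hist = alarm_histogram(scores["risk_score"], max_alarms)
        r_dice = r_hd = float("nan")
        if gt is not None:
            risk = scores["risk_score"].to_numpy(dtype=float)
            if "gt_dice" in gt.columns:
                qual = gt.reindex(scores["case_id"])["gt_dice"].to_numpy(dtype=float)
                r_dice = pearson_r(risk, qual)
            if "gt_hd" in gt.columns:
                qual = gt.reindex(scores["case_id"])["gt_hd"].to_numpy(dtype=float)
                r_hd = pearson_r(risk, qual)
        rows.append(
            CalibrationRow(
                alpha=a,
                histogram=tuple(int(c) for c in hist),
                entropy=shannon_entropy(hist),
                r_dice=r_dice,
                r_hd=r_hd,
            )
        )
    return rows


def calibration_frame(rows: Sequence[CalibrationRow]) -> pd.DataFrame:
    """Sweep rows as a frame: alpha, entropy, r_dice, r_hd, then one column
    per alarm-count category (``0a`` .. ``Na``)."""
    n_bins = len(rows[0].histogram)
    recs = []
    for r in rows:
        rec = {"alpha": r.alpha, "entropy": r.entropy, "r_dice": r.r_dice, "r_hd": r.r_hd}
        rec.update({f"{k}a": c for k, c in enumerate(r.histogram)})
        recs.append(rec)
    cols = ["alpha", "entropy", "r_dice", "r_hd"] + [f"{k}a" for k in range(n_bins)]
    return pd.DataFrame(recs)[cols]


Objective = Literal["max_abs_r_dice", "max_entropy", "combined"]


def recommend_alpha(rows: Sequence[CalibrationRow], objective: Objective = "combined") -> float:
    """Argmax of the calibration objective; ties go to the smaller alpha
    (the more sensitive, hence more conservative, setting)."""
    rows = sorted(rows, key=lambda r: r.alpha)

    def abs_r(r: CalibrationRow) -> float:
        return 0.0 if np.isnan(r.r_dice) else abs(r.r_dice)

    if objective == "max_abs_r_dice":
        keys = [abs_r(r) for r in rows]
    elif objective == "max_entropy":
        keys = [r.entropy for r in rows]
    elif objective == "combined":
        # rank-sum of |r_dice| and entropy; average ranks so neither
        # criterion dominates by scale
        r_rank = stats.rankdata([abs_r(r) for r in rows])
        h_rank = stats.rankdata([r.entropy for r in rows])
        keys = list(r_rank + h_rank)
    else:
        raise ValueError(f"unknown objective {objective!r}")
    best = int(np.argmax(keys))  # argmax takes the first = smallest alpha on ties
    return rows[best].alpha
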