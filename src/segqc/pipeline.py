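"""End-to-end orchestration: fuse → score → threshold → alarm → rank."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .fusion import FusionConfig, fuse_case
from .metrics import MetricTable, _mean_with_inf, dice, hausdorff, metric_table
from .qe import AlphaConfig, compute_thresholds, raise_alarms, rank_cases, risk_scores
from .seg_io import CaseEnsemble, ClassSpec, binarize

__all__ = ["PipelineResult", "fuse_cohort", "score_cohort", "gt_quality"]


@dataclass
class PipelineResult:
    """Everything one scoring run produces."""

    fusions: dict
    table: MetricTable
    thresholds: pd.DataFrame
    alarms: pd.DataFrame
    scores: pd.DataFrame
    ranking: list[str]


def fuse_cohort(
    cohort: Sequence[CaseEnsemble],
    class_spec: ClassSpec,
    config: FusionConfig | None = None,
) -> dict:
    """Fuse every case; returns case_id → fused mask."""
    config = config or FusionConfig()
    return {
        ens.case_id: fuse_case(
            [ens.candidates[s] for s in ens.sources], class_spec, config
        )
        for ens in cohort
    }


def score_cohort(
    cohort: Sequence[CaseEnsemble],
    class_spec: ClassSpec,
    fusion: FusionConfig | None = None,
    metrics: Sequence[str] = ("dice", "hausdorff"),
    alpha: AlphaConfig | float = 0.1,
    class_reduce: Literal["mean", "none"] = "mean",
    fusions: dict | None = None,
) -> PipelineResult:
    """Run the full quality-estimation procedure over a cohort.

    Steps: fuse each case's candidates, score every candidate against its
    fusion, derive per-(source, metric) robust thresholds across the cohort,
    raise alarms, accumulate per-case risk scores, and rank cases for
    review.  Pass precomputed ``fusions`` to re-score under a different
    alpha without re-fusing.
    """
    if fusions is None:
        fusions = fuse_cohort(cohort, class_spec, fusion)
    table = metric_table(cohort, fusions, class_spec, metrics, class_reduce)
    thresholds = compute_thresholds(table, alpha)
    alarms = raise_alarms(table, thresholds)
    scores = risk_scores(alarms)
    return PipelineResult(
        fusions=fusions,
        table=table,
        thresholds=thresholds,
        alarms=alarms,
        scores=scores,
        ranking=rank_cases(scores),
    )


def gt_quality(
    cohort: Sequence[CaseEnsemble],
    fusions: dict,
    class_spec: ClassSpec,
) -> pd.DataFrame:
    """True per-case quality of the fusion against ground truth.

    Columns: case_id, gt_dice (class-mean Dice) and gt_hd (class-mean
    Hausdorff; infinite whenever any class distance is infinite, so such
    cases drop out of downstream correlations).  Cases without ground truth
    are skipped.
    """
    rows = []
    for ens in cohort:
        if ens.ground_truth is None:
            continue
        fused = fusions[ens.case_id]
        d_vals, h_vals = [], []
        for _, ids in class_spec.items():
            f = binarize(fused, ids)
            g = binarize(ens.ground_truth, ids)
            d_vals.append(dice(f, g))
            h_vals.append(hausdorff(f, g))
        d_arr = np.asarray(d_vals, dtype=float)
        finite = d_arr[~np.isnan(d_arr)]
        rows.append(
            {
                "case_id": ens.case_id,
                "gt_dice": float(finite.mean()) if finite.size else float("nan"),
                "gt_hd": _mean_with_inf(np.asarray(h_vals, dtype=float)),
            }
        )
    return pd.DataFrame(rows)
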