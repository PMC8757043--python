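"""Similarity metrics between segmentation masks.

Two metrics drive the quality-estimation pipeline: the volumetric Dice
coefficient (overlap in [0, 1], higher is better, spacing-independent) and
the Hausdorff distance (mm, lower is better, computed over foreground voxel
sets with anisotropic spacing).

Degenerate inputs have defined semantics rather than exceptions, because
they carry signal downstream:

* exactly one mask empty  -> Dice 0, Hausdorff +inf
* both masks empty        -> NaN for either metric

NaN/inf values are excluded from threshold estimation but always raise an
alarm: an ensemble member that predicts nothing (or an ensemble that
unanimously predicts nothing) deserves human review.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .seg_io import ClassSpec, GridMismatchError, SegMask, binarize

__all__ = [
    "METRIC_ORIENTATION",
    "dice",
    "dice_arrays",
    "hausdorff",
    "hausdorff_arrays",
    "oracle_hausdorff",
    "metric_table",
    "reduce_classes",
    "MetricTable",
]

#: Direction in which each metric improves; drives sign orientation in
#: thresholding ("higher_better" passes through, "lower_better" is negated).
METRIC_ORIENTATION: dict[str, str] = {
    "dice": "higher_better",
    "hausdorff": "lower_better",
    "hausdorff95": "lower_better",
}

REDUCED_CLASS = "__mean__"


def _check_grids(a: SegMask, b: SegMask, spacing: bool = False) -> None:
    if a.shape != b.shape:
        raise GridMismatchError(f"shape mismatch: {a.shape} vs {b.shape}")
    if spacing and not np.allclose(a.spacing, b.spacing):
        raise GridMismatchError(f"spacing mismatch: {a.spacing} vs {b.spacing}")


def dice_arrays(a: np.ndarray, b: np.ndarray) -> float:
    """Dice on boolean arrays; NaN when both are empty, 0 when one is."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return float("nan")
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / (na + nb)


def dice(a: SegMask, b: SegMask) -> float:
    """Volumetric Dice coefficient 2|A∩B| / (|A|+|B|) between binary masks."""
    _check_grids(a, b)
    return dice_arrays(a.voxels > 0, b.voxels > 0)


def _directed_distances(
    source: np.ndarray, target: np.ndarray, spacing: Sequence[float]
) -> np.ndarray:
    """Distance (mm) from every foreground voxel of ``source`` to the nearest
    foreground voxel of ``target``, via a spacing-aware distance transform."""
    dt = ndimage.distance_transform_edt(~target, sampling=spacing)
    return dt[source]


def hausdorff_arrays(
    a: np.ndarray, b: np.ndarray, spacing: Sequence[float], percentile: float = 100.0
) -> float:
    """(Percentile) Hausdorff distance in mm between boolean arrays.

    The classic distance is the max over both directed farthest-nearest
    distances; ``percentile`` < 100 gives the robust variant (e.g. HD95).
    One empty set -> +inf; both empty -> NaN.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    ea, eb = not a.any(), not b.any()
    if ea and eb:
        return float("nan")
    if ea or eb:
        return float("inf")
    d_ab = _directed_distances(a, b, spacing)
    d_ba = _directed_distances(b, a, spacing)
    if percentile >= 100.0:
        return float(max(d_ab.max(), d_ba.max()))
    return float(max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile)))


def hausdorff(a: SegMask, b: SegMask, percentile: float = 100.0) -> float:
    """Hausdorff distance (mm) between binary masks on one grid."""
    _check_grids(a, b, spacing=True)
    return hausdorff_arrays(a.voxels > 0, b.voxels > 0, a.spacing, percentile)


def oracle_hausdorff(a: SegMask, b: SegMask) -> float:
    """Brute-force all-pairs Hausdorff distance; a test oracle only.

    Enumerates every foreground voxel pair in physical coordinates and takes
    the max of the two directed farthest-nearest distances.  Quadratic in
    foreground size — keep masks small.
    """
    _check_grids(a, b, spacing=True)
    pa = np.argwhere(a.voxels > 0) * np.asarray(a.spacing)
    pb = np.argwhere(b.voxels > 0) * np.asarray(b.spacing)
    if len(pa) == 0 and len(pb) == 0:
        return float("nan")
    if len(pa) == 0 or len(pb) == 0:
        return float("inf")
    d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2)
    d_ab = np.sqrt(d2.min(axis=1)).max()
    d_ba = np.sqrt(d2.min(axis=0)).max()
    return float(max(d_ab, d_ba))


_METRIC_FNS = {
    "dice": dice,
    "hausdorff": hausdorff,
    "hausdorff95": lambda a, b: hausdorff(a, b, percentile=95.0),
}


@dataclass
class MetricTable:
    """Tidy per-cell similarity values plus the roster that indexes them.

    ``values`` has columns case_id, source_id, class_name, metric, value and
    forms a complete grid over (cases × sources × classes × metrics); cells
    may hold NaN or ±inf but are never missing.
    """

    values: pd.DataFrame
    sources: list[str]
    class_names: list[str]
    metrics: list[str]

    @property
    def cases(self) -> list[str]:
        return sorted(self.values["case_id"].unique())


def _mean_with_inf(vals: np.ndarray) -> float:
    """Class mean with explicit propagation: any inf -> inf, else any NaN ->
    NaN, else the arithmetic mean."""
    if np.isinf(vals).any():
        return float("inf")
    if np.isnan(vals).any():
        return float("nan")
    return float(vals.mean())


def reduce_classes(table: MetricTable) -> MetricTable:
    """Average each (case, source, metric) over classes into one reduced cell.

    The reduction gives one alarm opportunity per (source, metric), so a
    K-source, M-metric ensemble yields at most K·M alarms per case.
    """
    df = table.values
    red = (
        df.groupby(["case_id", "source_id", "metric"], sort=True)["value"]
        .apply(lambda s: _mean_with_inf(s.to_numpy()))
        .reset_index()
    )
    red["class_name"] = REDUCED_CLASS
    red = red[["case_id", "source_id", "class_name", "metric", "value"]]
    return MetricTable(
        values=red,
        sources=table.sources,
        class_names=[REDUCED_CLASS],
        metrics=table.metrics,
    )


def metric_table(
    cohort: Sequence,
    fusions: Mapping[str, SegMask],
    class_spec: ClassSpec,
    metrics: Sequence[str] = ("dice", "hausdorff"),
    class_reduce: Literal["mean", "none"] = "mean",
) -> MetricTable:
    """Score every candidate of every case against that case's fusion.

    For each (case, source, class, metric) cell the metric is evaluated
    between the class-binarized fusion and the class-binarized candidate.
    With ``class_reduce="mean"`` the per-class table is averaged over classes
    (inf dominates, then NaN) into one cell per (case, source, metric).
    """
    for m in metrics:
        if m not in _METRIC_FNS:
            raise ValueError(f"unknown metric {m!r}; choose from {sorted(_METRIC_FNS)}")
    rows = []
    roster: set[str] | None = None
    for ens in cohort:
        if ens.case_id not in fusions:
            raise ValueError(f"no fusion provided for case {ens.case_id!r}")
        if roster is None:
            roster = set(ens.sources)
        elif set(ens.sources) != roster:
            raise ValueError(
                f"roster mismatch in case {ens.case_id!r}: {sorted(ens.sources)} "
                f"vs {sorted(roster)}"
            )
        fusion = fusions[ens.case_id]
        fused_bin = {name: binarize(fusion, ids) for name, ids in class_spec.items()}
        for src in ens.sources:
            cand = ens.candidates[src]
            for name, ids in class_spec.items():
                cand_bin = binarize(cand, ids)
                for m in metrics:
                    rows.append(
                        {
                            "case_id": ens.case_id,
                            "source_id": src,
                            "class_name": name,
                            "metric": m,
                            "value": _METRIC_FNS[m](fused_bin[name], cand_bin),
                        }
                    )
    table = MetricTable(
        values=pd.DataFrame(rows),
        sources=sorted(roster or set()),
        class_names=list(class_spec.class_names),
        metrics=list(metrics),
    )
    if class_reduce == "mean":
        return reduce_classes(table)
    return table
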