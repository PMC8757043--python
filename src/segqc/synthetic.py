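"""Synthetic segmentation-ensemble cohorts with graded, known quality.

Each case gets a phantom ground truth (a few ellipsoidal components per
class, placed away from the volume boundary) and K candidate masks derived
from it by corruption operators that mimic how real segmenters fail:

* boundary perturbation — per-component dilation or erosion by a random
  radius (over-/under-segmentation of a lesion boundary);
* component dropout — an entire lesion missed;
* spurious components — small false-positive blobs elsewhere in the volume.

Corruption intensity is controlled by a per-case difficulty grade
λ ∈ [0, 1]: hard images are hard for every algorithm, so all candidates of
a case share one λ, with small per-source jitter providing the discord the
quality-estimation method feeds on.  λ = 0 reproduces the ground truth
exactly.  Two degenerate regimes are reachable on purpose: zero jitter
(all members fail identically — the method's blind spot) and p_miss = 1 at
λ = 1 (empty candidates, exercising the infinite-Hausdorff alarm path).

Every stochastic operation draws from a generator seeded by
(seed, stream, case_index[, source_index]), so any single mask is
reproducible in isolation, not just whole-run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .metrics import dice
from .seg_io import CaseEnsemble, ClassSpec, SegMask, binarize, write_mask

__all__ = ["SimConfig", "make_phantom", "corrupt", "make_cohort", "write_cohort"]

# rng stream tags, so the per-case/per-source streams never collide
_STREAM_LAMBDA = 1
_STREAM_PHANTOM = 2
_STREAM_CORRUPT = 3
_STREAM_JITTER = 4


def _default_classes() -> ClassSpec:
    return ClassSpec([1, 2], ["core", "edema"])


@dataclass(frozen=True)
class SimConfig:
    """Cohort-generator settings.

    λ-scaled corruption: a candidate with per-source difficulty λ_s drops
    each true component with probability ``p_miss * λ_s``, gains
    Poisson(``p_spurious * λ_s``) spurious blobs, and has each surviving
    component dilated or eroded by a radius up to ``boundary_sigma * λ_s``
    voxels.  ``source_jitter`` is the s.d. of the per-source perturbation of
    the case difficulty (0 ⇒ identical errors across the ensemble).
    """

    n_cases: int = 50
    n_sources: int = 5
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    classes: ClassSpec = field(default_factory=_default_classes)
    quality_grade: tuple[float, ...] | None = None
    p_miss: float = 0.3
    p_spurious: float = 2.0
    boundary_sigma: float = 3.0
    source_jitter: float = 0.15
    n_components: tuple[int, int] = (1, 3)
    component_radius: tuple[float, float] = (3.0, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_miss <= 1):
            raise ValueError("p_miss must be a probability")
        if self.p_spurious < 0 or self.boundary_sigma < 0 or self.source_jitter < 0:
            raise ValueError("rates must be non-negative")
        if any(s <= 0 for s in self.shape) or any(s <= 0 for s in self.spacing):
            raise ValueError("shape and spacing must be positive")
        if self.quality_grade is not None:
            qg = tuple(float(q) for q in self.quality_grade)
            if len(qg) != self.n_cases:
                raise ValueError("quality_grade must list one λ per case")
            if any(not 0 <= q <= 1 for q in qg):
                raise ValueError("quality grades must lie in [0, 1]")
            object.__setattr__(self, "quality_grade", qg)


def _ellipsoid(shape: Sequence[int], center: np.ndarray, radii: np.ndarray) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(tuple(shape), dtype=float)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def _ball(radius: int) -> np.ndarray:
    span = np.arange(-radius, radius + 1)
    x, y, z = np.meshgrid(span, span, span, indexing="ij")
    return x * x + y * y + z * z <= radius * radius


def case_lambda(config: SimConfig, case_index: int) -> float:
    """Per-case difficulty grade: configured explicitly, else Uniform(0,1)."""
    if config.quality_grade is not None:
        return config.quality_grade[case_index]
    rng = np.random.default_rng([config.seed, _STREAM_LAMBDA, case_index])
    return float(rng.uniform())


def make_phantom(config: SimConfig, case_index: int) -> SegMask:
    """Ground-truth phantom for one case: per class, a few ellipsoids placed
    away from the boundary; classes never overlap (earlier classes keep
    contested voxels).  Deterministic in (seed, case_index)."""
    rng = np.random.default_rng([config.seed, _STREAM_PHANTOM, case_index])
    shape = np.array(config.shape)
    r_lo, r_hi = config.component_radius
    # shrink components on small grids so they always fit with a margin
    r_hi = min(r_hi, min(shape) / 4)
    r_lo = min(r_lo, r_hi)
    margin = int(np.ceil(r_hi)) + 2
    out = np.zeros(config.shape, dtype=np.int32)
    for name, ids in config.classes.items():
        label = config.classes.output_label(name)
        n_comp = int(rng.integers(config.n_components[0], config.n_components[1] + 1))
        for _ in range(n_comp):
            center = rng.uniform(margin, shape - margin)
            radii = rng.uniform(r_lo, r_hi, size=3)
            blob = _ellipsoid(config.shape, center, radii)
            out[blob & (out == 0)] = label
    return SegMask(
        voxels=out,
        spacing=config.spacing,
        case_id=f"case_{case_index:03d}",
        source_id="gt",
    )


def corrupt(
    gt: SegMask, lam: float, config: SimConfig, source_index: int, case_index: int = 0
) -> SegMask:
    """One candidate mask: the ground truth degraded at intensity λ.

    λ = 0 returns an exact copy.  Deterministic in
    (seed, case_index, source_index).
    """
    if not 0 <= lam <= 1:
        raise ValueError("λ must lie in [0, 1]")
    source_id = f"alg{source_index:02d}"
    if lam == 0:
        return gt.with_voxels(gt.voxels.copy(), source_id=source_id)
    rng = np.random.default_rng(
        [config.seed, _STREAM_CORRUPT, case_index, source_index]
    )
    out = np.zeros(gt.shape, dtype=np.int32)
    max_radius = int(np.floor(config.boundary_sigma * lam))
    for name, ids in config.classes.items():
        label = config.classes.output_label(name)
        class_mask = binarize(gt, ids).voxels > 0
        comps, n_comp = ndimage.label(class_mask)
        for c in range(1, n_comp + 1):
            if rng.random() < config.p_miss * lam:
                continue  # missed component
            comp = comps == c
            radius = int(rng.integers(0, max_radius + 1))
            if radius > 0:
                ball = _ball(radius)
                if rng.random() < 0.5:
                    comp = ndimage.binary_dilation(comp, structure=ball)
                else:
                    comp = ndimage.binary_erosion(comp, structure=ball)
            out[comp & (out == 0)] = label

    # spurious false-positive blobs on the background
    n_spurious = int(rng.poisson(config.p_spurious * lam))
    labels = [config.classes.output_label(n) for n in config.classes.class_names]
    shape = np.array(gt.shape)
    for _ in range(n_spurious):
        center = rng.uniform(3, shape - 3)
        radii = rng.uniform(1.0, 2.5, size=3)
        blob = _ellipsoid(gt.shape, center, radii)
        label = labels[int(rng.integers(len(labels)))]
        out[blob & (out == 0)] = label
    return gt.with_voxels(out, source_id=source_id)


def _true_mean_dice(cand: SegMask, gt: SegMask, classes: ClassSpec) -> float:
    vals = [dice(binarize(cand, ids), binarize(gt, ids)) for _, ids in classes.items()]
    arr = np.asarray(vals, dtype=float)
    finite = arr[~np.isnan(arr)]
    return float(finite.mean()) if finite.size else float("nan")


def make_cohort(config: SimConfig) -> tuple[list[CaseEnsemble], pd.DataFrame]:
    """Generate the cohort and its truth ledger.

    Returns the list of ensembles (each carrying its ground truth) and a
    per-(case, source) frame with columns case_id, source_id, lambda_case,
    lambda_source, true_dice — the class-mean Dice of each candidate against
    ground truth, for validating that alarms track real quality.
    """
    cohort: list[CaseEnsemble] = []
    records = []
    for i in range(config.n_cases):
        gt = make_phantom(config, i)
        lam = case_lambda(config, i)
        candidates = {}
        for j in range(config.n_sources):
            jit = np.random.default_rng(
                [config.seed, _STREAM_JITTER, i, j]
            ).normal(scale=config.source_jitter) if config.source_jitter > 0 else 0.0
            lam_s = float(np.clip(lam + jit, 0.0, 1.0))
            cand = corrupt(gt, lam_s, config, source_index=j, case_index=i)
            candidates[cand.source_id] = cand
            records.append(
                {
                    "case_id": gt.case_id,
                    "source_id": cand.source_id,
                    "lambda_case": lam,
                    "lambda_source": lam_s,
                    "true_dice": _true_mean_dice(cand, gt, config.classes),
                }
            )
        cohort.append(
            CaseEnsemble(case_id=gt.case_id, candidates=candidates, ground_truth=gt)
        )
    return cohort, pd.DataFrame(records)


def write_cohort(
    cohort: Sequence[CaseEnsemble],
    out_dir: str | Path,
    ledger: pd.DataFrame | None = None,
) -> Path:
    """Write the cohort as NIfTI files plus the YAML index and truth CSV.

    Returns the path of the index file, directly consumable by
    :func:`segqc.seg_io.load_cohort`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index: dict = {}
    for ens in cohort:
        case_dir = out_dir / ens.case_id
        entry: dict = {"sources": {}}
        for src, mask in sorted(ens.candidates.items()):
            rel = f"{ens.case_id}/{src}.nii.gz"
            write_mask(mask, out_dir / rel)
            entry["sources"][src] = rel
        if ens.ground_truth is not None:
            rel = f"{ens.case_id}/gt.nii.gz"
            write_mask(ens.ground_truth, out_dir / rel)
            entry["gt"] = rel
        index[ens.case_id] = entry
    index_path = out_dir / "cohort.yaml"
    with open(index_path, "w") as fh:
        yaml.safe_dump(index, fh, sort_keys=True)
    if ledger is not None:
        ledger.to_csv(out_dir / "truth.csv", index=False)
    return index_path
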