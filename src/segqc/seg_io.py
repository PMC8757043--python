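"""Segmentation mask containers and NIfTI cohort I/O.

The atoms of the pipeline are :class:`SegMask` (one 3D integer label volume
on a known voxel grid) and :class:`CaseEnsemble` (all candidate masks for one
case, optionally with a ground-truth mask).  Masks belonging to one case must
live on the same grid: the method assumes co-registered inputs, and grids are
validated rather than resampled so that registration failures surface as
errors instead of being silently absorbed.

Multi-label maps are decomposed into binary class masks with
:func:`binarize`; an evaluation class may be a single label or a union of
labels (e.g. tumor core = enhancing tumor + necrosis).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "SegMask",
    "CaseEnsemble",
    "ClassSpec",
    "GridMismatchError",
    "read_mask",
    "write_mask",
    "binarize",
    "load_cohort",
    "load_cohort_index",
]

#: Tolerance for rounding floating-point NIfTI encodings of integer labels.
LABEL_ROUND_TOL = 1e-3


class GridMismatchError(ValueError):
    """Masks that must share one voxel grid do not."""


@dataclass(frozen=True)
class SegMask:
    """One 3D label volume with grid geometry.

    Parameters
    ----------
    voxels
        3D array of non-negative integer label IDs; 0 is background.
    spacing
        Per-axis voxel size in mm, strictly positive.
    case_id, source_id
        Identifiers for the exam and for the algorithm/rater that produced
        the mask.
    affine
        Optional 4x4 voxel-to-world matrix, carried through I/O only; all
        comparisons happen in voxel space with ``spacing`` as the metric.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    case_id: str = ""
    source_id: str = ""
    affine: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={vox.ndim}")
        if not np.issubdtype(vox.dtype, np.integer):
            raise ValueError("voxels must be an integer array")
        if vox.size and vox.min() < 0:
            raise ValueError("label values must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive numbers, got {self.spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def same_grid(self, other: "SegMask") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    def labels(self) -> np.ndarray:
        """Sorted unique label IDs present in the volume."""
        return np.unique(self.voxels)

    def with_voxels(self, voxels: np.ndarray, source_id: str | None = None) -> "SegMask":
        return SegMask(
            voxels=voxels,
            spacing=self.spacing,
            case_id=self.case_id,
            source_id=self.source_id if source_id is None else source_id,
            affine=self.affine,
        )


@dataclass
class CaseEnsemble:
    """All candidate segmentations for one case, keyed by source."""

    case_id: str
    candidates: dict[str, SegMask]
    ground_truth: SegMask | None = None

    def __post_init__(self) -> None:
        if len(self.candidates) < 2:
            raise ValueError(
                f"case {self.case_id!r}: an ensemble needs >= 2 candidates, "
                f"got {len(self.candidates)}"
            )
        masks = list(self.candidates.values())
        if self.ground_truth is not None:
            masks.append(self.ground_truth)
        ref = masks[0]
        for m in masks[1:]:
            if not ref.same_grid(m):
                raise GridMismatchError(
                    f"case {self.case_id!r}: mask {m.source_id!r} is on a "
                    f"different grid ({m.shape}, {m.spacing}) than "
                    f"{ref.source_id!r} ({ref.shape}, {ref.spacing})"
                )

    @property
    def sources(self) -> list[str]:
        return sorted(self.candidates)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return next(iter(self.candidates.values())).shape


@dataclass(frozen=True)
class ClassSpec:
    """Ordered evaluation classes over label IDs.

    Each class is a single label ID or a set of IDs (a composite region such
    as tumor core).  Class order doubles as the default precedence used to
    break ties in multi-label fusion.
    """

    class_ids: tuple[frozenset[int], ...]
    class_names: tuple[str, ...]

    def __init__(
        self,
        class_ids: Sequence[int | Sequence[int] | frozenset[int]],
        class_names: Sequence[str],
    ) -> None:
        if not class_ids:
            raise ValueError("ClassSpec needs at least one class")
        if len(class_ids) != len(class_names):
            raise ValueError("class_ids and class_names must be parallel")
        if len(set(class_names)) != len(class_names):
            raise ValueError("duplicate class names")
        ids = tuple(
            frozenset([int(c)]) if np.isscalar(c) else frozenset(int(x) for x in c)  # type: ignore[arg-type]
            for c in class_ids
        )
        object.__setattr__(self, "class_ids", ids)
        object.__setattr__(self, "class_names", tuple(str(n) for n in class_names))

    def __len__(self) -> int:
        return len(self.class_names)

    def items(self):
        return zip(self.class_names, self.class_ids)

    def ids_for(self, name: str) -> frozenset[int]:
        return self.class_ids[self.class_names.index(name)]

    def output_label(self, name: str) -> int:
        """Representative label written for this class when recomposing a
        multi-label map (the smallest member ID)."""
        return min(self.ids_for(name))

    @classmethod
    def binary(cls, name: str = "foreground") -> "ClassSpec":
        return cls([1], [name])


def read_mask(path: str | os.PathLike, case_id: str = "", source_id: str = "") -> SegMask:
    """Read one NIfTI segmentation mask.

    Voxel spacing is taken from the header geometry.  Floating-point volumes
    are accepted when every value lies within ``LABEL_ROUND_TOL`` of an
    integer (common for masks saved as float); anything farther is an error,
    since rounding real-valued data would fabricate labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, rtol=0, atol=LABEL_ROUND_TOL):
            worst = float(np.abs(data - rounded).max())
            raise ValueError(
                f"{path}: non-integer voxel values (max deviation {worst:.4g} "
                f"exceeds tolerance {LABEL_ROUND_TOL})"
            )
        data = rounded.astype(np.int32)
    else:
        data = data.astype(np.int32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: non-positive voxel spacing {spacing}")
    return SegMask(
        voxels=data,
        spacing=spacing,  # type: ignore[arg-type]
        case_id=case_id,
        source_id=source_id,
        affine=np.asarray(img.affine),
    )


def write_mask(mask: SegMask, path: str | os.PathLike) -> None:
    """Write a mask as NIfTI-1, preserving spacing (and affine when known)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if mask.affine is not None:
        affine = mask.affine
    else:
        affine = np.diag(list(mask.spacing) + [1.0])
    img = nib.Nifti1Image(mask.voxels.astype(np.int16), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def binarize(mask: SegMask, class_ids: int | Sequence[int] | frozenset[int]) -> SegMask:
    """Binary mask of voxels whose label belongs to ``class_ids``.

    A class absent from the volume yields an all-zero mask, which is legal
    (and, downstream, exactly the situation the infinite-Hausdorff alarm
    rule exists for).
    """
    if np.isscalar(class_ids):
        ids = frozenset([int(class_ids)])  # type: ignore[arg-type]
    else:
        ids = frozenset(int(x) for x in class_ids)  # type: ignore[union-attr]
    if not ids:
        raise ValueError("class must be non-empty")
    out = np.isin(mask.voxels, sorted(ids)).astype(np.int32)
    return mask.with_voxels(out)


def load_cohort_index(path: str | os.PathLike) -> dict:
    """Read a YAML/JSON cohort index: {case: {sources: {name: path}, gt: path?}}."""
    with open(path) as fh:
        index = yaml.safe_load(fh)
    if not isinstance(index, Mapping) or not index:
        raise ValueError(f"{path}: cohort index must be a non-empty mapping")
    return dict(index)


def load_cohort(
    index: Mapping[str, Mapping] | str | os.PathLike,
    base_dir: str | os.PathLike | None = None,
) -> list[CaseEnsemble]:
    """Load a cohort of case ensembles from a cohort index.

    ``index`` is either the mapping itself or a path to a YAML/JSON file.
    Every case must list the same roster of source IDs (a fixed ensemble),
    and all masks of a case must share one grid.  Relative paths resolve
    against ``base_dir`` (default: the index file's directory, else cwd).
    """
    if isinstance(index, (str, os.PathLike)):
        if base_dir is None:
            base_dir = Path(index).parent
        index = load_cohort_index(index)
    base = Path(base_dir) if base_dir is not None else Path(".")

    def resolve(p: str) -> Path:
        p = Path(p)
        return p if p.is_absolute() else base / p

    rosters = {
        case_id: frozenset(entry.get("sources", {}))
        for case_id, entry in index.items()
    }
    roster = next(iter(rosters.values()))
    bad = {c: sorted(r) for c, r in rosters.items() if r != roster}
    if bad:
        raise ValueError(
            f"roster mismatch: expected sources {sorted(roster)} in every case, "
            f"but got {bad}"
        )

    cohort = []
    for case_id in sorted(index):
        entry = index[case_id]
        candidates = {
            src: read_mask(resolve(p), case_id=case_id, source_id=src)
            for src, p in sorted(entry["sources"].items())
        }
        gt = None
        if entry.get("gt"):
            gt = read_mask(resolve(entry["gt"]), case_id=case_id, source_id="gt")
        cohort.append(CaseEnsemble(case_id=case_id, candidates=candidates, ground_truth=gt))
    return cohort
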