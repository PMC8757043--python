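"""Label fusion: equal-weight majority voting and SIMPLE iterative fusion.

Both fusers build a consensus mask from a case's candidate segmentations.
Majority voting is the strict-majority rule; SIMPLE (Selective and Iterative
Method for Performance Level Estimation, Langerak et al.) re-weights
candidates by their agreement with the evolving consensus and discards poor
performers, which tends to beat plain majority voting when ensemble members
differ in quality.

All fusion here is deterministic: ties are resolved by explicit rules, never
by input order, so both fusers are permutation-invariant in the candidate
list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .metrics import dice_arrays
from .seg_io import ClassSpec, GridMismatchError, SegMask, binarize

__all__ = [
    "FusionConfig",
    "SimpleResult",
    "majority_vote",
    "majority_vote_multilabel",
    "simple_fuse",
    "fuse_case",
]

TieRule = Literal["background", "foreground"]


@dataclass(frozen=True)
class FusionConfig:
    """Fusion method and its knobs.

    ``simple_discard_sd`` is the z-cutoff of SIMPLE's discard rule: a
    candidate is dropped when its estimated performance falls below
    mean - simple_discard_sd * sd of the retained performances.
    ``tie_rule`` settles exact vote ties (even ensembles); background is the
    conservative default — an under-segmented fusion lowers candidate
    agreement and produces more alarms, which is the safe failure direction
    for a triage tool.
    """

    method: Literal["majority", "simple"] = "majority"
    simple_max_iters: int = 25
    simple_discard_sd: float = 2.0
    tie_rule: TieRule = "background"

    def __post_init__(self) -> None:
        if self.method not in ("majority", "simple"):
            raise ValueError(f"unknown fusion method {self.method!r}")
        if self.simple_max_iters < 1:
            raise ValueError("simple_max_iters must be >= 1")
        if self.simple_discard_sd < 0:
            raise ValueError("simple_discard_sd must be non-negative")


@dataclass
class SimpleResult:
    """Outcome of a SIMPLE fusion: the mask, final per-candidate weights
    (estimated performance; 0 for discarded members), the retained source
    set, and the number of iterations run."""

    fused: SegMask
    weights: dict[str, float]
    retained: set[str]
    n_iters: int
    fell_back: bool = field(default=False)


def _check_binary_stack(candidates: Sequence[SegMask]) -> np.ndarray:
    if len(candidates) < 2:
        raise ValueError("fusion needs at least 2 candidates")
    ref = candidates[0]
    for c in candidates[1:]:
        if not ref.same_grid(c):
            raise GridMismatchError(
                f"candidate {c.source_id!r} grid {c.shape}/{c.spacing} differs "
                f"from {ref.source_id!r} {ref.shape}/{ref.spacing}"
            )
    stack = np.stack([c.voxels for c in candidates])
    if stack.max(initial=0) > 1:
        raise ValueError("binary fusion requires 0/1 masks; use the multilabel fuser")
    return stack


def majority_vote(candidates: Sequence[SegMask], tie_rule: TieRule = "background") -> SegMask:
    """Equal-weight strict-majority vote over binary masks.

    A voxel is foreground iff strictly more than half of the candidates mark
    it foreground; an exact tie (possible for even ensembles) goes to
    ``tie_rule``.
    """
    stack = _check_binary_stack(candidates)
    k = stack.shape[0]
    votes = stack.sum(axis=0)
    fused = votes * 2 > k
    if tie_rule == "foreground":
        fused = fused | (votes * 2 == k)
    return candidates[0].with_voxels(fused.astype(np.int32), source_id="fusion")


def majority_vote_multilabel(
    candidates: Sequence[SegMask],
    class_spec: ClassSpec,
    precedence: Sequence[str] | None = None,
) -> SegMask:
    """Plurality vote over multi-label maps.

    Per voxel the class with the most votes wins.  Background (a label in no
    class, including 0) wins any tie it participates in; a tie between
    classes with zero background involvement resolves by ``precedence``
    (default: class_spec order).  The winning class is written as its
    representative label from ``class_spec``.
    """
    if len(candidates) < 2:
        raise ValueError("fusion needs at least 2 candidates")
    ref = candidates[0]
    for c in candidates[1:]:
        if not ref.same_grid(c):
            raise GridMismatchError(
                f"candidate {c.source_id!r} grid differs from {ref.source_id!r}"
            )
    if precedence is None:
        precedence = list(class_spec.class_names)
    if set(precedence) != set(class_spec.class_names):
        raise ValueError("precedence must be a permutation of the class names")

    stack = np.stack([c.voxels for c in candidates])
    k = stack.shape[0]
    class_votes = {
        name: np.isin(stack, sorted(ids)).sum(axis=0)
        for name, ids in class_spec.items()
    }
    any_class = np.zeros_like(stack, dtype=bool)
    for _, ids in class_spec.items():
        any_class |= np.isin(stack, sorted(ids))
    bg_votes = k - any_class.sum(axis=0)

    best = np.maximum.reduce(list(class_votes.values()))
    out = np.zeros(ref.shape, dtype=np.int32)
    # background wins ties: a class must strictly beat the background count
    decided = best > bg_votes
    for name in precedence:  # earlier classes claim tied voxels first
        take = decided & (class_votes[name] == best) & (out == 0)
        out[take] = class_spec.output_label(name)
    return ref.with_voxels(out, source_id="fusion")


def _weighted_vote(
    stack: np.ndarray, weights: np.ndarray, template: SegMask, tie_rule: TieRule
) -> SegMask:
    total = float(weights.sum())
    mass = np.tensordot(weights, stack, axes=1)
    fused = mass * 2 > total
    if tie_rule == "foreground":
        fused = fused | np.isclose(mass * 2, total)
    else:
        fused = fused & ~np.isclose(mass * 2, total)
    return template.with_voxels(fused.astype(np.int32), source_id="fusion")


def simple_fuse(candidates: Sequence[SegMask], config: FusionConfig | None = None) -> SimpleResult:
    """SIMPLE iterative fusion of binary candidates.

    The scheme: (1) initialise the consensus as the equal-weight majority
    vote; (2) estimate each retained candidate's performance as its Dice
    against the current consensus; (3) discard candidates whose performance
    falls below mean - ``simple_discard_sd``·sd of the retained performances;
    (4) re-fuse the retained candidates by performance-weighted voting
    (foreground where the weighted foreground mass exceeds half the total
    weight).  Steps 2–4 repeat until the retained set and fused mask stop
    changing or ``simple_max_iters`` is reached.

    Degenerate cases: with fewer than 3 retained candidates the spread is
    uninformative and no discarding happens (pure weighted voting); if the
    rule would discard everything, the fuser falls back to the majority vote
    of all candidates and flags a warning.
    """
    config = config or FusionConfig(method="simple")
    stack = _check_binary_stack(candidates).astype(np.float64)
    names = [c.source_id or f"cand{i}" for i, c in enumerate(candidates)]
    if len(set(names)) != len(names):
        names = [f"{n}#{i}" for i, n in enumerate(names)]
    template = candidates[0]

    fused = majority_vote(candidates, tie_rule=config.tie_rule)
    retained = np.ones(len(candidates), dtype=bool)
    weights = np.ones(len(candidates))
    n_iters = 0

    for n_iters in range(1, config.simple_max_iters + 1):
        perf = np.array(
            [_performance(stack[i], fused.voxels) for i in range(len(candidates))]
        )
        perf[~retained] = 0.0
        kept = perf[retained]
        new_retained = retained.copy()
        if retained.sum() >= 3:
            sd = kept.std()
            if sd > 0:
                cutoff = kept.mean() - config.simple_discard_sd * sd
                # the boundary counts as discarded: a lone failure among
                # n members lands exactly at z = -(n-1)/sqrt(n-1), which for
                # n = 5 is the default cutoff itself; the epsilon absorbs
                # float noise in mean/sd
                new_retained &= perf > cutoff + 1e-12
        if not new_retained.any():
            warnings.warn(
                "SIMPLE discarded every candidate; falling back to majority vote",
                RuntimeWarning,
                stacklevel=2,
            )
            fused = majority_vote(candidates, tie_rule=config.tie_rule)
            return SimpleResult(
                fused=fused,
                weights={n: 1.0 for n in names},
                retained=set(names),
                n_iters=n_iters,
                fell_back=True,
            )
        weights = np.where(new_retained, perf, 0.0)
        if weights.sum() == 0:  # all retained candidates empty vs empty fusion
            weights = new_retained.astype(float)
        new_fused = _weighted_vote(
            stack[new_retained], weights[new_retained], template, config.tie_rule
        )
        unchanged = (
            np.array_equal(new_retained, retained)
            and np.array_equal(new_fused.voxels, fused.voxels)
        )
        retained, fused = new_retained, new_fused
        if unchanged:
            break

    return SimpleResult(
        fused=fused,
        weights={n: float(w) for n, w in zip(names, weights)},
        retained={n for n, r in zip(names, retained) if r},
        n_iters=n_iters,
    )


def _performance(candidate: np.ndarray, fused: np.ndarray) -> float:
    d = dice_arrays(candidate > 0, fused > 0)
    # both empty: the candidate matches the (empty) consensus perfectly
    return 1.0 if np.isnan(d) else d


def fuse_case(
    candidates: Sequence[SegMask],
    class_spec: ClassSpec,
    config: FusionConfig | None = None,
    return_details: bool = False,
) -> SegMask | tuple[SegMask, dict]:
    """Fuse one case's candidates under ``config``.

    Majority voting handles multi-label maps natively.  SIMPLE is defined on
    binary masks, so for multi-class specs it runs per class channel and the
    channels are recomposed in class precedence order (later classes do not
    overwrite earlier ones).

    With ``return_details`` the per-class SIMPLE bookkeeping (weights,
    retained set, iteration count) is returned alongside the mask; empty for
    majority voting, which has none.
    """
    config = config or FusionConfig()
    details: dict = {}
    if config.method == "majority":
        if len(class_spec) == 1 and all(c.voxels.max(initial=0) <= 1 for c in candidates):
            fused = majority_vote(candidates, tie_rule=config.tie_rule)
        else:
            fused = majority_vote_multilabel(candidates, class_spec)
        return (fused, details) if return_details else fused
    # SIMPLE
    if len(class_spec) == 1 and all(c.voxels.max(initial=0) <= 1 for c in candidates):
        res = simple_fuse(candidates, config)
        details[class_spec.class_names[0]] = _simple_details(res)
        return (res.fused, details) if return_details else res.fused
    out = np.zeros(candidates[0].shape, dtype=np.int32)
    for name, ids in class_spec.items():
        channel = [binarize(c, ids) for c in candidates]
        res = simple_fuse(channel, config)
        details[name] = _simple_details(res)
        write = (res.fused.voxels > 0) & (out == 0)
        out[write] = class_spec.output_label(name)
    fused = candidates[0].with_voxels(out, source_id="fusion")
    return (fused, details) if return_details else fused


def _simple_details(res: SimpleResult) -> dict:
    return {
        "weights": res.weights,
        "retained": sorted(res.retained),
        "n_iters": res.n_iters,
        "fell_back": res.fell_back,
    }
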