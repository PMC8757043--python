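# Methods

## Model and assumptions

`segqc` estimates segmentation quality without ground truth by measuring
discord inside an ensemble.  The underlying assumption is simple: if several
independent segmenters agree on an exam, their consensus is probably right
and each member is probably close to it; if they disagree, something about
the exam is hard, and the exam deserves review.  The method therefore
requires an ensemble (≥ 2 members — it is undefined for a single algorithm)
and inherits two blind spots that follow directly from the assumption:

* if all members converge to the *same* error, there is no discord to
  detect (the zero-jitter regime of the synthetic generator reproduces
  this deliberately);
* the estimate is only as meaningful as the similarity metrics used —
  alarms computed from Dice and Hausdorff distance measure what Dice and
  Hausdorff distance measure.

All masks of a case must be co-registered on one voxel grid.  Grid
agreement is **validated, never repaired**: silently resampling a
misregistered mask would hide exactly the kind of failure the alarms exist
to surface.  Comparisons happen in voxel space; only the voxel spacing (mm)
enters any metric, so full orientation matrices are carried through I/O but
ignored analytically.

## Procedure

Per case: fuse candidates → score each candidate against the fusion.
Per cohort: for each (algorithm, class, metric) series, compute the robust
threshold `median − MAD·α` on oriented values; flag cells strictly below
it, plus all NaN/infinite cells; sum flags per case into a risk score.

Decisions worth spelling out:

* **Orientation.**  Metrics negatively correlated with quality (Hausdorff)
  are negated before thresholding so one rule ("below ⇒ alarm") covers
  everything.  Reported thresholds are mapped back to the natural scale
  (a positive mm upper bound for Hausdorff).
* **Strict inequality.**  A value exactly at the threshold does not alarm.
  With α = 0 and an odd cohort this leaves the median case unflagged,
  which is the intended "approximately half" behaviour.
* **Non-finite cells.**  NaN (both masks empty) and ±inf (exactly one mask
  empty) are excluded from median/MAD estimation — one empty prediction
  must not poison the threshold for the whole series — but always raise an
  alarm.  Treating empty-vs-empty as NaN rather than a perfect score is an
  interpretive choice: an ensemble that unanimously predicts nothing
  deserves a human look.
* **Unscaled MAD.**  No 1.4826 normal-consistency factor; any scaling is
  absorbed by α, which is the tunable quantity anyway.
* **Threshold scope.**  One threshold per (algorithm, metric[, class])
  across the cohort of cases, i.e. each algorithm is compared against its
  own typical agreement level.  A per-image variant (thresholding within a
  single exam across algorithms) is a different estimator and is out of
  scope here.
* **Class reduction.**  By default per-class metrics are averaged into one
  value per (algorithm, metric) before thresholding — any infinite class
  value makes the mean infinite, else any NaN makes it NaN — giving a
  maximum risk score of `n_algorithms × n_metrics`.  `class_reduce="none"`
  keeps per-class alarm opportunities instead.
* **Ranking.**  Descending risk score, ties broken lexicographically by
  case id, so triage lists are reproducible.

## Fusion

**Majority voting** is strict: a voxel is foreground only if more than half
the members say so; exact ties (even ensembles) default to background.  The
conservative tie rule errs toward an under-segmented fusion, which lowers
candidate agreement and produces *more* alarms — the safe failure direction
for a triage tool.  The multi-label variant counts votes per evaluation
class (a class may be a union of labels); background wins any tie it is
part of, and ties among classes resolve by the class precedence order.

**SIMPLE** starts from the majority vote, estimates each member's
performance as its Dice against the current consensus, discards members
whose performance falls at or below `mean − 2·sd` of the retained
performances, and re-fuses with performance-proportional weights (voxel
foreground iff the weighted foreground mass exceeds half the retained
weight), iterating to a fixed point (cap: 25 iterations).  Three boundary
rules make the scheme total:

* the discard cutoff treats the boundary as discarded (with a 1e-12 float
  tolerance).  This is deliberate: a single total failure among `n`
  otherwise-identical members sits at z = −√(n−1) exactly — for the
  default 2·sd cutoff and n = 5, *on* the boundary — and a total failure
  is precisely what the discard step exists to remove;
* no discarding when fewer than 3 members remain (the spread of 2 values
  cannot identify an outlier) or when the spread is zero (identical
  performances);
* if the rule would discard everyone, the fuser falls back to plain
  majority voting and warns.

SIMPLE's hyperparameters (iteration cap, sd multiplier, weight definition)
are not canonical in the literature; all three are exposed on
`FusionConfig`.  On multi-label inputs SIMPLE runs per class channel and
recomposes by precedence.  Fusion is deterministic throughout; both fusers
are invariant to candidate order.

## Metrics

Dice is the plain volumetric overlap `2|A∩B|/(|A|+|B|)`; it ignores
spacing by definition.  Hausdorff is the classic 100th-percentile
symmetric distance over foreground voxel sets, computed from two
spacing-aware Euclidean distance transforms, in mm; HD95 is available
behind a flag but is not a default.  A brute-force all-pairs oracle
(`oracle_hausdorff`) exists purely for testing; the distance-transform
implementation is checked against it exactly (within 1e-9 mm of float
noise) on hundreds of random small masks.

## Alpha calibration

`sweep_alpha` recomputes thresholds and alarms for each α on a grid
(default −3 … 3, densest near 0 where sensitivity changes fastest) and
summarizes each setting by the alarm-count histogram, its Shannon entropy
in **nats**, and — when ground truth exists — Pearson correlations between
risk score and the fusion's true class-mean Dice (`r_dice`) and Hausdorff
(`r_hd`; cases with infinite ground-truth distance are dropped from the
correlation, which returns NA below 3 valid pairs or at zero variance).
Risk scores are non-increasing in α, so the 0-alarm bin can only grow as α
rises; entropy peaks where the cohort spreads across bins.
`recommend_alpha` takes the argmax of |r_dice|, of entropy, or of their
rank-sum ("combined" — ranks rather than raw values so neither criterion
dominates by scale; this combiner is a package choice, config-exposed),
breaking ties toward the smaller, more sensitive α.

## Synthetic cohorts

The generator stands in for imaging data, not for anatomy.  Each case gets
a phantom of 1–3 ellipsoidal components per class (default two classes on a
64³ grid, component radii 3–8 voxels, placed away from the boundary) and
`K` candidates produced by corrupting the phantom at a per-case difficulty
λ ~ Uniform(0, 1):

| knob | default | meaning |
|---|---|---|
| `p_miss` | 0.3 | per-component dropout probability at λ = 1 |
| `p_spurious` | 2.0 | Poisson mean of false-positive blobs at λ = 1 |
| `boundary_sigma` | 3.0 | max dilation/erosion radius (voxels) at λ = 1 |
| `source_jitter` | 0.15 | s.d. of per-member perturbation of λ |

Shared per-case λ encodes that hard exams are hard for every algorithm —
without it, alarm counts could not correlate with per-case quality; the
per-member jitter supplies the discord the method feeds on.  λ = 0 yields
exact copies of the truth; λ = 1 with `p_miss = 1` yields empty candidates,
exercising the infinite-Hausdorff alarm path.  Every stochastic step draws
from a generator seeded by (seed, stream, case, member), so any single mask
is reproducible in isolation and a fixed seed gives byte-identical cohorts.

What passing tests on these phantoms shows: the pipeline's bookkeeping is
correct and the discord→quality link holds when ensemble errors are
independent perturbations of a shared truth.  What it does not show:
behaviour under correlated CNN failure modes, intensity-driven errors,
anatomy-specific shape priors, or registration error — none of which the
generator emulates.

## Problem sizes and numerics

The validation suite runs the full pipeline on a seeded 50-case ×
5-member cohort of 64³ phantoms — large enough for stable medians per
series and a meaningful cohort correlation, small enough to score in well
under a minute.  On that cohort, risk scores at α = 0.1 recover true fused
quality with `r_dice ≈ −0.73`.  Float ties in weighted voting are settled
with `np.isclose` toward the configured tie rule; NIfTI volumes written as
floats are accepted when every voxel is within 1e-3 of an integer and
rejected otherwise.

## Known limitations

* Per-algorithm thresholds need a cohort (≥ 2 finite values per series;
  in practice a few dozen cases) before alarms mean anything; the
  degenerate-cohort error is deliberate, not a convenience fallback.
* Risk scores are unweighted flag counts; a metric that is noisy on a
  given anatomy contributes as much as a reliable one (per-series α
  overrides are the provided mitigation).
* SIMPLE equivalence with other implementations is not claimed; variants
  differ in discard schedules and weighting.
* Entropy and correlation calibrations are in-cohort; transferring an α
  across sites or scanners is untested territory.
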