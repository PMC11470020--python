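"""Detection evaluation: IoU matching, FROC curves and bootstrap CIs.

The free-response ROC (FROC) compares the true-positive rate
TPR = TP / (TP + FN) against the average number of false positives per
image FPPI = FP / n_images across all prediction-score thresholds at a
fixed IoU threshold.  The curve is reduced to a single "mean FROC" score by
averaging the TPR at fixed FPPI evaluation points; confidence intervals
come from bootstrapping whole images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: default IoU threshold for calling a prediction a match
DEFAULT_IOU_THRESHOLD = 0.1
#: FPPI evaluation points: the prevailing lesion-detection convention
DEFAULT_FPPI_POINTS = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
#: bootstrap defaults
DEFAULT_BOOTSTRAP_REPS = 1000
DEFAULT_CI_LEVEL = 0.95

Box = tuple[int, int, int, int, int, int]


@dataclass(frozen=True)
class MatchRecord:
    """The sweep's wire payload: a prediction score and whether it hit a GT box."""

    score: float
    is_tp: bool


@dataclass
class FROCResult:
    fppi_points: tuple[float, ...]
    tpr_at_fppi: tuple[float, ...]
    mean_froc: float
    n_images: int
    n_gt: int
    ci_lo: float | None = None
    ci_hi: float | None = None

    def __post_init__(self):
        if len(self.tpr_at_fppi) != len(self.fppi_points):
            raise ValueError("curve length mismatch")


def _validate_box(box: Box) -> None:
    z0, z1, y0, y1, x0, x1 = box
    if not (z1 > z0 and y1 > y0 and x1 > x0):
        raise ValueError(f"degenerate box {box}")


def iou(box_a: Box, box_b: Box) -> float:
    """Intersection over union of two half-open voxel boxes."""
    _validate_box(box_a)
    _validate_box(box_b)
    inter = 1
    for i in range(3):
        lo = max(box_a[2 * i], box_b[2 * i])
        hi = min(box_a[2 * i + 1], box_b[2 * i + 1])
        if hi <= lo:
            return 0.0
        inter *= hi - lo
    vol_a = np.prod([box_a[2 * i + 1] - box_a[2 * i] for i in range(3)])
    vol_b = np.prod([box_b[2 * i + 1] - box_b[2 * i] for i in range(3)])
    return float(inter / (vol_a + vol_b - inter))


def match_detections(detections, gt_boxes: list[Box],
                     iou_threshold: float = DEFAULT_IOU_THRESHOLD,
                     ) -> list[MatchRecord]:
    """Greedy one-to-one matching of one image's detections to its GT boxes.

    Detections are visited in descending score order (score ties broken by
    higher best-IoU, then input order); each takes the unmatched GT box of
    highest IoU >= threshold, else is recorded as a non-match.

    ``detections`` is a sequence of objects with ``.score`` and ``.box``.
    """
    for b in gt_boxes:
        _validate_box(b)
    best = []
    for idx, d in enumerate(detections):
        ious = [iou(d.box, g) for g in gt_boxes]
        j = int(np.argmax(ious)) if ious else -1
        best.append((d, idx, max(ious) if ious else 0.0))
    order = sorted(best, key=lambda t: (-t[0].score, -t[2], t[1]))
    taken = [False] * len(gt_boxes)
    records = []
    for d, _idx, _b in order:
        cand = [(iou(d.box, g), j) for j, g in enumerate(gt_boxes)
                if not taken[j]]
        cand = [(v, j) for v, j in cand if v >= iou_threshold]
        if cand:
            _v, j = max(cand, key=lambda t: (t[0], -t[1]))
            taken[j] = True
            records.append(MatchRecord(score=d.score, is_tp=True))
        else:
            records.append(MatchRecord(score=d.score, is_tp=False))
    return records


def froc(records: list[MatchRecord], n_gt: int, n_images: int,
         fppi_points: tuple[float, ...] = DEFAULT_FPPI_POINTS) -> FROCResult:
    """FROC curve over all distinct score thresholds.

    At threshold t, TP counts matched records with score >= t and FP counts
    unmatched ones; the TPR reported at a target FPPI value f is the highest
    TPR among thresholds whose FPPI does not exceed f (0 if none qualifies).
    mean FROC is the mean of those TPRs.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if n_gt < 1:
        raise ValueError("n_gt must be >= 1")
    if not records:
        return FROCResult(fppi_points=tuple(fppi_points),
                          tpr_at_fppi=(0.0,) * len(fppi_points),
                          mean_froc=0.0, n_images=n_images, n_gt=n_gt)
    scores = np.array([r.score for r in records], dtype=np.float64)
    tps = np.array([r.is_tp for r in records], dtype=bool)
    order = np.argsort(-scores, kind="stable")
    scores, tps = scores[order], tps[order]
    cum_tp = np.cumsum(tps)
    cum_fp = np.cumsum(~tps)
    # last index of each distinct score = operating point of threshold==score
    last = np.nonzero(np.diff(scores, append=np.nan))[0]
    tpr = cum_tp[last] / n_gt            # TPR, non-decreasing as t drops
    fppi = cum_fp[last] / n_images       # FPPI, non-decreasing as t drops
    out = []
    for f in fppi_points:
        ok = fppi <= f
        out.append(float(tpr[ok].max()) if ok.any() else 0.0)
    return FROCResult(fppi_points=tuple(fppi_points), tpr_at_fppi=tuple(out),
                      mean_froc=float(np.mean(out)), n_images=n_images, n_gt=n_gt)


def pooled_froc(per_image: list[tuple[list[MatchRecord], int]],
                fppi_points: tuple[float, ...] = DEFAULT_FPPI_POINTS) -> FROCResult:
    """FROC over a list of per-image (records, n_gt) pairs."""
    records = [r for recs, _ in per_image for r in recs]
    n_gt = sum(g for _, g in per_image)
    return froc(records, n_gt=n_gt, n_images=len(per_image), fppi_points=fppi_points)


def bootstrap_ci(per_image: list[tuple[list[MatchRecord], int]],
                 n_reps: int = DEFAULT_BOOTSTRAP_REPS,
                 level: float = DEFAULT_CI_LEVEL,
                 seed: int = 0,
                 fppi_points: tuple[float, ...] = DEFAULT_FPPI_POINTS) -> FROCResult:
    """Mean FROC with a percentile bootstrap CI, resampling whole images.

    Keeping each image's records together preserves the per-image FPPI
    semantics under resampling.  Replicates whose resample holds no GT box
    are counted as mean FROC 0.
    """
    if not per_image:
        raise ValueError("need at least one image")
    point = pooled_froc(per_image, fppi_points)
    rng = np.random.default_rng(seed)
    n = len(per_image)
    reps = np.empty(n_reps)
    for r in range(n_reps):
        idx = rng.integers(0, n, size=n)
        sample = [per_image[i] for i in idx]
        if sum(g for _, g in sample) == 0:
            reps[r] = 0.0
        else:
            reps[r] = pooled_froc(sample, fppi_points).mean_froc
    lo, hi = np.percentile(reps, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    point.ci_lo, point.ci_hi = float(lo), float(hi)
    return point
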