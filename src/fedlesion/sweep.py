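"""Distributed empirical hyperparameter optimization (the "sweep").

After federated training, inference hyperparameters (minimum prediction
score, minimum object size) are tuned empirically.  Per-client FROC scores
cannot be aggregated — each client's curve rests on its own thresholds — so
instead every client evaluates each candidate value on its local validation
set and ships only *match records* (score, hit-or-miss flags) plus counts.
The server pools those records, computes one global FROC per candidate, and
selects the argmax.  Parameters are optimized sequentially because they are
interdependent: each selection is frozen into the configuration before the
next parameter is swept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .detector import ModelState, predict
from .fingerprint import Plan
from .metrics import (DEFAULT_FPPI_POINTS, DEFAULT_IOU_THRESHOLD, MatchRecord,
                      froc, match_detections)

MIN_SCORE = "min_score"
MIN_OBJECT_SIZE = "min_object_size"
PARAM_NAMES = (MIN_SCORE, MIN_OBJECT_SIZE)

#: default candidate grid for the score threshold
DEFAULT_SCORE_CANDIDATES = tuple(round(0.1 * i, 1) for i in range(1, 10))


@dataclass
class SweepParam:
    name: str
    candidates: tuple[float, ...]
    selected: float | None = None

    def __post_init__(self):
        if self.name not in PARAM_NAMES:
            raise ValueError(f"unknown sweep parameter {self.name!r}")
        if not self.candidates:
            raise ValueError("candidate list must be non-empty")
        self.candidates = tuple(sorted(self.candidates))


@dataclass
class SweepPayload:
    """One client's wire payload for one parameter: scores, match flags and
    counts per candidate — never voxels, boxes optional and omitted here."""

    institution_id: str
    param_name: str
    per_candidate: dict[float, tuple[list[MatchRecord], int, int]]  # records, n_gt, n_images


@dataclass
class SweepResult:
    selections: dict[str, float]
    froc_table: list[dict] = field(default_factory=list)  # param, candidate, mean_froc


def client_sweep_eval(state: ModelState, val_volumes, plan: Plan,
                      param: SweepParam, fixed_values: dict[str, float],
                      institution_id: str = "",
                      iou_threshold: float = DEFAULT_IOU_THRESHOLD,
                      candidates_by_image: dict | None = None) -> SweepPayload:
    """Evaluate every candidate value of one parameter on the local
    validation set, other parameters held at ``fixed_values``."""
    if not val_volumes:
        raise ValueError(f"institution {institution_id!r} has an empty validation set")
    if candidates_by_image is None:
        # proposals are model- and threshold-independent: compute once per image
        from .detector import propose_candidates
        candidates_by_image = {v.image_id: propose_candidates(v, plan)
                               for v in val_volumes}
    per_candidate = {}
    for value in param.candidates:
        cfg = dict(fixed_values)
        cfg[param.name] = value
        records: list[MatchRecord] = []
        n_gt = 0
        for vol in val_volumes:
            cands = candidates_by_image[vol.image_id]
            dets = predict(state, vol, plan,
                           min_score=cfg.get(MIN_SCORE, 0.0),
                           min_object_size=cfg.get(MIN_OBJECT_SIZE, 0.0),
                           candidates=cands)
            records.extend(match_detections(dets, [b.box for b in vol.boxes],
                                            iou_threshold=iou_threshold))
            n_gt += len(vol.boxes)
        per_candidate[value] = (records, n_gt, len(val_volumes))
    return SweepPayload(institution_id=institution_id, param_name=param.name,
                        per_candidate=per_candidate)


def server_sweep_select(payloads: list[SweepPayload], param: SweepParam,
                        fppi_points=DEFAULT_FPPI_POINTS,
                        ) -> tuple[float, list[dict]]:
    """Pool match records across institutions, compute the global FROC per
    candidate, select the argmax (ties -> smaller candidate value)."""
    if not payloads:
        raise ValueError("no sweep payloads")
    for p in payloads:
        missing = set(param.candidates) - set(p.per_candidate)
        if p.param_name != param.name or missing:
            raise ValueError(
                f"institution {p.institution_id!r} did not report candidate(s) "
                f"{sorted(missing)} for {param.name!r}")
    table = []
    best_value, best_score = None, -1.0
    for value in param.candidates:   # ascending: first argmax is the smallest
        records = [r for p in payloads for r in p.per_candidate[value][0]]
        n_gt = sum(p.per_candidate[value][1] for p in payloads)
        n_images = sum(p.per_candidate[value][2] for p in payloads)
        score = froc(records, n_gt=n_gt, n_images=n_images,
                     fppi_points=fppi_points).mean_froc if n_gt else 0.0
        table.append({"param": param.name, "candidate": value, "mean_froc": score})
        if score > best_score:
            best_value, best_score = value, score
    return best_value, table


def run_sweep(state: ModelState, institution_val_sets: dict[str, list],
              plan: Plan, params: list[SweepParam],
              iou_threshold: float = DEFAULT_IOU_THRESHOLD,
              fppi_points=DEFAULT_FPPI_POINTS,
              candidates_by_image: dict | None = None) -> SweepResult:
    """Sequential distributed sweep over ``params`` (in the given order).

    Unset parameters start from the permissive value 0 (no filtering) until
    their own sweep fixes them.
    """
    fixed: dict[str, float] = {name: 0.0 for name in PARAM_NAMES}
    result = SweepResult(selections={})
    for param in params:
        payloads = [client_sweep_eval(state, vols, plan, param, fixed,
                                      institution_id=inst,
                                      iou_threshold=iou_threshold,
                                      candidates_by_image=candidates_by_image)
                    for inst, vols in institution_val_sets.items()]
        selected, table = server_sweep_select(payloads, param, fppi_points)
        param.selected = selected
        fixed[param.name] = selected
        result.selections[param.name] = selected
        result.froc_table.extend(table)
    return result


def default_sweep_params(plan: Plan, box_volumes) -> list[SweepParam]:
    """min_score over 0.1..0.9 then min_object_size over {0, p10, p25, p50}
    of the training box volumes (from the global fingerprint)."""
    import numpy as np

    vols = np.asarray(list(box_volumes), dtype=float)
    sizes = (0.0, *(float(np.percentile(vols, q)) for q in (10, 25, 50)))
    return [SweepParam(MIN_SCORE, DEFAULT_SCORE_CANDIDATES),
            SweepParam(MIN_OBJECT_SIZE, tuple(sorted(set(sizes))))]
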