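"""End-to-end in-process federated experiment orchestration.

Pipeline (one process plays server and all virtual institutions):

1. every institution computes a local data fingerprint; the server
   aggregates them (syn or nosyn) and derives the training plan;
2. R global rounds: broadcast weights, each client runs E local epochs with
   its strategy's penalty term, the server aggregates (FedAvg / FedDC
   daisy-chaining) and updates mu for adaptive schedules;
3. the distributed hyperparameter sweep selects min_score and
   min_object_size on held-out local validation splits;
4. FROC with bootstrap CIs is computed per institution and pooled, on the
   validation and test sets, at the selected hyperparameters.

Everything is deterministic given the config seed: per-round/per-client
training seeds, the fingerprint draw and the bootstrap are all derived from
it by hashing.  The ``centralized`` strategy runs the identical pipeline
with the clients' pools merged into one institution and no aggregation
step, giving the single-site baseline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import detector, fingerprint, strategies, sweep
from .detector import ModelState, MoonConfig, ProxConfig, TrainConfig
from .metrics import (DEFAULT_BOOTSTRAP_REPS, DEFAULT_CI_LEVEL,
                      DEFAULT_FPPI_POINTS, DEFAULT_IOU_THRESHOLD, FROCResult,
                      bootstrap_ci, match_detections)
from .strategies import (CENTRALIZED, FEDDC, FEDMOON, FEDPROX, RoundHistory,
                         RoundRecord, StrategyConfig, fedavg_aggregate,
                         feddc_step, update_mu)
from .synthdata import FederatedDataset, derive_seed

logger = logging.getLogger("fedlesion")


@dataclass
class EvaluationConfig:
    iou_threshold: float = DEFAULT_IOU_THRESHOLD
    fppi_points: tuple[float, ...] = DEFAULT_FPPI_POINTS
    bootstrap_reps: int = DEFAULT_BOOTSTRAP_REPS
    ci_level: float = DEFAULT_CI_LEVEL


@dataclass
class ExperimentConfig:
    rounds: int = 10                 # R global rounds
    local_epochs: int = 5            # E local epochs per round
    strategy: StrategyConfig = field(default_factory=StrategyConfig)
    fingerprint_method: str = fingerprint.NOSYN
    train: TrainConfig = field(default_factory=TrainConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    validation_fraction: float = 0.1  # held out from each client's train set
    seed: int = 0

    def __post_init__(self):
        if self.rounds < 1 or self.local_epochs < 0:
            raise ValueError("need rounds >= 1 and local_epochs >= 0")
        if self.fingerprint_method not in (fingerprint.SYN, fingerprint.NOSYN):
            raise ValueError("fingerprint_method must be 'syn' or 'nosyn'")
        # E is carried by the training config so local_train sees one source
        self.train.epochs = self.local_epochs


@dataclass
class ExperimentResult:
    history: RoundHistory
    final_state: ModelState
    plan: fingerprint.Plan
    sweep_result: sweep.SweepResult
    froc: dict[str, dict[str, FROCResult]]   # {"validation"/"test": {inst or "pooled": ...}}
    provenance: dict

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "provenance": self.provenance,
            "rounds": [{"round": r.round, "loss": r.loss, "mu": r.mu,
                        "client_losses": r.client_losses,
                        "client_sizes": r.client_sizes}
                       for r in self.history.records],
            "plan": asdict(self.plan),
            "sweep": {"selections": self.sweep_result.selections,
                      "froc_table": self.sweep_result.froc_table},
            "froc": {split: {k: asdict(v) for k, v in d.items()}
                     for split, d in self.froc.items()},
            "model": {"descriptor": self.final_state.descriptor(),
                      "weight_norm": float(np.linalg.norm(self.final_state.w))},
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class _Client:
    institution_id: str
    fit_volumes: list
    val_volumes: list
    test_volumes: list
    candidates: list = field(default_factory=list)        # pooled over fit volumes
    state: ModelState | None = None

    @property
    def n_samples(self) -> int:
        return len(self.fit_volumes)


def _split_validation(train_volumes, fraction: float, seed: int):
    """Deterministic held-out validation split (at least one image each)."""
    n = len(train_volumes)
    n_val = max(1, round(fraction * n)) if n > 1 else 0
    order = np.random.default_rng(seed).permutation(n)
    val_idx = set(order[:n_val].tolist())
    fit = [v for i, v in enumerate(train_volumes) if i not in val_idx]
    val = [v for i, v in enumerate(train_volumes) if i in val_idx]
    return fit, val


def _build_clients(ds: FederatedDataset, cfg: ExperimentConfig,
                   plan: fingerprint.Plan) -> list[_Client]:
    clients = []
    insts = ds.institution_ids()
    if cfg.strategy.name == CENTRALIZED:
        train = [v for i in insts for v in ds.train_volumes(i)]
        test = [v for i in insts for v in ds.test_volumes(i)]
        # keep the original id for a single-site dataset so all derived seeds
        # coincide with the single-client federated run
        name = insts[0] if len(insts) == 1 else "central"
        groups = [(name, train, test)]
    else:
        groups = [(i, ds.train_volumes(i), ds.test_volumes(i)) for i in insts]
    for inst, train, test in groups:
        fit, val = _split_validation(train, cfg.validation_fraction,
                                     derive_seed(cfg.seed, "valsplit", inst))
        cands = [c for v in fit for c in detector.propose_candidates(
            v, plan, match_iou=cfg.evaluation.iou_threshold)]
        clients.append(_Client(institution_id=inst, fit_volumes=fit,
                               val_volumes=val, test_volumes=test,
                               candidates=cands))
    return clients


def run_round(round_index: int, global_w: np.ndarray, clients: list[_Client],
              cfg: ExperimentConfig, mu: float) -> tuple[np.ndarray, RoundRecord]:
    """One global round: broadcast, local training, aggregation.

    For FedAvg/FedProx/FedMOON every client starts from the broadcast global
    weights; for FedDC clients keep their own models between rounds and the
    server either daisy-chains (permutes) or FedAvg-aggregates them.  For the
    centralized baseline the single client's weights simply carry over.
    Returns the new global weight vector (for FedDC, the FedAvg mean of the
    per-client models, used for reporting) and the round record.
    """
    name = cfg.strategy.name
    client_losses, client_sizes, new_ws = [], [], []
    for k, client in enumerate(clients):
        if name == FEDDC or name == CENTRALIZED:
            start_w = client.state.w if client.state is not None else global_w
        else:
            start_w = global_w
        state = ModelState(w=start_w.copy())
        prox = moon = None
        if name == FEDPROX:
            prox = ProxConfig(mu=mu, w_global=global_w)
        elif name == FEDMOON:
            moon = MoonConfig(mu=mu, tau=cfg.strategy.tau, w_global=global_w)
        train_seed = derive_seed(cfg.seed, "round", round_index, client.institution_id)
        new_state, losses = detector.local_train(
            state, client.candidates, cfg.train, seed=train_seed,
            prox_cfg=prox, moon_cfg=moon)
        client.state = new_state
        new_ws.append(new_state.w)
        client_losses.append(losses[-1] if losses else float("nan"))
        client_sizes.append(client.n_samples)

    pairs = list(zip(new_ws, client_sizes))
    if name == CENTRALIZED:
        new_global = new_ws[0]
    elif name == FEDDC:
        routed = feddc_step(round_index, cfg.strategy, pairs,
                            seed=derive_seed(cfg.seed, "daisy", round_index))
        for client, w in zip(clients, routed):
            client.state = ModelState(w=w)
        new_global = fedavg_aggregate(pairs)
    else:
        new_global = fedavg_aggregate(pairs)
        for client in clients:
            client.state = ModelState(w=new_global.copy())

    total = sum(client_sizes)
    ell = float(sum(l * n for l, n in zip(client_losses, client_sizes)) / total)
    record = RoundRecord(round=round_index, loss=ell, mu=mu,
                         client_losses=client_losses, client_sizes=client_sizes)
    logger.info("round %d: loss=%.4f mu=%.4g |w|=%.3f",
                round_index, ell, mu, float(np.linalg.norm(new_global)))
    return new_global, record


def _evaluate_split(clients: list[_Client], which: str, state: ModelState,
                    plan: fingerprint.Plan, selections: dict[str, float],
                    cfg: EvaluationConfig, seed: int) -> dict[str, FROCResult]:
    per_inst: dict[str, FROCResult] = {}
    pooled: list[tuple[list, int]] = []
    for client in clients:
        volumes = client.val_volumes if which == "validation" else client.test_volumes
        per_image = []
        for vol in volumes:
            dets = detector.predict(state, vol, plan,
                                    min_score=selections.get(sweep.MIN_SCORE, 0.0),
                                    min_object_size=selections.get(sweep.MIN_OBJECT_SIZE, 0.0))
            recs = match_detections(dets, [b.box for b in vol.boxes],
                                    iou_threshold=cfg.iou_threshold)
            per_image.append((recs, len(vol.boxes)))
        pooled.extend(per_image)
        if per_image and sum(g for _, g in per_image) > 0:
            per_inst[client.institution_id] = bootstrap_ci(
                per_image, n_reps=cfg.bootstrap_reps, level=cfg.ci_level,
                seed=derive_seed(seed, "boot", which, client.institution_id),
                fppi_points=cfg.fppi_points)
    if pooled and sum(g for _, g in pooled) > 0:
        per_inst["pooled"] = bootstrap_ci(
            pooled, n_reps=cfg.bootstrap_reps, level=cfg.ci_level,
            seed=derive_seed(seed, "boot", which, "pooled"),
            fppi_points=cfg.fppi_points)
    return per_inst


def run_experiment(cfg: ExperimentConfig, ds: FederatedDataset,
                   results_path: str | Path | None = None) -> ExperimentResult:
    """Fingerprint -> plan -> R federated rounds -> sweep -> FROC evaluation."""
    insts = ds.institution_ids()
    stage = "fingerprint"
    try:
        locals_ = [fingerprint.compute_local_fingerprint(
            i, ds.train_volumes(i), cfg.fingerprint_method) for i in insts]
        gfp = fingerprint.build_global_fingerprint(
            locals_, cfg.fingerprint_method, seed=derive_seed(cfg.seed, "syn"))
        stage = "planning"
        plan = fingerprint.derive_plan(gfp)

        stage = "training"
        clients = _build_clients(ds, cfg, plan)
        global_w = detector.init_model(derive_seed(cfg.seed, "init")).w
        history = RoundHistory()
        mu = cfg.strategy.mu
        for r in range(1, cfg.rounds + 1):
            global_w, record = run_round(r, global_w, clients, cfg, mu)
            history.append(record)
            mu = update_mu(cfg.strategy, history)
        final_state = ModelState(w=global_w)

        stage = "sweep"
        val_sets = {c.institution_id: c.val_volumes for c in clients if c.val_volumes}
        box_volumes = [v for fp in gfp.image_fingerprints for v in fp.box_volumes]
        params = sweep.default_sweep_params(plan, box_volumes)
        sweep_result = sweep.run_sweep(final_state, val_sets, plan, params,
                                       iou_threshold=cfg.evaluation.iou_threshold,
                                       fppi_points=cfg.evaluation.fppi_points)

        stage = "evaluation"
        froc_out = {which: _evaluate_split(clients, which, final_state, plan,
                                           sweep_result.selections,
                                           cfg.evaluation, cfg.seed)
                    for which in ("validation", "test")}
    except Exception as err:
        raise RuntimeError(f"experiment failed in stage {stage!r}: {err}") from err

    result = ExperimentResult(
        history=history, final_state=final_state, plan=plan,
        sweep_result=sweep_result, froc=froc_out,
        provenance={"seed": cfg.seed, "rounds": cfg.rounds,
                    "local_epochs": cfg.local_epochs,
                    "strategy": asdict(cfg.strategy),
                    "fingerprint_method": cfg.fingerprint_method,
                    "n_institutions": len(insts),
                    "loss": cfg.train.loss})
    if results_path is not None:
        result.to_json(results_path)
    return result
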