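"""Federated aggregation strategies and adaptive-mu schedules.

Server side: FedAvg (sample-count-weighted parameter averaging) and FedDC
(daisy chaining — periodic random permutation of whole client models instead
of averaging).  Client side: the FedProx proximal term and the MOON
model-contrastive term, both scaled by mu; mu can follow loss-driven
schedules that react to the aggregated round loss ell_r:

========== =========================================================
fixed       mu constant
every_exp   mu /= 2 if ell_r < ell_{r-1}, else mu *= 2
every2nd    mu -= 0.1 if ell_r < ell_{r-1} and ell_{r-1} < ell_{r-2},
            else mu += 0.1
every2nd_exp  halve under the two-decrease condition, else double
========== =========================================================

ell_r is the sample-count-weighted mean of the clients' final-local-epoch
base losses.  mu is clamped to [MU_MIN, MU_MAX]; before the schedule's
condition has enough history it leaves mu unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FEDAVG = "fedavg"
FEDPROX = "fedprox"
FEDMOON = "fedmoon"
FEDDC = "feddc"
CENTRALIZED = "centralized"
STRATEGIES = (FEDAVG, FEDPROX, FEDMOON, FEDDC, CENTRALIZED)

MU_SCHEDULES = ("fixed", "every2nd", "every_exp", "every2nd_exp")

MU_MIN = 1e-4
MU_MAX = 1e2
MU_ADDITIVE_STEP = 0.1


@dataclass
class StrategyConfig:
    name: str = FEDAVG
    mu: float = 0.0
    tau: float = 0.5
    mu_schedule: str = "fixed"
    daisy_interval: int = 5          # b: permutation every b-th round
    mu_bounds: tuple[float, float] = (MU_MIN, MU_MAX)

    def __post_init__(self):
        if self.name not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.name!r}")
        if self.mu < 0 or self.tau <= 0 or self.daisy_interval < 1:
            raise ValueError("need mu >= 0, tau > 0, daisy_interval >= 1")
        if self.mu_schedule not in MU_SCHEDULES:
            raise ValueError(f"unknown mu schedule {self.mu_schedule!r}")


@dataclass
class RoundRecord:
    round: int
    loss: float                  # ell_r
    mu: float                    # mu used this round
    client_losses: list[float]
    client_sizes: list[int]


@dataclass
class RoundHistory:
    records: list[RoundRecord] = field(default_factory=list)

    def losses(self) -> list[float]:
        return [r.loss for r in self.records]

    def append(self, record: RoundRecord) -> None:
        self.records.append(record)


def fedavg_aggregate(client_states: list[tuple[np.ndarray, int]]) -> np.ndarray:
    """Sample-count-weighted average of client parameter vectors.

    Weights are normalized first (n_k / sum n), so a single client's vector
    passes through bitwise unchanged.
    """
    if not client_states:
        raise ValueError("no client states")
    shapes = {w.shape for w, _ in client_states}
    if len(shapes) != 1:
        raise ValueError(f"mismatched parameter shapes: {shapes}")
    total = sum(n for _, n in client_states)
    if total <= 0:
        raise ValueError("total sample count must be positive")
    out = np.zeros_like(client_states[0][0])
    for w, n in client_states:
        out += (n / total) * w
    return out


def fedprox_term(w_local: np.ndarray, w_global: np.ndarray, mu: float) -> float:
    """(mu/2) * ||w_local - w_global||_2^2."""
    if w_local.shape != w_global.shape:
        raise ValueError("parameter shape mismatch")
    delta = w_local - w_global
    return float(0.5 * mu * np.dot(delta, delta))


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero-norm vector")
    return float(np.dot(a, b) / (na * nb))


def moon_term(z: np.ndarray, z_glob: np.ndarray, z_prev: np.ndarray,
              mu: float, tau: float) -> float:
    """Model-contrastive loss:
    -mu * log[ exp(sim(z,z_glob)/tau) / (exp(sim(z,z_glob)/tau)
                                         + exp(sim(z,z_prev)/tau)) ].

    Always positive; decreasing in sim(z, z_glob), increasing in
    sim(z, z_prev).  Similarity is cosine.
    """
    if not (z.shape == z_glob.shape == z_prev.shape):
        raise ValueError("representation dimension mismatch")
    sim_g = _cosine(z, z_glob)
    sim_p = _cosine(z, z_prev)
    return float(mu * np.log1p(np.exp((sim_p - sim_g) / tau)))


def update_mu(cfg: StrategyConfig, history: RoundHistory) -> float:
    """Next round's mu from the loss history, clamped to cfg.mu_bounds.

    With fewer completed rounds than the schedule's condition references,
    mu is returned unchanged (conservative start, not the else-branch).
    """
    mu = history.records[-1].mu if history.records else cfg.mu
    losses = history.losses()
    sched = cfg.mu_schedule
    if sched == "fixed":
        return mu
    if sched == "every_exp":
        if len(losses) < 2:
            return mu
        mu = mu / 2 if losses[-1] < losses[-2] else mu * 2
    else:  # every2nd, every2nd_exp: two consecutive decreases
        if len(losses) < 3:
            return mu
        decreasing = losses[-1] < losses[-2] and losses[-2] < losses[-3]
        if sched == "every2nd":
            # additive schedule is floored at 0 rather than the multiplicative
            # lower bound, so mu can switch the penalty fully off
            mu = mu - MU_ADDITIVE_STEP if decreasing else mu + MU_ADDITIVE_STEP
            return float(min(max(mu, 0.0), cfg.mu_bounds[1]))
        mu = mu / 2 if decreasing else mu * 2
    lo, hi = cfg.mu_bounds
    return float(min(max(mu, lo), hi))


def feddc_step(round_index: int, cfg: StrategyConfig,
               client_states: list[tuple[np.ndarray, int]],
               seed: int) -> list[np.ndarray]:
    """One FedDC server step for (1-based) global round r.

    If r mod b == 0: a seeded uniform-random permutation routes whole client
    weight vectors between institutions — no averaging, the multiset of
    models is conserved.  Otherwise every client receives the FedAvg
    aggregate.
    """
    if not client_states:
        raise ValueError("no client states")
    if round_index % cfg.daisy_interval == 0:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(client_states))
        return [client_states[j][0].copy() for j in perm]
    agg = fedavg_aggregate(client_states)
    return [agg.copy() for _ in client_states]
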