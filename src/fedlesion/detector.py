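"""Candidate-proposal + scoring detector, CPU-trainable in seconds.

The detector factors object detection into two stages that together stand in
for a full anchor-based 3D detector at desk scale:

1. *Proposal*: scale-normalized Laplacian-of-Gaussian blob detection at the
   plan's candidate scales, after plan-driven normalization (percentile
   clipping + z-scoring).  Each local maximum becomes a cubic candidate box
   with a 6-dimensional feature vector.
2. *Scoring*: a small multilayer perceptron (hidden widths 32 and 16) maps
   candidate features to a lesion probability.  The penultimate activation
   (dim 16) is the representation ``z`` used by model-contrastive federated
   training; the parameters round-trip losslessly through one flat vector,
   the unit exchanged between federation clients and server.

Training supports the two class-imbalance objectives — focal loss and hard
negative mining (HNM) — plus the optional proximal (FedProx) and
model-contrastive (MOON) penalty terms added by federated strategies.
Gradients are analytic; everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .fingerprint import Plan
from .metrics import iou
from .synthdata import AnnotatedVolume

#: probability clamp for loss evaluation
SCORE_EPS = 1e-7
#: candidate feature layout (standardized per volume)
FEATURE_NAMES = ("log_response", "local_mean", "local_std",
                 "scale", "center_intensity", "box_volume")
N_FEATURES = len(FEATURE_NAMES)
#: minimum scale-normalized LoG response for a candidate; low enough that
#: noise maxima survive as negatives — the class imbalance focal loss and
#: hard negative mining exist to handle
RESPONSE_THRESHOLD = 0.1
#: cap on candidates per scale per volume
MAX_CANDIDATES_PER_SCALE = 50
#: overlap at which cross-scale candidates are considered the same blob
SCALE_NMS_IOU = 0.3
#: IoU at or above which a candidate counts as positive (matches evaluation)
MATCH_IOU = 0.1


# ---------------------------------------------------------------------------
# Candidate proposal
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Candidate:
    image_id: str
    box: tuple[int, int, int, int, int, int]
    feature_vector: np.ndarray
    iou_with_gt: float
    is_positive: bool


@dataclass(frozen=True)
class Detection:
    image_id: str
    box: tuple[int, int, int, int, int, int]
    score: float

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0,1]")


def normalize_image(image: np.ndarray, plan: Plan) -> np.ndarray:
    """Plan-driven preprocessing: clip to [clip_lo, clip_hi], then z-score."""
    clipped = np.clip(image, plan.clip_lo, plan.clip_hi)
    std = plan.norm_std if plan.norm_std > 0 else 1.0
    return (clipped - plan.norm_mean) / std


def _cube_box(center, half, shape):
    box = []
    for c, s in zip(center, shape):
        lo = max(0, int(round(c - half)))
        hi = min(s, int(round(c + half)))
        if hi <= lo:  # degenerate after clipping: widen to one voxel
            lo, hi = max(0, min(lo, s - 1)), max(1, min(lo + 1, s))
        box.extend([lo, hi])
    return tuple(box)


def propose_candidates(volume: AnnotatedVolume, plan: Plan,
                       match_iou: float = MATCH_IOU) -> list[Candidate]:
    """Multi-scale LoG blob candidates on the plan-normalized volume.

    For each plan scale r the scale-normalized response -sigma^2 * LoG
    (sigma = r/sqrt(3), the blob-matched width) is computed; 3x3x3 local
    maxima above RESPONSE_THRESHOLD become cubic boxes of side 2r.  The
    strongest MAX_CANDIDATES_PER_SCALE maxima per scale are kept, then the
    usual cross-scale selection: where candidates from different scales
    overlap (IoU >= SCALE_NMS_IOU) only the strongest response survives, so
    one blob yields one candidate.  Feature vectors are standardized across
    the volume's candidate set.
    """
    img = normalize_image(volume.image, plan)
    raw: list[tuple] = []
    for scale in plan.candidate_scales:
        sigma = scale / math.sqrt(3.0)
        resp = -(sigma ** 2) * ndimage.gaussian_laplace(img, sigma)
        peaks = (resp == ndimage.maximum_filter(resp, size=3)) & (resp > RESPONSE_THRESHOLD)
        coords = np.argwhere(peaks)
        if len(coords) > MAX_CANDIDATES_PER_SCALE:
            strengths = resp[tuple(coords.T)]
            coords = coords[np.argsort(-strengths)[:MAX_CANDIDATES_PER_SCALE]]
        for c in coords:
            box = _cube_box(c, scale, img.shape)
            z0, z1, y0, y1, x0, x1 = box
            patch = img[z0:z1, y0:y1, x0:x1]
            raw.append((box, np.array([
                resp[tuple(c)], patch.mean(), patch.std(), scale,
                img[tuple(c)], float(np.prod([z1 - z0, y1 - y0, x1 - x0]))])))
    if not raw:
        return []
    # cross-scale blob selection: strongest response wins among overlaps
    raw.sort(key=lambda t: -t[1][0])
    kept: list[tuple] = []
    for box, f in raw:
        if all(iou(box, kbox) < SCALE_NMS_IOU for kbox, _ in kept):
            kept.append((box, f))
    raw = kept
    feats = np.stack([f for _, f in raw])
    mu, sd = feats.mean(axis=0), feats.std(axis=0)
    sd[sd < 1e-8] = 1.0
    feats = (feats - mu) / sd
    gt = [b.box for b in volume.boxes]
    out = []
    for (box, _), fv in zip(raw, feats):
        best = max((iou(box, g) for g in gt), default=0.0)
        out.append(Candidate(image_id=volume.image_id, box=box, feature_vector=fv,
                             iou_with_gt=best, is_positive=best >= match_iou))
    return out


# ---------------------------------------------------------------------------
# Scoring model: 2-hidden-layer MLP with a flat parameter vector
# ---------------------------------------------------------------------------

@dataclass
class ModelState:
    """Flat parameter vector plus the architecture that interprets it."""

    w: np.ndarray
    n_features: int = N_FEATURES
    hidden: tuple[int, int] = (32, 16)

    @property
    def representation_dim(self) -> int:
        return self.hidden[1]

    def copy(self) -> "ModelState":
        return replace(self, w=self.w.copy())

    def descriptor(self) -> dict:
        return {"n_features": self.n_features, "hidden": list(self.hidden),
                "n_params": int(self.w.size)}


def _shapes(n_features, hidden):
    h1, h2 = hidden
    return [(n_features, h1), (h1,), (h1, h2), (h2,), (h2, 1), (1,)]


def n_parameters(n_features: int = N_FEATURES, hidden=(32, 16)) -> int:
    return sum(int(np.prod(s)) for s in _shapes(n_features, hidden))


def init_model(seed: int, n_features: int = N_FEATURES,
               hidden: tuple[int, int] = (32, 16)) -> ModelState:
    """He-style initialization; biases zero."""
    rng = np.random.default_rng(seed)
    parts = []
    for shape in _shapes(n_features, hidden):
        if len(shape) == 2:
            parts.append(rng.normal(0.0, math.sqrt(2.0 / shape[0]), size=shape).ravel())
        else:
            parts.append(np.zeros(shape))
    return ModelState(w=np.concatenate(parts), n_features=n_features, hidden=hidden)


def _unpack(state: ModelState):
    mats, pos = [], 0
    for shape in _shapes(state.n_features, state.hidden):
        size = int(np.prod(shape))
        mats.append(state.w[pos:pos + size].reshape(shape))
        pos += size
    if pos != state.w.size:
        raise ValueError("parameter vector length does not match architecture")
    return mats  # W1, b1, W2, b2, w3, b3


def get_parameters(state: ModelState) -> np.ndarray:
    return state.w.copy()


def set_parameters(state: ModelState, w: np.ndarray) -> ModelState:
    if w.shape != state.w.shape:
        raise ValueError("parameter shape mismatch")
    return replace(state, w=np.asarray(w, dtype=np.float64).copy())


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def forward(state: ModelState, X: np.ndarray):
    """Returns (p, cache); cache feeds backprop and holds z = h2."""
    W1, b1, W2, b2, w3, b3 = _unpack(state)
    a1 = X @ W1 + b1
    h1 = np.maximum(a1, 0.0)
    a2 = h1 @ W2 + b2
    h2 = np.maximum(a2, 0.0)
    s = h2 @ w3 + b3
    p = _sigmoid(s[:, 0])
    return p, (X, a1, h1, a2, h2)


def predict_scores(state: ModelState, X: np.ndarray) -> np.ndarray:
    return forward(state, X)[0]


def representation(state: ModelState, X: np.ndarray) -> np.ndarray:
    """z: penultimate activation, one row per sample."""
    return forward(state, X)[1][4]


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FocalConfig:
    alpha: float = 0.25
    gamma: float = 2.0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0 or self.gamma < 0:
            raise ValueError("need alpha in [0,1] and gamma >= 0")


@dataclass(frozen=True)
class HNMConfig:
    neg_pos_ratio: int = 3

    def __post_init__(self):
        if self.neg_pos_ratio < 1:
            raise ValueError("neg_pos_ratio must be >= 1")


def focal_loss(p, y, cfg: FocalConfig):
    """-alpha_t (1 - p_t)^gamma log(p_t) with p_t = p if y=1 else 1-p.

    Scores outside (0,1) are clamped to [SCORE_EPS, 1-SCORE_EPS].  Accepts
    scalars or arrays.
    """
    p = np.clip(np.asarray(p, dtype=np.float64), SCORE_EPS, 1.0 - SCORE_EPS)
    y = np.asarray(y)
    pt = np.where(y == 1, p, 1.0 - p)
    at = np.where(y == 1, cfg.alpha, 1.0 - cfg.alpha)
    out = -at * (1.0 - pt) ** cfg.gamma * np.log(pt)
    return float(out) if out.ndim == 0 else out


def _cross_entropy(p, y):
    p = np.clip(p, SCORE_EPS, 1.0 - SCORE_EPS)
    return np.where(y == 1, -np.log(p), -np.log(1.0 - p))


def select_hard_negatives(neg_losses: np.ndarray, n_pos: int,
                          cfg: HNMConfig) -> np.ndarray:
    """Indices of the top neg_pos_ratio * max(n_pos, 1) negatives by loss."""
    neg_losses = np.asarray(neg_losses, dtype=np.float64)
    quota = cfg.neg_pos_ratio * max(n_pos, 1)
    if neg_losses.size <= quota:
        return np.arange(neg_losses.size)
    return np.sort(np.argsort(-neg_losses, kind="stable")[:quota])


def _focal_dlds(p, y, cfg: FocalConfig):
    """d(focal)/d(logit); reduces to 0.5*(p-y) at gamma=0, alpha=0.5."""
    pc = np.clip(p, SCORE_EPS, 1.0 - SCORE_EPS)
    pt = np.where(y == 1, pc, 1.0 - pc)
    at = np.where(y == 1, cfg.alpha, 1.0 - cfg.alpha)
    g = cfg.gamma
    if g == 0:
        dldpt = -at / pt
    else:
        dldpt = at * (g * (1.0 - pt) ** (g - 1.0) * np.log(pt)
                      - (1.0 - pt) ** g / pt)
    sgn = np.where(y == 1, 1.0, -1.0)
    return dldpt * sgn * pt * (1.0 - pt)


# ---------------------------------------------------------------------------
# Local training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    epochs: int = 5
    batch_size: int = 32
    learning_rate: float = 0.1
    loss: str = "hnm"            # hnm | focal
    focal: FocalConfig = field(default_factory=FocalConfig)
    hnm: HNMConfig = field(default_factory=HNMConfig)

    def __post_init__(self):
        if self.loss not in ("hnm", "focal"):
            raise ValueError("loss must be 'hnm' or 'focal'")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class ProxConfig:
    """FedProx: adds (mu/2)||w - w_global||^2 to the local objective."""

    mu: float
    w_global: np.ndarray


@dataclass
class MoonConfig:
    """MOON: model-contrastive penalty on the representation z.

    z_glob comes from the broadcast global weights on the current minibatch;
    z_prev from the client's previous-local-epoch snapshot.
    """

    mu: float
    tau: float
    w_global: np.ndarray


def _cosine_rows(a: np.ndarray, b: np.ndarray, eps: float = 1e-12):
    na = np.maximum(np.linalg.norm(a, axis=1), eps)
    nb = np.maximum(np.linalg.norm(b, axis=1), eps)
    return (a * b).sum(axis=1) / (na * nb)


def _moon_batch(z, z_glob, z_prev, mu, tau):
    """Per-sample MOON losses and d(loss)/dz."""
    eps = 1e-12
    sim_g = _cosine_rows(z, z_glob)
    sim_p = _cosine_rows(z, z_prev)
    delta = (sim_p - sim_g) / tau
    loss = mu * np.log1p(np.exp(delta))
    coef = mu * _sigmoid(delta)[:, None] / tau   # d loss / d(sim_p - sim_g)
    nz = np.maximum(np.linalg.norm(z, axis=1, keepdims=True), eps)

    def dcos_dz(u):
        nu = np.maximum(np.linalg.norm(u, axis=1, keepdims=True), eps)
        c = _cosine_rows(z, u)[:, None]
        return u / (nz * nu) - c * z / nz**2

    dz = coef * (dcos_dz(z_prev) - dcos_dz(z_glob))
    return loss, dz


def local_train(state: ModelState, candidates: list[Candidate],
                train_cfg: TrainConfig, seed: int,
                prox_cfg: ProxConfig | None = None,
                moon_cfg: MoonConfig | None = None,
                ) -> tuple[ModelState, list[float]]:
    """Minibatch SGD on the scoring head for ``train_cfg.epochs`` epochs.

    The objective per minibatch is the configured base loss (focal, or
    cross-entropy restricted to positives plus the hardest negatives) plus
    the optional FedProx and MOON penalties.  Returns the new state and the
    per-epoch mean *base* loss (penalties excluded), which drives the
    adaptive-mu schedules.  Deterministic given the seed.
    """
    X = np.stack([c.feature_vector for c in candidates])
    y = np.array([c.is_positive for c in candidates], dtype=np.float64)
    if train_cfg.epochs > 0 and (y.sum() == 0 or y.sum() == y.size):
        raise ValueError(
            "training needs at least one positive and one negative candidate; "
            "use an easier synthetic configuration (higher contrast / larger lesions)")
    rng = np.random.default_rng(seed)
    w = state.w.copy()
    glob_state = None
    if moon_cfg is not None:
        glob_state = set_parameters(state, moon_cfg.w_global)
    epoch_losses: list[float] = []
    n = X.shape[0]
    for _epoch in range(train_cfg.epochs):
        prev_state = set_parameters(state, w)  # previous-epoch snapshot for MOON
        order = rng.permutation(n)
        batch_losses, batch_sizes = [], []
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            cur = set_parameters(state, w)
            grad, base_loss = _batch_gradient(
                cur, X[idx], y[idx], train_cfg, prox_cfg, moon_cfg,
                glob_state, prev_state)
            w -= train_cfg.learning_rate * grad
            batch_losses.append(base_loss * len(idx))
            batch_sizes.append(len(idx))
        epoch_losses.append(float(np.sum(batch_losses) / np.sum(batch_sizes)))
    return set_parameters(state, w), epoch_losses


def _batch_gradient(state, Xb, yb, cfg: TrainConfig, prox_cfg, moon_cfg,
                    glob_state, prev_state):
    W1, b1, W2, b2, w3, b3 = _unpack(state)
    p, (X, a1, h1, a2, h2) = forward(state, Xb)
    m = len(yb)

    if cfg.loss == "focal":
        weights = np.ones(m)
        base = focal_loss(p, yb, cfg.focal)
        dlds = _focal_dlds(p, yb, cfg.focal)
    else:
        ce = _cross_entropy(p, yb)
        weights = np.zeros(m)
        pos = yb == 1
        weights[pos] = 1.0
        neg_idx = np.nonzero(~pos)[0]
        hard = select_hard_negatives(ce[neg_idx], int(pos.sum()), cfg.hnm)
        weights[neg_idx[hard]] = 1.0
        base = ce
        dlds = weights * (p - yb)
    denom = max(weights.sum(), 1.0)
    base_loss = float((weights * base).sum() / denom)
    ds = (dlds * (np.ones(m) if cfg.loss == "focal" else 1.0)) / (
        m if cfg.loss == "focal" else denom)

    dh2 = ds[:, None] @ w3.T
    if moon_cfg is not None:
        z_glob = representation(glob_state, Xb)
        z_prev = representation(prev_state, Xb)
        _mloss, dz = _moon_batch(h2, z_glob, z_prev, moon_cfg.mu, moon_cfg.tau)
        dh2 = dh2 + dz / m

    da2 = dh2 * (a2 > 0)
    dh1 = da2 @ W2.T
    da1 = dh1 * (a1 > 0)
    grads = [X.T @ da1, da1.sum(axis=0),
             h1.T @ da2, da2.sum(axis=0),
             h2.T @ ds[:, None], np.array([ds.sum()])]
    flat = np.concatenate([g.ravel() for g in grads])
    if prox_cfg is not None and prox_cfg.mu != 0.0:
        flat = flat + prox_cfg.mu * (state.w - prox_cfg.w_global)
    return flat, base_loss


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def predict(state: ModelState, volume: AnnotatedVolume, plan: Plan,
            min_score: float = 0.0, min_object_size: float = 0.0,
            candidates: list[Candidate] | None = None) -> list[Detection]:
    """Score proposals and filter by minimum score and box volume.

    ``candidates`` may be supplied to reuse precomputed proposals (they are
    model-independent).  Detections are sorted by descending score.
    """
    if candidates is None:
        candidates = propose_candidates(volume, plan)
    if not candidates:
        return []
    X = np.stack([c.feature_vector for c in candidates])
    scores = predict_scores(state, X)
    dets = [Detection(image_id=c.image_id, box=c.box, score=float(s))
            for c, s in zip(candidates, scores)
            if s >= min_score and _box_volume(c.box) >= min_object_size]
    return sorted(dets, key=lambda d: -d.score)


def _box_volume(box) -> int:
    z0, z1, y0, y1, x0, x1 = box
    return (z1 - z0) * (y1 - y0) * (x1 - x0)
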