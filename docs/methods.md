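# Methods

`fedlesion` simulates, in a single process, a federation of virtual
institutions that jointly train and configure a 3D lesion detector without
exchanging raw images. This note records the models and procedures the
package implements, the parameters that matter, and the choices made where
the design was genuinely open.

## Synthetic study conditions

The generator (`synthdata`) renders small 3D volumes that carry the
statistical structure federated lesion detection experiments depend on,
and nothing more:

- **Background**: i.i.d. Gaussian voxels, mean 100, σ = 10 (arbitrary
  intensity units).
- **Lesions**: axis-aligned ellipsoids (per-axis radii uniform in
  2.5–5 voxels) of additive contrast drawn uniformly from 3–50 units, each
  labeled malignant with probability `malignant_fraction`. The contrast
  floor sits *below* the blob-scale detection limit on purpose: a screening
  cohort contains lesions from invisible to obvious, and a benchmark in
  which every lesion is trivially findable saturates every strategy at
  mean FROC 1.0 and can discriminate nothing. Lesion placements that would
  overlap are resampled (up to 100 tries) so ground-truth boxes are
  unambiguous; the annotation is the tight bounding box of the ellipsoid
  support, half-open, zero-based, (z, y, x) order.
- **Manufacturer shift**: after lesion insertion the whole volume is mapped
  `v → scale·v + offset + N(0, noise_std)`, one parameter triple per
  manufacturer tag. This is the domain shift that drives the
  manufacturer-based non-IID scenario; the magnitudes are free parameters
  (25-unit offsets between institutions in the bundled configurations),
  since no canonical values exist for them.
- **Default volume**: 28×44×44 voxels at (2, 1, 1) mm spacing, two lesions
  — small enough that a full multi-strategy experiment battery runs on one
  CPU core in minutes, the problem scale all bundled experiments and the
  reproduction script use.

Determinism is end to end: per-image seeds are SHA-256 hashes of
(master seed, institution, split, index), recorded in the manifest, and a
dataset written twice is byte-identical (NIfTI gzip included).

What the generator does **not** emulate: anatomy and texture (background is
white noise), intensity physics (no HU calibration), spacing
heterogeneity within an institution, annotation noise, and lesion-count /
size correlations. Tests passing on these volumes therefore demonstrate
the correctness and behaviour of the *pipeline* — fingerprint aggregation,
partitioning, federated optimization, evaluation protocol — not clinical
detection performance.

## Data fingerprints and the plan

Each institution computes per-image properties (spacing, shape, intensity
statistics with 0.5th/99.5th percentile outlier bounds, box volumes,
labels, manufacturer). Per-image properties concatenate trivially into the
global fingerprint; the global *intensity distribution* does not, so two
aggregation routes are implemented:

- **nosyn** — every 10th voxel of each image (C-order flatten, stride 10
  from index 0) is pooled at the server; global statistics are recomputed
  from the pool. Accurate, but raw voxel values leave the institution.
- **syn** — each image is reduced to five scalars: mean, standard
  deviation, min, max, and a sample count; the server redraws that many
  values from the Gaussian N(mean, sd) truncated to [min, max] and pools
  the redraws. No voxel value crosses the wire. Sampling uses the inverse
  CDF on the truncated interval (exact truncation, deterministic cost,
  σ = 0 degenerates to copies of the mean); the per-image sample count is
  ceil(n_voxels/10) — matching the nosyn density so the two routes are
  comparable — capped at 10,000 to bound server memory. Global min/max are
  taken exactly as min(lower)/max(upper) over the specs rather than from
  the finite redraw.

Percentiles everywhere use linear interpolation between order statistics
(numpy's default), stated so independent oracles can match bit for bit.
Pooling is done in canonical image-id order, which makes global statistics
bitwise invariant to the order institutions report in. Image statistics
use all voxels; no foreground mask is applied (synthetic volumes have no
canonical mask, and this convention must be kept in mind when comparing
against planners that mask).

The plan derived from the global fingerprint is a deliberately small rule
base: target spacing = per-axis median of image spacings; clip range =
global 0.5th/99.5th percentiles; normalization mean/σ computed on the
clipped pool; candidate blob radii = equivalent-sphere radii
(3V/4π)^(1/3) at the 10th/50th/90th percentiles of annotated box volumes;
default minimum object size = 10th percentile of box volumes; default
minimum score 0.5.

## Partitioning scenarios

- **Label-based IID**: images (case label = malignant if any box is) are
  shuffled per label stratum and dealt round-robin, the deal continuing
  across strata, so per-institution label counts stay within one image of
  the even share and sizes within one of each other. Test pools are dealt
  the same way.
- **Manufacturer-based non-IID**: images route to the institution owning
  their manufacturer (train and test alike); quantity skew follows the
  manufacturer mix.
- **Dirichlet label skew**: per class, institution fractions are one draw
  X ~ Dir(α); image counts follow by largest-remainder rounding (remainder
  ties to the lower institution index). With the leave-one-out flag an
  extra institution receives the whole test pool and no training data. If
  a draw empties an institution, one image migrates from the largest one —
  the alternative (redrawing) would bias the realized fractions.

## Detector

A two-stage stand-in for an anchor-based 3D detector, sized to train in
seconds on a CPU:

1. **Proposal** — after plan-driven normalization, scale-normalized
   Laplacian-of-Gaussian responses (σ = r/√3 per plan radius r) are
   computed; 3×3×3 local maxima above a response threshold of 0.1 become
   cubic candidates of side 2r (top 50 per scale). Cross-scale selection
   keeps only the strongest response among candidates overlapping at
   IoU ≥ 0.3 — one blob, one candidate; without this, each lesion produces
   one near-duplicate per scale, and the duplicates surface as
   high-confidence false positives in any one-to-one evaluation. The
   response threshold sits low enough that noise maxima survive as
   negatives: the class imbalance is wanted, it is what focal loss and
   hard negative mining exist to handle. Each candidate carries six
   features (LoG response, local mean, local σ, scale, center intensity,
   box volume), standardized per volume. Candidates at IoU ≥ 0.1 with a
   ground-truth box are positives — the same threshold the evaluation
   uses.
2. **Scoring** — a perceptron with hidden widths 32 and 16 (ReLU) and a
   sigmoid output on the candidate features. The penultimate activation
   (dim 16) is the representation `z` used by the model-contrastive
   strategy; all parameters live in one flat vector (769 for the default
   architecture), the unit clients and server exchange. Gradients are
   analytic; training is plain minibatch SGD (batch 32, learning rate 0.1),
   seeded and deterministic.

Two imbalance objectives are available:

- **Focal loss** `−α_t (1−p_t)^γ log p_t`, p_t = p for positives and 1−p
  otherwise, α_t likewise α / 1−α; defaults α = 0.25, γ = 2. Scores are
  clamped to [1e−7, 1−1e−7] before the logarithm.
- **Hard negative mining** (the default): per minibatch, cross-entropy on
  all positives plus the top-loss negatives at a 3:1 negative:positive
  ratio (at least one quota when the batch has no positive).

## Federated strategies

One global round broadcasts the server weights, runs E local epochs per
client, and aggregates. Defaults are R = 10 rounds of E = 5 local epochs.

- **FedAvg**: sample-count-weighted mean, weights n_k/Σn normalized before
  the sum so a single client's vector passes through bitwise — which makes
  single-client FedAvg *exactly* the centralized baseline, a property the
  tests assert.
- **FedProx**: adds (μ/2)‖w − w_global‖² to the local objective (gradient
  μ(w − w_global) on the flat vector). Note the stability bound of
  explicit SGD: the proximal gradient step contracts only for
  μ < 2/learning-rate (μ < 20 at the defaults); larger μ oscillates and
  diverges. μ beyond that bound is accepted but not useful.
- **FedMOON**: subtracts μ·log softmax of cosine similarities at
  temperature τ, pulling the current minibatch representation z toward the
  broadcast model's z_glob and away from z_prev from the client's
  previous-local-epoch snapshot (in epoch 1 the snapshot is the broadcast
  model itself). The penalty's gradient flows through z only; z_glob and
  z_prev are constants.
- **FedDC (daisy chaining)**: every b-th round (r mod b = 0, rounds
  1-based, default b = 5) whole client models are routed through a seeded
  uniform-random permutation (identity permitted) with no averaging;
  other rounds fall back to FedAvg. Clients keep their own models between
  rounds.

Adaptive μ schedules react to the round loss ℓ_r, defined here as the
sample-count-weighted mean of clients' final-local-epoch *base* losses
(penalty terms excluded, so ℓ_r is comparable across strategies):
`every_exp` halves μ when ℓ_r < ℓ_{r−1} and doubles it otherwise;
`every2nd` subtracts 0.1 after two consecutive decreases and adds 0.1
otherwise; `every2nd_exp` halves/doubles under the two-decrease condition.
Multiplicative updates are clamped to [1e−4, 1e2]; the additive schedule is
floored at 0 so the penalty can switch fully off. Until a schedule's
condition has enough history (one or two completed rounds), μ stays
unchanged rather than taking the else-branch. Updates happen once per
global round.

## Evaluation

Greedy one-to-one matching in descending score order (ties by higher IoU,
then input order): each detection claims the unmatched ground-truth box of
highest IoU ≥ 0.1, else is a false positive. The FROC curve sweeps every
distinct score as a threshold; the TPR reported at a target FPPI value is
the best TPR among operating points with FPPI not exceeding it. Mean FROC
averages the TPR at FPPI ∈ {1/8, 1/4, 1/2, 1, 2, 4, 8} (the prevailing
convention; configurable). Confidence intervals are percentile bootstrap
over whole images (default 1000 replicates, 95%), keeping each image's
records together; replicates that resample no ground-truth box count as 0.

## Distributed hyperparameter sweep

Per-client FROC scores cannot be averaged — each client's curve rests on
its own thresholds — so clients evaluate each candidate value on their
held-out validation split (10% of local training images, seeded, excluded
from training) and ship only match records (score, hit flag) plus ground
truth and image counts. The server pools records, computes one global FROC
per candidate and takes the argmax, ties to the smaller value. Parameters
are swept sequentially (min_score over 0.1–0.9, then min_object_size over
{0, p10, p25, p50} of training box volumes), each selection frozen before
the next sweep; the protocol is exactly equivalent to a centralized sweep
over pooled raw predictions, which the tests verify. Final FROC numbers
are computed at the selected thresholds.

## Numerical and degenerate-input conventions

- Sub-seeds everywhere are SHA-256 hashes (< 2³¹) of the master seed plus
  a role string, never consecutive integers.
- A constant image produces no candidates (no strict LoG maxima); a
  candidate set without both classes aborts training with a pointer to
  easier generator settings.
- Zero-norm vectors are rejected by the cosine similarity; the batch MOON
  gradient guards norms with 1e−12.
- Clipped probability ε = 1e−7; feature-standardization σ floor 1e−8.
- E = 0 local epochs returns the input weights bitwise, so a zero-epoch
  experiment ends at its initialization.

## Known limitations

- The detector is a six-feature candidate scorer, not a learned 3D
  backbone; absolute FROC values on the synthetic task say nothing about
  LUNA16/Duke-scale performance, only the *relative* behaviour of the
  federated machinery is meaningful.
- Proposals are model-independent, so federated strategies differ only
  through the scoring head — intentional, to isolate aggregation effects.
- The μ stability bound above; schedules can push μ into the unstable
  region if the loss plateaus for many rounds.
- The bootstrap treats images as exchangeable; institution-level clustering
  of the test pool is not resampled.
- The in-process federation is sequential and fault-free; no transport,
  client sampling, or stragglers.
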