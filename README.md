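# fedlesion

Federated, self-configuring 3D lesion detection — at desk scale.

Hospitals cannot pool medical images, but they can pool model weights.
`fedlesion` implements the full pipeline a federation of virtual
institutions needs to train and *configure* an object detector for 3D
lesion detection without any raw image leaving its site, and makes every
stage testable on seeded synthetic volumes on a single CPU:

1. **Global data fingerprint** — each institution summarizes its dataset
   (spacings, intensity distribution, object sizes); summaries aggregate
   into one global fingerprint by either pooling every 10th voxel
   (*nosyn*) or redrawing from per-image truncated Gaussians
   N(μ, σ) on [min, max] (*syn*, no voxel value crosses the wire). A rule
   base turns the fingerprint into a training plan (clip range, target
   spacing, normalization, candidate blob scales).
2. **Partitioning** — three heterogeneity scenarios: label-stratified IID,
   manufacturer-based non-IID (domain shift), and Dirichlet label skew
   X ~ Dir(α) per class, optionally with a leave-one-out test institution.
3. **Federated training** — R global rounds of E local epochs under
   FedAvg (w = Σ n_k w_k / Σ n_k), FedProx (+ (μ/2)‖w − w_global‖²),
   FedMOON (− μ log softmax of cosine similarities sim(z, z_glob),
   sim(z, z_prev) at temperature τ), or FedDC daisy chaining (random
   permutation of whole client models every b-th round). μ can follow
   loss-driven schedules (halve/double on a round-loss decrease, or
   ±0.1 on two consecutive decreases).
4. **Distributed sweep** — inference hyperparameters (minimum prediction
   score, minimum object size) are optimized sequentially; clients ship
   only match records (score, hit flag) and counts, the server computes
   pooled FROC per candidate value and selects the argmax — provably
   equivalent to sweeping over pooled raw predictions.
5. **Evaluation** — greedy IoU-0.1 matching, FROC (TPR = TP/(TP+FN)
   against FPPI = FP/images), mean FROC over FPPI ∈ {1/8 … 8}, and
   percentile bootstrap CIs over whole images (1000 replicates, 95%).

The detector itself is deliberately small — multi-scale
Laplacian-of-Gaussian candidate proposal plus an MLP scorer with a flat
parameter vector and a 16-d representation — so that federation behaviour,
not GPU training, is what the package exercises. See `docs/methods.md` for
the models, conventions, and limitations.

## Worked example

Simulate a 3-institution federation (manufacturer-shifted intensities,
10 train + 5 test volumes each), run the full pipeline under FedAvg, and
report:

```sh
$ fedlesion simulate --out demo/ds --institutions 3 --n-train 10 --n-test 5 --seed 1
wrote 3 institutions x (10+5) volumes to demo/ds

$ fedlesion run --dataset demo/ds --strategy fedavg --seed 1 --out demo/results.json
pooled test mean FROC 0.933 [0.833, 1.000]
results -> demo/results.json

$ fedlesion report --results demo/results.json
strategy=fedavg rounds=10 epochs=5 fingerprint=nosyn
round losses: 0.055 0.019 0.009 0.006 0.005 0.004 0.003 0.003 0.002 0.002
sweep selections: {'min_object_size': 0.0, 'min_score': 0.1}
test       I1       mean FROC 1.000 [1.000, 1.000]
test       I2       mean FROC 0.900 [0.700, 1.000]
test       I3       mean FROC 0.900 [0.700, 1.000]
test       pooled   mean FROC 0.933 [0.833, 1.000]
validation I1       mean FROC 1.000 [1.000, 1.000]
validation I2       mean FROC 1.000 [1.000, 1.000]
validation I3       mean FROC 1.000 [1.000, 1.000]
validation pooled   mean FROC 1.000 [1.000, 1.000]
```

Reading this: the ten round losses are the sample-weighted client training
losses ℓ_1…ℓ_10 (they drive the adaptive-μ schedules when one is
configured); the sweep settled on a 0.1 score threshold and no minimum
object size; the pooled test mean FROC of 0.933 says the global model
recovers 93% of the achievable TPR averaged over the seven FPPI operating
points, with the bracketed 95% bootstrap interval. Some synthetic lesions
are generated below the detection limit by design, so values below 1.0 are
expected and the per-institution spread reflects the manufacturer shift.

The same pipeline runs as a library (`fedlesion.run_experiment`), and
`fedlesion partition` / `fedlesion fingerprint` expose the intermediate
stages; external NIfTI + annotation-CSV datasets travel the same reader
path as the simulator's output.

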