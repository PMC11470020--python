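"""Virtual-institution dataset partitioning.

Three scenarios mirror the heterogeneity regimes studied in federated
lesion detection:

* ``iid_label`` — stratified by the image-level label so every institution
  sees the same label mix (the IID baseline);
* ``manufacturer_noniid`` — images routed by scanner manufacturer, the
  feature-distribution (domain) skew, with whatever quantity skew the
  manufacturer mix implies;
* ``dirichlet_label_loo`` — label skew: per class, institution shares are a
  draw from Dir(alpha); optionally a leave-one-out institution holds the
  entire test pool and no training data, probing generalization to an
  unseen site.

An image's stratification label is *malignant* if any of its boxes is
malignant, else *benign* (allocation is per case, not per box).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthdata import BENIGN, MALIGNANT, AnnotatedVolume, FederatedDataset

IID_LABEL = "iid_label"
MANUFACTURER_NONIID = "manufacturer_noniid"
DIRICHLET_LABEL_LOO = "dirichlet_label_loo"
SCHEMES = (IID_LABEL, MANUFACTURER_NONIID, DIRICHLET_LABEL_LOO)


@dataclass(frozen=True)
class PoolEntry:
    """One image in the source pool, as the partitioner sees it."""

    image_id: str
    label: str          # image-level: malignant if any box is
    manufacturer: str
    split: str          # train | test


def image_label(volume: AnnotatedVolume) -> str:
    return MALIGNANT if any(b.label == MALIGNANT for b in volume.boxes) else BENIGN


def pool_from_dataset(ds: FederatedDataset) -> list[PoolEntry]:
    """Flatten a federated dataset into a partitioning pool (drops its split)."""
    entries = []
    for inst, entry in ds.manifest.items():
        for split, ids in (("train", entry["train_ids"]), ("test", entry["test_ids"])):
            for image_id in ids:
                v = ds.volumes[image_id]
                entries.append(PoolEntry(image_id=image_id, label=image_label(v),
                                         manufacturer=v.manufacturer, split=split))
    return entries


@dataclass
class PartitionConfig:
    scheme: str
    n_institutions: int = 3
    alpha_per_class: dict[str, list[float]] = field(default_factory=dict)
    manufacturer_assignment: dict[str, list[str]] = field(default_factory=dict)
    loo: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        for label, alpha in self.alpha_per_class.items():
            if len(alpha) != self.n_institutions or any(a <= 0 for a in alpha):
                raise ValueError(f"invalid alpha for {label!r}: {alpha}")
        subsets = [set(v) for v in self.manufacturer_assignment.values()]
        for i, a in enumerate(subsets):
            for b in subsets[i + 1:]:
                if a & b:
                    raise ValueError("manufacturer subsets must be pairwise disjoint")


@dataclass
class InstitutionAssignment:
    institution_id: str
    train_ids: list[str]
    test_ids: list[str]

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids must be disjoint")


def _check_disjoint_cover(assignments, pool_train_ids):
    seen: set[str] = set()
    for a in assignments:
        dup = seen & set(a.train_ids)
        if dup:
            raise AssertionError(f"image(s) assigned twice: {sorted(dup)[:3]}")
        seen |= set(a.train_ids)
    if seen != set(pool_train_ids):
        raise AssertionError("institution train sets do not cover the pool")


def split_iid_label(pool: list[PoolEntry], n_institutions: int,
                    seed: int) -> list[InstitutionAssignment]:
    """Stratified IID split: shuffle within each label group, deal round-robin.

    Continuing the deal across groups keeps total sizes within one image of
    each other while per-label counts stay within one of the even share.
    The test pool is dealt the same way, so each institution receives an
    individual test set with a matching label mix.
    """
    if not pool:
        raise ValueError("empty pool")
    if n_institutions < 1 or len([e for e in pool if e.split == "train"]) < n_institutions:
        raise ValueError("pool smaller than the number of institutions")
    rng = np.random.default_rng(seed)
    buckets: dict[str, dict[str, list[str]]] = {
        "train": {i: [] for i in range(n_institutions)},
        "test": {i: [] for i in range(n_institutions)}}
    for split in ("train", "test"):
        cursor = 0
        for label in (BENIGN, MALIGNANT):
            ids = sorted(e.image_id for e in pool
                         if e.split == split and e.label == label)
            rng.shuffle(ids)
            for image_id in ids:
                buckets[split][cursor % n_institutions].append(image_id)
                cursor += 1
    assignments = [InstitutionAssignment(institution_id=f"I{i + 1}",
                                         train_ids=buckets["train"][i],
                                         test_ids=buckets["test"][i])
                   for i in range(n_institutions)]
    _check_disjoint_cover(assignments, [e.image_id for e in pool if e.split == "train"])
    return assignments


def split_manufacturer_noniid(
        pool: list[PoolEntry],
        manufacturer_assignment: dict[str, list[str]]) -> list[InstitutionAssignment]:
    """Route every image (train and test alike) to the institution owning its
    manufacturer; quantity skew follows the manufacturer counts."""
    owner = {m: inst for inst, ms in manufacturer_assignment.items() for m in ms}
    missing = sorted({e.manufacturer for e in pool} - set(owner))
    if missing:
        raise ValueError(f"manufacturer(s) not assigned to any institution: {missing}")
    assignments = {inst: InstitutionAssignment(inst, [], [])
                   for inst in manufacturer_assignment}
    for e in pool:
        a = assignments[owner[e.manufacturer]]
        (a.train_ids if e.split == "train" else a.test_ids).append(e.image_id)
    out = list(assignments.values())
    _check_disjoint_cover(out, [e.image_id for e in pool if e.split == "train"])
    return out


def largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing to ``total`` with largest-remainder rounding;
    remainder ties broken by lower index."""
    raw = np.asarray(fractions, dtype=np.float64) * total
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    if short > 0:
        order = np.lexsort((np.arange(len(raw)), -(raw - base)))
        base[order[:short]] += 1
    return base


def split_dirichlet_label_loo(pool: list[PoolEntry],
                              alpha_per_class: dict[str, list[float]],
                              seed: int, loo: bool = False,
                              fractions_override: dict[str, np.ndarray] | None = None,
                              ) -> list[InstitutionAssignment]:
    """Label-skewed split: per class, institution fractions X ~ Dir(alpha).

    Training images of each class are shuffled and allocated in the drawn
    fractions (largest-remainder rounding).  With ``loo`` the entire test
    pool goes to one extra institution holding no training data; otherwise
    test images are allocated per class with the same drawn fractions.  If a
    draw leaves an institution without training images, one image migrates
    from the largest institution.  ``fractions_override`` pins the draw for
    a class (used by tests exercising the rounding arithmetic).
    """
    n_inst = {len(a) for a in alpha_per_class.values()}
    if len(n_inst) != 1:
        raise ValueError("alpha vectors must share one length")
    k = n_inst.pop()
    rng = np.random.default_rng(seed)
    train_alloc: dict[int, list[str]] = {i: [] for i in range(k)}
    test_alloc: dict[int, list[str]] = {i: [] for i in range(k)}
    pool_labels = {e.label for e in pool}
    for label, alpha in alpha_per_class.items():
        if label not in pool_labels:
            import warnings
            warnings.warn(f"class {label!r} in alpha but absent from pool; skipped")
            continue
        if fractions_override and label in fractions_override:
            x = np.asarray(fractions_override[label], dtype=np.float64)
        else:
            x = rng.dirichlet(alpha)
        for split, alloc in (("train", train_alloc), ("test", test_alloc)):
            if loo and split == "test":
                continue
            ids = sorted(e.image_id for e in pool
                         if e.split == split and e.label == label)
            rng.shuffle(ids)
            counts = largest_remainder(x, len(ids))
            pos = 0
            for i in range(k):
                alloc[i].extend(ids[pos:pos + counts[i]])
                pos += counts[i]
    # every training institution must end up non-empty
    for i in range(k):
        if not train_alloc[i]:
            donor = max(train_alloc, key=lambda j: len(train_alloc[j]))
            if not train_alloc[donor]:
                raise ValueError("pool has no training images to allocate")
            train_alloc[i].append(train_alloc[donor].pop())
    assignments = [InstitutionAssignment(f"I{i + 1}", train_alloc[i], test_alloc[i])
                   for i in range(k)]
    if loo:
        test_ids = sorted(e.image_id for e in pool if e.split == "test")
        assignments.append(InstitutionAssignment(f"I{k + 1}", [], test_ids))
    _check_disjoint_cover(assignments, [e.image_id for e in pool if e.split == "train"])
    return assignments


def split_pool(pool: list[PoolEntry], cfg: PartitionConfig) -> list[InstitutionAssignment]:
    if cfg.scheme == IID_LABEL:
        return split_iid_label(pool, cfg.n_institutions, cfg.seed)
    if cfg.scheme == MANUFACTURER_NONIID:
        return split_manufacturer_noniid(pool, cfg.manufacturer_assignment)
    return split_dirichlet_label_loo(pool, cfg.alpha_per_class, cfg.seed, loo=cfg.loo)


def summarize_partition(assignments: list[InstitutionAssignment],
                        volumes: dict[str, AnnotatedVolume]) -> pd.DataFrame:
    """Per-institution composition table: image/label counts, manufacturer
    mix, median box volume and median image-median intensity, and each
    median's share of the sum of medians across institutions."""
    rows = []
    for a in assignments:
        vols = [volumes[i] for i in a.train_ids]
        boxes = [b for v in vols for b in v.boxes]
        mfr = pd.Series([v.manufacturer for v in vols])
        box_vols = [b.volume for b in boxes]
        med_int = [float(np.median(v.image)) for v in vols]
        rows.append({
            "institution_id": a.institution_id,
            "n_images": len(vols),
            "n_boxes": len(boxes),
            "n_benign": sum(b.label == BENIGN for b in boxes),
            "n_malignant": sum(b.label == MALIGNANT for b in boxes),
            "manufacturer_composition": (
                {} if mfr.empty else mfr.value_counts(normalize=True).to_dict()),
            "median_box_volume": float(np.median(box_vols)) if box_vols else np.nan,
            "median_intensity": float(np.median(med_int)) if med_int else np.nan,
        })
    df = pd.DataFrame(rows)
    for col in ("median_box_volume", "median_intensity"):
        total = df[col].sum(skipna=True)
        df[col + "_share"] = df[col] / total if total else np.nan
    return df
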