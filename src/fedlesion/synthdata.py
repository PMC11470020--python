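"""Seeded synthetic 3D lesion volumes and federated datasets.

Volumes emulate the heterogeneity structure that drives the federated
experiments: a Gaussian background, additive ellipsoidal lesions with a
benign/malignant label, and a per-manufacturer affine intensity transform
(scale, offset, extra noise) applied to the whole volume — the synthetic
stand-in for scanner-induced domain shift.  Everything is deterministic
given the seed; per-image sub-seeds are derived by hashing so that
institutions and images are statistically independent.

Axis order is (z, y, x) everywhere; boxes are zero-based half-open voxel
ranges (z0, z1, y0, y1, x0, x1).
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

BENIGN = "benign"
MALIGNANT = "malignant"
LABELS = (BENIGN, MALIGNANT)


def derive_seed(*parts) -> int:
    """Stable sub-seed from arbitrary parts (< 2**31)."""
    key = "|".join(str(p) for p in parts).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


@dataclass(frozen=True)
class BoxAnnotation:
    """Half-open voxel box (z0,z1,y0,y1,x0,x1) with a two-class label."""

    box: tuple[int, int, int, int, int, int]
    label: str

    def __post_init__(self):
        z0, z1, y0, y1, x0, x1 = self.box
        if not (z1 > z0 and y1 > y0 and x1 > x0):
            raise ValueError(f"degenerate box {self.box}")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def volume(self) -> int:
        z0, z1, y0, y1, x0, x1 = self.box
        return (z1 - z0) * (y1 - y0) * (x1 - x0)


@dataclass
class AnnotatedVolume:
    image: np.ndarray                  # 3D float array, (z, y, x)
    spacing: tuple[float, float, float]  # mm per axis
    image_id: str
    manufacturer: str
    boxes: list[BoxAnnotation] = field(default_factory=list)

    def __post_init__(self):
        if self.image.ndim != 3:
            raise ValueError("image must be 3D")
        for b in self.boxes:
            z0, z1, y0, y1, x0, x1 = b.box
            if not (0 <= z0 and z1 <= self.image.shape[0]
                    and 0 <= y0 and y1 <= self.image.shape[1]
                    and 0 <= x0 and x1 <= self.image.shape[2]):
                raise ValueError(f"box {b.box} outside image {self.image.shape}")


@dataclass(frozen=True)
class VolumeSpec:
    """Generator parameters for one synthetic volume.

    Intensity model: background ~ N(background_mean, background_std),
    lesions add contrast drawn from lesion_contrast_range, then the whole
    volume is mapped v -> manufacturer_scale*v + manufacturer_offset +
    N(0, manufacturer_noise_std).
    """

    shape: tuple[int, int, int] = (28, 44, 44)
    spacing: tuple[float, float, float] = (2.0, 1.0, 1.0)
    background_mean: float = 100.0
    background_std: float = 10.0
    manufacturer: str = "vendorA"
    manufacturer_offset: float = 0.0
    manufacturer_scale: float = 1.0
    manufacturer_noise_std: float = 0.0
    n_lesions: int = 2
    lesion_radius_range: tuple[float, float] = (2.5, 5.0)
    lesion_contrast_range: tuple[float, float] = (3.0, 50.0)
    malignant_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if any(s < 16 for s in self.shape):
            raise ValueError(f"shape must be >= (16,16,16), got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not 0.0 <= self.malignant_fraction <= 1.0:
            raise ValueError("malignant_fraction must lie in [0,1]")
        lo, hi = self.lesion_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid lesion_radius_range")
        if 2 * hi >= min(self.shape):
            raise ValueError("lesion radii do not fit inside the volume")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")


def _boxes_overlap(a, b) -> bool:
    return all(a[2 * i] < b[2 * i + 1] and b[2 * i] < a[2 * i + 1] for i in range(3))


def generate_volume(spec: VolumeSpec, image_id: str = "img") -> AnnotatedVolume:
    """Render one annotated volume; bit-identical for identical (spec, seed).

    Lesions are axis-aligned ellipsoids; candidate centers overlapping an
    already placed lesion are resampled (up to 100 tries each) so ground-truth
    boxes stay unambiguous.  Boxes are the tight bounding boxes of the
    ellipsoid supports.  The manufacturer transform is applied last, so it
    shifts lesion and background intensities alike.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    image = rng.normal(spec.background_mean, spec.background_std, size=shape)

    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    boxes: list[BoxAnnotation] = []
    placed: list[tuple[int, ...]] = []
    for _ in range(spec.n_lesions):
        for _attempt in range(100):
            radii = rng.uniform(*spec.lesion_radius_range, size=3)
            center = np.array([rng.uniform(r, s - r) for r, s in zip(radii, shape)])
            lo = np.floor(center - radii).astype(int)
            hi = np.ceil(center + radii).astype(int) + 1
            bbox = (lo[0], hi[0], lo[1], hi[1], lo[2], hi[2])
            if not any(_boxes_overlap(bbox, p) for p in placed):
                break
        else:
            raise RuntimeError(f"could not place lesion without overlap for spec {spec}")
        contrast = rng.uniform(*spec.lesion_contrast_range)
        support = (((zz - center[0]) / radii[0]) ** 2
                   + ((yy - center[1]) / radii[1]) ** 2
                   + ((xx - center[2]) / radii[2]) ** 2) <= 1.0
        image[support] += contrast
        idx = np.nonzero(support)
        tight = tuple(int(v) for pair in ((a.min(), a.max() + 1) for a in idx) for v in pair)
        placed.append(tight)
        label = MALIGNANT if rng.uniform() < spec.malignant_fraction else BENIGN
        boxes.append(BoxAnnotation(box=tight, label=label))

    image = spec.manufacturer_scale * image + spec.manufacturer_offset
    if spec.manufacturer_noise_std > 0:
        image = image + rng.normal(0.0, spec.manufacturer_noise_std, size=shape)

    return AnnotatedVolume(image=image, spacing=spec.spacing, image_id=image_id,
                           manufacturer=spec.manufacturer, boxes=boxes)


@dataclass
class FederatedDataset:
    """In-memory federation: volumes keyed by id plus the split manifest."""

    volumes: dict[str, AnnotatedVolume]
    manifest: dict[str, dict]  # institution -> {train_ids, test_ids, manufacturer, seeds}

    def institution_ids(self) -> list[str]:
        return list(self.manifest)

    def train_volumes(self, institution: str) -> list[AnnotatedVolume]:
        return [self.volumes[i] for i in self.manifest[institution]["train_ids"]]

    def test_volumes(self, institution: str) -> list[AnnotatedVolume]:
        return [self.volumes[i] for i in self.manifest[institution]["test_ids"]]


def generate_federated_dataset(
    institution_specs: dict[str, VolumeSpec],
    n_train: int | dict[str, int],
    n_test: int | dict[str, int],
    seed: int,
    out_dir: str | Path | None = None,
) -> FederatedDataset:
    """Generate per-institution train/test volumes from VolumeSpec templates.

    Each image gets an independent sub-seed hash(seed, institution, split,
    index), recorded in the manifest.  With ``out_dir`` set, NIfTI volumes,
    an annotation CSV and the manifest JSON are written to disk.
    """
    volumes: dict[str, AnnotatedVolume] = {}
    manifest: dict[str, dict] = {}
    for inst, template in institution_specs.items():
        ntr = n_train[inst] if isinstance(n_train, dict) else n_train
        nte = n_test[inst] if isinstance(n_test, dict) else n_test
        if ntr < 1 or nte < 1:
            raise ValueError(f"n_train and n_test must be >= 1 (institution {inst})")
        entry = {"train_ids": [], "test_ids": [], "manufacturer": template.manufacturer,
                 "seeds": {}}
        for split, n, key in (("train", ntr, "train_ids"), ("test", nte, "test_ids")):
            for idx in range(n):
                image_id = f"{inst}_{split}_{idx:04d}"
                if image_id in volumes:
                    raise ValueError(f"duplicate image_id {image_id}")
                sub = derive_seed(seed, inst, split, idx)
                vol = generate_volume(replace(template, seed=sub), image_id=image_id)
                volumes[image_id] = vol
                entry[key].append(image_id)
                entry["seeds"][image_id] = sub
        manifest[inst] = entry

    ds = FederatedDataset(volumes=volumes, manifest=manifest)
    if out_dir is not None:
        write_dataset(ds, out_dir)
    return ds


# ---------------------------------------------------------------------------
# Disk I/O: NIfTI volumes, annotation CSV, manifest JSON
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["image_id", "z0", "z1", "y0", "y1", "x0", "x1", "label"]


def write_volume_nifti(volume: AnnotatedVolume, path: str | Path) -> None:
    # nibabel stores data in (x, y, z); transpose so spacing lines up.
    data = np.asarray(volume.image, dtype=np.float32).transpose(2, 1, 0)
    affine = np.diag([volume.spacing[2], volume.spacing[1], volume.spacing[0], 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_volume_nifti(path: str | Path, image_id: str,
                      manufacturer: str = "unknown",
                      boxes: list[BoxAnnotation] | None = None) -> AnnotatedVolume:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64).transpose(2, 1, 0)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return AnnotatedVolume(image=data, spacing=spacing, image_id=image_id,
                           manufacturer=manufacturer, boxes=list(boxes or []))


def write_annotations_csv(volumes: dict[str, AnnotatedVolume], path: str | Path) -> None:
    """Columns: image_id,z0,z1,y0,y1,x0,x1,label — zero-based half-open (z,y,x)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ANNOTATION_COLUMNS)
        for image_id in sorted(volumes):
            for b in volumes[image_id].boxes:
                writer.writerow([image_id, *b.box, b.label])


def read_annotations_csv(path: str | Path) -> dict[str, list[BoxAnnotation]]:
    out: dict[str, list[BoxAnnotation]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            box = tuple(int(row[c]) for c in ANNOTATION_COLUMNS[1:7])
            out.setdefault(row["image_id"], []).append(
                BoxAnnotation(box=box, label=row["label"]))
    return out


def write_dataset(ds: FederatedDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    for image_id, vol in ds.volumes.items():
        write_volume_nifti(vol, out / "images" / f"{image_id}.nii.gz")
    write_annotations_csv(ds.volumes, out / "annotations.csv")
    meta = {inst: {**e, "seeds": {k: int(v) for k, v in e["seeds"].items()}}
            for inst, e in ds.manifest.items()}
    with open(out / "manifest.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_dataset(in_dir: str | Path) -> FederatedDataset:
    src = Path(in_dir)
    with open(src / "manifest.json") as fh:
        manifest = json.load(fh)
    annotations = read_annotations_csv(src / "annotations.csv")
    volumes: dict[str, AnnotatedVolume] = {}
    for inst, entry in manifest.items():
        for image_id in entry["train_ids"] + entry["test_ids"]:
            volumes[image_id] = read_volume_nifti(
                src / "images" / f"{image_id}.nii.gz", image_id,
                manufacturer=entry["manufacturer"],
                boxes=annotations.get(image_id, []))
    return FederatedDataset(volumes=volumes, manifest=manifest)
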