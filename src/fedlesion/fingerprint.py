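"""Local and global data fingerprints and the simplified training plan.

A fingerprint characterizes a dataset by per-image properties (spacing,
shape, intensity distribution, object sizes) that a self-configuring
detector uses to pick its preprocessing and candidate scales.  Per-image
properties concatenate trivially across institutions; the *global* intensity
distribution does not, so two aggregation methods are provided:

``nosyn``
    every 10th voxel of every image (flattened in (z,y,x) order, stride 10
    starting at index 0) is pooled at the server and the global statistics
    are recomputed from the pooled samples.  Accurate, but ships raw voxel
    values.
``syn``
    each image is summarized by a truncated Gaussian (its mean and standard
    deviation, truncated to its min/max); the server redraws samples from
    those distributions and recomputes the statistics.  No raw voxel value
    ever leaves an institution.

Percentiles use linear interpolation between order statistics (numpy's
default), stated here so independent oracles can match bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .synthdata import AnnotatedVolume, derive_seed

NOSYN = "nosyn"
SYN = "syn"

#: stride of the nosyn voxel subsampling
VOXEL_STRIDE = 10
#: cap on per-image syn sample counts, bounds server memory
SYN_SAMPLE_CAP = 10_000


@dataclass(frozen=True)
class IntensityStats:
    mean: float
    std: float
    min: float
    max: float
    median: float
    p0_5: float
    p99_5: float

    def __post_init__(self):
        if not (self.min <= self.p0_5 <= self.median <= self.p99_5 <= self.max):
            raise ValueError("intensity percentiles out of order")
        if self.std < 0:
            raise ValueError("std must be >= 0")

    @classmethod
    def from_samples(cls, samples: np.ndarray) -> "IntensityStats":
        samples = np.asarray(samples, dtype=np.float64).ravel()
        if samples.size == 0:
            raise ValueError("cannot compute intensity stats from an empty sample")
        p0_5, med, p99_5 = np.percentile(samples, [0.5, 50.0, 99.5])
        return cls(mean=float(samples.mean()), std=float(samples.std()),
                   min=float(samples.min()), max=float(samples.max()),
                   median=float(med), p0_5=float(p0_5), p99_5=float(p99_5))


def aggregate_intensity_stats(samples: np.ndarray) -> IntensityStats:
    """Global statistics of a pooled sample vector (mean/std/min/max/percentiles)."""
    return IntensityStats.from_samples(samples)


@dataclass
class ImageFingerprint:
    image_id: str
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]
    n_voxels: int
    stats: IntensityStats
    box_volumes: list[int]
    labels: list[str]
    manufacturer: str

    def __post_init__(self):
        if self.n_voxels != int(np.prod(self.shape)):
            raise ValueError("n_voxels inconsistent with shape")
        if any(v <= 0 for v in self.box_volumes):
            raise ValueError("box volumes must be positive")


def compute_image_fingerprint(volume: AnnotatedVolume) -> ImageFingerprint:
    """Per-image fingerprint over *all* voxels (no foreground mask)."""
    if volume.image.size == 0:
        raise ValueError("empty image")
    return ImageFingerprint(
        image_id=volume.image_id,
        spacing=volume.spacing,
        shape=tuple(volume.image.shape),
        n_voxels=int(volume.image.size),
        stats=IntensityStats.from_samples(volume.image),
        box_volumes=[b.volume for b in volume.boxes],
        labels=[b.label for b in volume.boxes],
        manufacturer=volume.manufacturer,
    )


def sample_voxels_nosyn(volume: AnnotatedVolume) -> np.ndarray:
    """Every 10th voxel of the image, flattened (z,y,x), starting at index 0."""
    flat = np.asarray(volume.image, dtype=np.float64).ravel(order="C")
    return flat[::VOXEL_STRIDE].copy()


@dataclass(frozen=True)
class TruncGaussSpec:
    """Privacy-preserving image summary: 5 scalars, no voxel values."""

    mu: float
    sigma: float
    lower: float
    upper: float
    n_samples: int
    image_id: str = ""

    def __post_init__(self):
        if not self.lower <= self.mu <= self.upper:
            raise ValueError("mu must lie in [lower, upper]")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def build_trunc_gauss_spec(fp: ImageFingerprint) -> TruncGaussSpec:
    """Summarize an image by mean/std truncated to [min, max].

    ``n_samples`` matches the nosyn subsampling density, ceil(n_voxels/10),
    capped so one image cannot dominate server memory.
    """
    n = min(math.ceil(fp.n_voxels / VOXEL_STRIDE), SYN_SAMPLE_CAP)
    return TruncGaussSpec(mu=fp.stats.mean, sigma=fp.stats.std,
                          lower=fp.stats.min, upper=fp.stats.max,
                          n_samples=n, image_id=fp.image_id)


def _draw_truncated(spec: TruncGaussSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.sigma == 0:
        return np.full(spec.n_samples, spec.mu)
    # inverse-CDF on the truncated interval: exact truncation, deterministic cost
    a = (spec.lower - spec.mu) / spec.sigma
    b = (spec.upper - spec.mu) / spec.sigma
    u = rng.uniform(size=spec.n_samples)
    return sps.truncnorm.ppf(u, a, b, loc=spec.mu, scale=spec.sigma)


def sample_voxels_syn(specs: list[TruncGaussSpec], seed: int) -> np.ndarray:
    """Redraw per-image truncated-Gaussian samples; per-image sub-seeds make
    the pooled vector invariant to institution/image ordering."""
    if not specs:
        raise ValueError("no truncated-Gaussian specs supplied")
    draws = [_draw_truncated(s, np.random.default_rng(derive_seed(seed, s.image_id)))
             for s in specs]
    return np.concatenate(draws)


@dataclass
class LocalFingerprint:
    institution_id: str
    image_fingerprints: list[ImageFingerprint]
    method: str                               # syn | nosyn
    voxel_samples: list[np.ndarray] = field(default_factory=list)   # nosyn payload
    trunc_specs: list[TruncGaussSpec] = field(default_factory=list)  # syn payload

    def __post_init__(self):
        if self.method not in (SYN, NOSYN):
            raise ValueError(f"unknown fingerprint method {self.method!r}")
        if self.method == SYN and self.voxel_samples:
            raise ValueError("syn payload must not contain raw voxel samples")


def compute_local_fingerprint(institution_id: str,
                              volumes: list[AnnotatedVolume],
                              method: str) -> LocalFingerprint:
    """What one institution computes and ships to the server."""
    fps = [compute_image_fingerprint(v) for v in volumes]
    lf = LocalFingerprint(institution_id=institution_id,
                          image_fingerprints=fps, method=method)
    if method == NOSYN:
        lf.voxel_samples = [sample_voxels_nosyn(v) for v in volumes]
    else:
        lf.trunc_specs = [build_trunc_gauss_spec(fp) for fp in fps]
    return lf


@dataclass
class GlobalFingerprint:
    image_fingerprints: list[ImageFingerprint]
    global_stats: IntensityStats
    method: str
    pooled_samples: np.ndarray   # nosyn voxels or syn redraws; feeds derive_plan

    @property
    def n_images(self) -> int:
        return len(self.image_fingerprints)


def build_global_fingerprint(local_fps: list[LocalFingerprint],
                             method: str, seed: int = 0) -> GlobalFingerprint:
    """Server-side aggregation of local fingerprints.

    nosyn pools the shipped voxel samples directly.  syn redraws from the
    shipped truncated-Gaussian specs; its global min/max are taken exactly as
    min(lower)/max(upper) over the specs rather than from the finite redraw.
    """
    if not local_fps:
        raise ValueError("no local fingerprints")
    methods = {lf.method for lf in local_fps}
    if methods != {method}:
        raise ValueError(f"mixed or mismatched fingerprint methods: {methods} vs {method!r}")
    images = [fp for lf in local_fps for fp in lf.image_fingerprints]
    if method == NOSYN:
        # pool in canonical image order: global stats independent of the
        # order institutions report in, down to the last bit
        pairs = sorted(((fp.image_id, s) for lf in local_fps
                        for fp, s in zip(lf.image_fingerprints, lf.voxel_samples)),
                       key=lambda t: t[0])
        pooled = np.concatenate([s for _, s in pairs])
        gstats = aggregate_intensity_stats(pooled)
    else:
        specs = sorted((s for lf in local_fps for s in lf.trunc_specs),
                       key=lambda s: s.image_id)
        pooled = sample_voxels_syn(specs, seed)
        st = aggregate_intensity_stats(pooled)
        gstats = IntensityStats(
            mean=st.mean, std=st.std,
            min=min(s.lower for s in specs), max=max(s.upper for s in specs),
            median=st.median, p0_5=st.p0_5, p99_5=st.p99_5)
    return GlobalFingerprint(image_fingerprints=images, global_stats=gstats,
                             method=method, pooled_samples=pooled)


@dataclass(frozen=True)
class Plan:
    """Simplified rule-based training plan derived from the global fingerprint."""

    target_spacing: tuple[float, float, float]
    clip_lo: float
    clip_hi: float
    norm_mean: float
    norm_std: float
    candidate_scales: tuple[float, ...]   # blob radii in voxels, sorted
    min_object_size_default: float        # voxels
    min_score_default: float = 0.5

    def __post_init__(self):
        if not self.clip_lo < self.clip_hi:
            raise ValueError("clip_lo must be < clip_hi")
        if not self.candidate_scales:
            raise ValueError("candidate_scales must be non-empty")
        if list(self.candidate_scales) != sorted(self.candidate_scales):
            raise ValueError("candidate_scales must be sorted")


def equivalent_sphere_radius(volume: float) -> float:
    """Radius of the sphere with the given voxel volume, (3V/4pi)^(1/3)."""
    return (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)


def derive_plan(gfp: GlobalFingerprint) -> Plan:
    """Rule-based plan: median spacing, outlier clipping at the global 0.5th
    and 99.5th percentiles, z-score normalization, and candidate blob radii
    at the 10th/50th/90th percentiles of the annotated box volumes."""
    if gfp.n_images == 0:
        raise ValueError("global fingerprint holds no images")
    box_volumes = np.array([v for fp in gfp.image_fingerprints for v in fp.box_volumes],
                           dtype=np.float64)
    if box_volumes.size == 0:
        raise ValueError("global fingerprint holds no annotated boxes")
    spacings = np.array([fp.spacing for fp in gfp.image_fingerprints])
    target_spacing = tuple(float(s) for s in np.median(spacings, axis=0))
    clip_lo, clip_hi = gfp.global_stats.p0_5, gfp.global_stats.p99_5
    clipped = np.clip(gfp.pooled_samples, clip_lo, clip_hi)
    vol_p10, vol_p50, vol_p90 = np.percentile(box_volumes, [10, 50, 90])
    scales = tuple(sorted({equivalent_sphere_radius(v)
                           for v in (vol_p10, vol_p50, vol_p90)}))
    return Plan(target_spacing=target_spacing,
                clip_lo=float(clip_lo), clip_hi=float(clip_hi),
                norm_mean=float(clipped.mean()), norm_std=float(clipped.std()),
                candidate_scales=scales,
                min_object_size_default=float(vol_p10))
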