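"""Fingerprinting: per-image stats, syn/nosyn aggregation, plan rules."""

import math

import numpy as np
import pytest

import fedlesion as fl
from fedlesion.fingerprint import (NOSYN, SYN, TruncGaussSpec,
                                   equivalent_sphere_radius)
from fedlesion.synthdata import AnnotatedVolume, BoxAnnotation

from conftest import brute_force_stats, make_dataset


def _volume_from_array(arr, image_id="t", boxes=()):
    return AnnotatedVolume(image=np.asarray(arr, dtype=float),
                           spacing=(1.0, 1.0, 1.0), image_id=image_id,
                           manufacturer="m", boxes=list(boxes))


class TestImageFingerprint:
    def test_constant_image_degenerate_stats(self):
        fp = fl.compute_image_fingerprint(_volume_from_array(np.full((4, 4, 4), 7.0)))
        st = fp.stats
        assert st.mean == st.median == st.min == st.max == 7.0
        assert st.std == 0.0

    def test_box_volume_arithmetic(self):
        vol = _volume_from_array(np.zeros((4, 4, 4)),
                                 boxes=[BoxAnnotation((0, 2, 0, 2, 0, 2), "benign")])
        assert fl.compute_image_fingerprint(vol).box_volumes == [8]

    def test_percentiles_match_brute_force_oracle(self):
        arr = np.arange(1.0, 1001.0).reshape(10, 10, 10)
        st = fl.compute_image_fingerprint(_volume_from_array(arr)).stats
        ref = brute_force_stats(arr)
        for f in ("p0_5", "median", "p99_5", "mean", "std"):
            assert getattr(st, f) == pytest.approx(ref[f], rel=1e-12)


class TestNosynSampling:
    @pytest.mark.parametrize("n_voxels, expected", [(100, 10), (9, 1), (1000, 100)])
    def test_every_tenth_voxel_count(self, n_voxels, expected):
        side = round(n_voxels ** (1 / 3))
        arr = np.arange(n_voxels, dtype=float)
        vol = _volume_from_array(arr.reshape(-1, 1, 1))
        assert fl.sample_voxels_nosyn(vol).size == expected

    def test_stride_starts_at_flat_index_zero(self):
        arr = np.arange(30.0).reshape(2, 3, 5)
        np.testing.assert_array_equal(
            fl.sample_voxels_nosyn(_volume_from_array(arr)), [0.0, 10.0, 20.0])

    def test_constant_image_constant_samples(self):
        s = fl.sample_voxels_nosyn(_volume_from_array(np.full((5, 5, 4), 5.0)))
        assert np.all(s == 5.0)


class TestSynSampling:
    def test_spec_field_mapping(self):
        fp = fl.compute_image_fingerprint(
            _volume_from_array(np.linspace(0, 20, 1000).reshape(10, 10, 10)))
        spec = fl.build_trunc_gauss_spec(fp)
        assert spec.mu == fp.stats.mean and spec.sigma == fp.stats.std
        assert spec.lower == fp.stats.min and spec.upper == fp.stats.max
        assert spec.n_samples == 100

    def test_zero_variance_spec_samples_equal_mu(self):
        spec = TruncGaussSpec(mu=3.0, sigma=0.0, lower=3.0, upper=3.0,
                              n_samples=5, image_id="a")
        assert np.all(fl.sample_voxels_syn([spec], seed=0) == 3.0)

    def test_samples_respect_truncation_bounds(self):
        spec = TruncGaussSpec(mu=0.0, sigma=5.0, lower=-2.0, upper=3.0,
                              n_samples=10_000, image_id="a")
        s = fl.sample_voxels_syn([spec], seed=1)
        assert s.min() >= -2.0 and s.max() <= 3.0

    def test_symmetric_truncation_has_zero_mean(self):
        spec = TruncGaussSpec(mu=0.0, sigma=1.0, lower=-1.0, upper=1.0,
                              n_samples=100_000, image_id="a")
        assert abs(fl.sample_voxels_syn([spec], seed=2).mean()) < 0.02

    def test_fixed_seed_is_deterministic(self):
        spec = TruncGaussSpec(mu=1.0, sigma=2.0, lower=-5.0, upper=8.0,
                              n_samples=100, image_id="a")
        np.testing.assert_array_equal(fl.sample_voxels_syn([spec], seed=3),
                                      fl.sample_voxels_syn([spec], seed=3))


class TestAggregation:
    def test_median_of_1_to_100(self):
        st = fl.aggregate_intensity_stats(np.arange(1.0, 101.0))
        assert st.median == 50.5

    def test_singleton_sample(self):
        st = fl.aggregate_intensity_stats(np.array([3.0]))
        assert st.mean == st.median == st.min == st.max == 3.0

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            fl.aggregate_intensity_stats(np.array([]))

    def test_nosyn_global_stats_equal_brute_force_pooling(self, dataset):
        locals_ = [fl.compute_local_fingerprint(i, dataset.train_volumes(i), NOSYN)
                   for i in dataset.institution_ids()]
        gfp = fl.build_global_fingerprint(locals_, NOSYN)
        pooled = np.concatenate([fl.sample_voxels_nosyn(v)
                                 for i in dataset.institution_ids()
                                 for v in dataset.train_volumes(i)])
        ref = brute_force_stats(pooled)
        for f, v in ref.items():
            assert getattr(gfp.global_stats, f) == pytest.approx(v, rel=1e-12)


class TestGlobalFingerprint:
    def test_single_institution_identity(self, dataset):
        lf = fl.compute_local_fingerprint("I1", dataset.train_volumes("I1"), NOSYN)
        gfp = fl.build_global_fingerprint([lf], NOSYN)
        assert [f.image_id for f in gfp.image_fingerprints] == \
            [f.image_id for f in lf.image_fingerprints]

    def test_mixed_methods_rejected(self, dataset):
        a = fl.compute_local_fingerprint("I1", dataset.train_volumes("I1"), NOSYN)
        b = fl.compute_local_fingerprint("I2", dataset.train_volumes("I2"), SYN)
        with pytest.raises(ValueError):
            fl.build_global_fingerprint([a, b], NOSYN)

    def test_syn_payload_contains_no_voxel_arrays(self, dataset):
        lf = fl.compute_local_fingerprint("I1", dataset.train_volumes("I1"), SYN)
        assert lf.voxel_samples == []
        assert len(lf.trunc_specs) == len(lf.image_fingerprints)
        for spec in lf.trunc_specs:
            scalars = (spec.mu, spec.sigma, spec.lower, spec.upper, spec.n_samples)
            assert all(np.isscalar(v) for v in scalars) and len(scalars) == 5

    @pytest.mark.parametrize("method", [NOSYN, SYN])
    def test_institution_order_invariance(self, dataset, method):
        locals_ = [fl.compute_local_fingerprint(i, dataset.train_volumes(i), method)
                   for i in dataset.institution_ids()]
        g1 = fl.build_global_fingerprint(locals_, method, seed=4)
        g2 = fl.build_global_fingerprint(locals_[::-1], method, seed=4)
        for f in ("mean", "std", "min", "max", "median", "p0_5", "p99_5"):
            assert getattr(g1.global_stats, f) == getattr(g2.global_stats, f)

    def test_syn_minmax_taken_exactly_from_specs(self, dataset):
        locals_ = [fl.compute_local_fingerprint(i, dataset.train_volumes(i), SYN)
                   for i in dataset.institution_ids()]
        gfp = fl.build_global_fingerprint(locals_, SYN, seed=0)
        specs = [s for lf in locals_ for s in lf.trunc_specs]
        assert gfp.global_stats.min == min(s.lower for s in specs)
        assert gfp.global_stats.max == max(s.upper for s in specs)


class TestPlan:
    def test_isotropic_spacing_propagates(self):
        ds = make_dataset(n_institutions=1, n_train=4, n_test=1,
                          spacing=(1.0, 1.0, 1.0))
        lf = fl.compute_local_fingerprint("I1", ds.train_volumes("I1"), NOSYN)
        plan = fl.derive_plan(fl.build_global_fingerprint([lf], NOSYN))
        assert plan.target_spacing == (1.0, 1.0, 1.0)

    def test_clip_range_is_global_percentiles(self, global_fingerprint, plan):
        assert plan.clip_lo == global_fingerprint.global_stats.p0_5
        assert plan.clip_hi == global_fingerprint.global_stats.p99_5

    def test_candidate_scales_match_sphere_radius_oracle(self, dataset):
        # box volumes {8, 64, 512}: p10/p50/p90 interpolate between them
        vols = np.array([8.0, 64.0, 512.0])
        fps = []
        for j, v in enumerate(vols):
            side = round(v ** (1 / 3))
            box = BoxAnnotation((0, side, 0, side, 0, side), "benign")
            fps.append(_volume_from_array(np.random.default_rng(j).normal(size=(16, 16, 16)),
                                          image_id=f"v{j}", boxes=[box]))
        lf = fl.compute_local_fingerprint("I1", fps, NOSYN)
        plan = fl.derive_plan(fl.build_global_fingerprint([lf], NOSYN))
        expected = sorted((3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0)
                          for v in np.percentile(vols, [10, 50, 90]))
        assert list(plan.candidate_scales) == pytest.approx(expected)
        assert equivalent_sphere_radius(4.0 * math.pi / 3.0) == pytest.approx(1.0)

    def test_no_boxes_is_an_error(self):
        vol = _volume_from_array(np.random.default_rng(0).normal(size=(16, 16, 16)))
        lf = fl.compute_local_fingerprint("I1", [vol], NOSYN)
        with pytest.raises(ValueError):
            fl.derive_plan(fl.build_global_fingerprint([lf], NOSYN))
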