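"""Candidate proposal, losses, local training, inference."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fedlesion as fl
from fedlesion import detector
from fedlesion.detector import (Candidate, FocalConfig, HNMConfig, MoonConfig,
                                ProxConfig, TrainConfig, forward,
                                get_parameters, init_model, set_parameters)


class TestFocalLoss:
    @given(p=st.floats(0.01, 0.99), y=st.integers(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_gamma_zero_is_alpha_weighted_cross_entropy(self, p, y):
        ce = -math.log(p) if y == 1 else -math.log(1 - p)
        got = fl.focal_loss(p, y, FocalConfig(alpha=0.5, gamma=0.0))
        assert got == pytest.approx(0.5 * ce, rel=1e-9)

    def test_loss_vanishes_as_pt_approaches_one(self):
        cfg = FocalConfig(alpha=0.25, gamma=2.0)
        assert fl.focal_loss(1.0 - 1e-9, 1, cfg) < 1e-12
        assert fl.focal_loss(1e-9, 0, cfg) < 1e-12

    def test_direct_evaluation_oracle(self):
        # y=1, p=0.9, gamma=2, alpha=0.25: -0.25 * 0.1^2 * log(0.9)
        expected = -0.25 * (1 - 0.9) ** 2 * math.log(0.9)
        assert fl.focal_loss(0.9, 1, FocalConfig(0.25, 2.0)) == pytest.approx(expected)

    @given(p=st.floats(0.001, 0.999))
    @settings(max_examples=50, deadline=None)
    def test_nonnegative_and_decreasing_in_pt(self, p):
        cfg = FocalConfig(alpha=0.25, gamma=2.0)
        assert fl.focal_loss(p, 1, cfg) >= 0.0
        assert fl.focal_loss(min(p + 1e-3, 0.9999), 1, cfg) <= fl.focal_loss(p, 1, cfg)

    def test_out_of_range_scores_clamped(self):
        cfg = FocalConfig(0.5, 0.0)
        assert np.isfinite(fl.focal_loss(1.5, 1, cfg))
        assert np.isfinite(fl.focal_loss(-0.5, 0, cfg))


class TestHardNegativeMining:
    def test_top_k_by_loss(self):
        losses = np.array([0.1, 0.9, 0.3, 0.8, 0.2, 0.7, 0.4, 0.6, 0.05, 0.5])
        idx = fl.select_hard_negatives(losses, n_pos=2, cfg=HNMConfig(3))
        assert sorted(losses[idx], reverse=True) == [0.9, 0.8, 0.7, 0.6, 0.5, 0.4]

    def test_saturation_returns_all(self):
        idx = fl.select_hard_negatives(np.array([0.1, 0.2]), n_pos=5, cfg=HNMConfig(3))
        assert idx.tolist() == [0, 1]

    def test_matches_sorting_oracle(self):
        rng = np.random.default_rng(0)
        losses = rng.uniform(size=50)
        idx = fl.select_hard_negatives(losses, n_pos=4, cfg=HNMConfig(3))
        oracle = np.argsort(-losses)[:12]
        assert set(idx.tolist()) == set(oracle.tolist())

    def test_zero_positives_still_mines_one_quota(self):
        idx = fl.select_hard_negatives(np.arange(10.0), n_pos=0, cfg=HNMConfig(3))
        assert len(idx) == 3


@pytest.fixture(scope="module")
def easy_dataset():
    # contrast far above the noise floor: every lesion is findable
    from conftest import make_dataset

    return make_dataset(n_institutions=2, n_train=8, n_test=2,
                        lesion_contrast_range=(40.0, 80.0))


class TestProposals:
    def test_constant_image_yields_no_candidates(self, plan):
        vol = fl.AnnotatedVolume(image=np.full((20, 20, 20), 5.0),
                                 spacing=(1, 1, 1), image_id="c", manufacturer="m")
        assert fl.propose_candidates(vol, plan) == []

    def test_bright_blob_is_proposed(self, easy_dataset, plan):
        vol = easy_dataset.train_volumes("I1")[0]
        cands = fl.propose_candidates(vol, plan)
        for gt in vol.boxes:
            assert any(fl.iou(c.box, gt.box) >= 0.1 for c in cands)

    def test_proposal_recall_on_easy_dataset(self, easy_dataset, plan):
        hits = total = 0
        for inst in easy_dataset.institution_ids():
            for vol in easy_dataset.train_volumes(inst):
                cands = fl.propose_candidates(vol, plan)
                for gt in vol.boxes:
                    total += 1
                    hits += any(fl.iou(c.box, gt.box) >= 0.1 for c in cands)
        assert total > 0 and hits / total >= 0.9

    def test_feature_vectors_and_flags_consistent(self, train_candidates):
        d = len(detector.FEATURE_NAMES)
        for c in train_candidates:
            assert c.feature_vector.shape == (d,)
            assert 0.0 <= c.iou_with_gt <= 1.0
            assert c.is_positive == (c.iou_with_gt >= detector.MATCH_IOU)


class TestModelState:
    def test_parameter_round_trip_is_identity(self):
        state = init_model(seed=1)
        w = get_parameters(state)
        state2 = set_parameters(state, w)
        assert np.array_equal(state2.w, state.w)
        assert state2.w is not state.w

    def test_representation_dimension(self, train_candidates):
        state = init_model(seed=0)
        X = np.stack([c.feature_vector for c in train_candidates[:7]])
        z = fl.detector.representation(state, X)
        assert z.shape == (7, state.representation_dim)

    def test_analytic_gradient_matches_finite_differences(self):
        # covers base loss (both objectives) + prox + moon paths
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, detector.N_FEATURES))
        y = (rng.uniform(size=12) < 0.4).astype(float)
        y[0], y[1] = 1.0, 0.0
        state = init_model(seed=5)
        glob = init_model(seed=6)
        prev = init_model(seed=7)
        for loss in ("focal", "hnm"):
            cfg = TrainConfig(loss=loss)
            prox = ProxConfig(mu=0.7, w_global=glob.w)
            moon = MoonConfig(mu=0.9, tau=0.5, w_global=glob.w)

            def objective(w):
                s = set_parameters(state, w)
                p, (_, _, _, _, h2) = forward(s, X)
                if loss == "focal":
                    base = float(np.mean(fl.focal_loss(p, y, cfg.focal)))
                else:
                    ce = detector._cross_entropy(p, y)
                    wts = np.zeros(len(y))
                    pos = y == 1
                    wts[pos] = 1.0
                    neg = np.nonzero(~pos)[0]
                    hard = fl.select_hard_negatives(ce[neg], int(pos.sum()), cfg.hnm)
                    wts[neg[hard]] = 1.0
                    base = float((wts * ce).sum() / max(wts.sum(), 1.0))
                zg = detector.representation(glob, X)
                zp = detector.representation(prev, X)
                mloss, _ = detector._moon_batch(h2, zg, zp, moon.mu, moon.tau)
                return (base + float(mloss.mean())
                        + 0.5 * prox.mu * float(np.sum((w - glob.w) ** 2)))

            grad, _ = detector._batch_gradient(state, X, y, cfg, prox, moon,
                                               glob, prev)
            idx = rng.choice(state.w.size, size=25, replace=False)
            eps = 1e-6
            for i in idx:
                wp, wm = state.w.copy(), state.w.copy()
                wp[i] += eps
                wm[i] -= eps
                num = (objective(wp) - objective(wm)) / (2 * eps)
                assert grad[i] == pytest.approx(num, rel=2e-4, abs=1e-7)


class TestLocalTrain:
    def test_zero_epochs_returns_input_weights(self, train_candidates):
        state = init_model(seed=0)
        new, losses = fl.local_train(state, train_candidates,
                                     TrainConfig(epochs=0), seed=1)
        assert np.array_equal(new.w, state.w) and losses == []

    def test_zero_mu_prox_equals_no_prox(self, train_candidates):
        state = init_model(seed=0)
        a, _ = fl.local_train(state, train_candidates, TrainConfig(epochs=2), seed=2)
        b, _ = fl.local_train(state, train_candidates, TrainConfig(epochs=2), seed=2,
                              prox_cfg=ProxConfig(mu=0.0, w_global=state.w + 1.0))
        assert np.array_equal(a.w, b.w)

    def test_losses_decrease_on_separable_features(self):
        rng = np.random.default_rng(0)
        cands = []
        for i in range(200):
            pos = i % 2 == 0
            f = rng.normal(loc=(2.0 if pos else -2.0), scale=0.3,
                           size=detector.N_FEATURES)
            cands.append(Candidate(image_id="x", box=(0, 2, 0, 2, 0, 2),
                                   feature_vector=f, iou_with_gt=float(pos),
                                   is_positive=pos))
        _, losses = fl.local_train(init_model(seed=1), cands,
                                   TrainConfig(epochs=5, loss="hnm"), seed=3)
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_training_is_deterministic(self, train_candidates):
        a, la = fl.local_train(init_model(seed=0), train_candidates,
                               TrainConfig(epochs=3), seed=5)
        b, lb = fl.local_train(init_model(seed=0), train_candidates,
                               TrainConfig(epochs=3), seed=5)
        assert np.array_equal(a.w, b.w) and la == lb

    def test_single_class_candidates_rejected(self, train_candidates):
        only_pos = [c for c in train_candidates if c.is_positive]
        with pytest.raises(ValueError, match="easier synthetic"):
            fl.local_train(init_model(seed=0), only_pos, TrainConfig(epochs=1), seed=0)


class TestPredict:
    def test_threshold_above_max_score_empties_output(self, dataset, plan, trained_state):
        vol = dataset.test_volumes("I1")[0]
        assert fl.predict(trained_state, vol, plan, min_score=1.0 + 1e-9) == []

    def test_no_filtering_returns_one_detection_per_proposal(self, dataset, plan,
                                                             trained_state):
        vol = dataset.test_volumes("I1")[0]
        cands = fl.propose_candidates(vol, plan)
        dets = fl.predict(trained_state, vol, plan, min_score=0.0, min_object_size=0.0)
        assert len(dets) == len(cands)
        assert all(d.score >= n.score for d, n in zip(dets, dets[1:]))

    def test_raising_min_score_never_adds_detections(self, dataset, plan, trained_state):
        vol = dataset.test_volumes("I2")[0]
        counts = [len(fl.predict(trained_state, vol, plan, min_score=s))
                  for s in np.linspace(0.0, 1.0, 11)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))
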