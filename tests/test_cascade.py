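"""Gentle-AdaBoost stages, cascade training, and sliding-window detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spinecurve as sc
from spinecurve.cascade import (
    StageClassifier,
    Stump,
    classify_window,
    detect,
    init_weights,
    load_model,
    save_model,
    train_stage,
    train_weak_learner,
    update_weights,
)


def _separable_2d(n=60, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal([2, 2], 0.4, (n // 2, 2)), rng.normal([-2, -2], 0.4, (n // 2, 2))]
    )
    y = np.concatenate([np.ones(n // 2), np.zeros(n // 2)])
    return X, y


def _stump_oracle(X, y, w):
    """Exhaustive scan over every feature, threshold and polarity."""
    best = (np.inf, None)
    for j in range(X.shape[1]):
        values = np.unique(X[:, j])
        cands = np.concatenate([(values[:-1] + values[1:]) / 2, values[-1:]])
        for th in cands:
            for pol in (1, -1):
                pred = (X[:, j] <= th) if pol == 1 else (X[:, j] > th)
                err = float(np.sum(w * np.abs(pred.astype(float) - y)))
                if err < best[0] - 1e-15:
                    best = (err, (j, th, pol))
    return best


class TestWeights:
    def test_balanced_classes(self):
        w = init_weights(np.array([0, 0, 1, 1]))
        assert np.allclose(w, 0.25)

    def test_unbalanced_classes(self):
        w = init_weights(np.array([0, 0, 0, 0, 0, 1]))
        assert np.allclose(w[:5], 0.1) and w[5] == pytest.approx(0.5)
        assert w.sum() == pytest.approx(1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(1, 30), st.integers(1, 30))
    def test_weights_always_sum_to_one(self, m, l):
        y = np.concatenate([np.zeros(m), np.ones(l)])
        assert init_weights(y).sum() == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            init_weights(np.ones(4))

    def test_update_shrinks_correct_samples_by_beta(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([1.0, 1.0, 0.0, 0.0])
        w = np.full(4, 0.25)
        # stump misclassifying sample 2 on purpose: threshold 2.5, pol +1
        stump = Stump(feature=0, threshold=2.5, polarity=1, error=0.25)
        w2 = update_weights(w, stump, X, y)
        assert w2.sum() == pytest.approx(1.0)
        # the misclassified sample keeps its raw weight, correct ones are
        # multiplied by beta = eps/(1-eps) = 1/3 before renormalization
        raw = np.array([0.25 / 3, 0.25 / 3, 0.25, 0.25 / 3])
        assert np.allclose(w2, raw / raw.sum())

    def test_misclassified_relative_weight_increases(self):
        X, y = _separable_2d(seed=1)
        w = init_weights(y)
        stump = train_weak_learner(X, y, w)
        stump.error = 0.3  # pretend imperfect so beta < 1
        wrong = stump.predict(X) != y
        if not wrong.any():
            wrong[0] = True
        w2 = update_weights(w, stump, X, y)
        assert w2[wrong].sum() / w2.sum() >= w[wrong].sum() / w.sum()


class TestWeakLearner:
    def test_perfect_stump_on_separable_data(self):
        X, y = _separable_2d()
        stump = train_weak_learner(X, y, init_weights(y))
        assert stump.error == pytest.approx(0.0, abs=1e-12)
        assert np.array_equal(stump.predict(X), y)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 6))
        y = (rng.random(25) > 0.5).astype(float)
        if y.sum() in (0, 25):
            y[0] = 1 - y[0]
        w = rng.random(25)
        w /= w.sum()
        stump = train_weak_learner(X, y, w)
        best_err, _ = _stump_oracle(X, y, w)
        assert stump.error == pytest.approx(best_err, abs=1e-12)

    def test_duplicated_samples_with_halved_weights_unchanged(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 3))
        y = (rng.random(20) > 0.5).astype(float)
        y[0], y[1] = 1, 0
        w = np.full(20, 1 / 20)
        s1 = train_weak_learner(X, y, w)
        X2 = np.vstack([X, X])
        y2 = np.concatenate([y, y])
        w2 = np.full(40, 1 / 40)
        s2 = train_weak_learner(X2, y2, w2)
        assert (s1.feature, s1.threshold, s1.polarity) == (
            s2.feature,
            s2.threshold,
            s2.polarity,
        )

    def test_constant_features_rejected(self):
        X = np.ones((10, 3))
        y = np.concatenate([np.ones(5), np.zeros(5)])
        with pytest.raises(ValueError):
            train_weak_learner(X, y, init_weights(y))


class TestStage:
    def test_separable_stage_reaches_targets_quickly(self):
        X, y = _separable_2d(n=80, seed=4)
        stage = train_stage(X, y, 0.9, 0.0001, max_learners=3, min_learners=1)
        assert stage.met_targets
        assert stage.fpr == 0.0 and stage.tpr == 1.0
        assert len(stage.stumps) <= 3

    def test_stage_score_is_additive(self):
        X, y = _separable_2d(n=40, seed=5)
        stage = train_stage(X, y, 0.9, 0.03, max_learners=6, min_learners=4)
        manual = np.zeros(len(y))
        for stump in stage.stumps:
            manual += stump.alpha * stump.predict(X)
        assert np.allclose(stage.scores(X), manual)

    def test_half_alpha_sum_threshold_is_majority_vote(self):
        # With the un-adjusted threshold, the decision is the weighted
        # majority vote of the ensemble.
        X, y = _separable_2d(n=40, seed=6)
        stage = train_stage(X, y, 0.9, 0.03, max_learners=5, min_learners=3)
        vote = StageClassifier(
            stage.stumps, stage.alpha_sum / 2, stage.tpr, stage.fpr, True
        )
        scores = stage.scores(X)
        assert np.array_equal(vote.decide(X), scores >= stage.alpha_sum / 2)

    def test_training_error_nonincreasing_on_separable_data(self):
        X, y = _separable_2d(n=60, seed=7)
        errs = []
        for t in range(1, 5):
            stage = train_stage(X, y, 0.99, 1e-9, max_learners=t, min_learners=t)
            pred = stage.scores(X) >= stage.alpha_sum / 2
            errs.append(float(np.mean(pred != y)))
        assert all(b <= a + 1e-12 for a, b in zip(errs, errs[1:]))

    def test_unreachable_targets_warn(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 2))  # pure noise labels
        y = (rng.random(40) > 0.5).astype(float)
        y[0], y[1] = 1, 0
        with pytest.warns(UserWarning):
            stage = train_stage(X, y, 0.999, 1e-6, max_learners=2, min_learners=1)
        assert not stage.met_targets


class TestCascade:
    def test_stage_reports_and_conjunction(self, phantom_setup):
        model = phantom_setup.model
        assert 1 <= len(model.stages) <= phantom_setup.cfg.detector.n_stages
        for row in model.report:
            assert row["tpr"] >= phantom_setup.cfg.detector.tpr_target
            assert row["fpr"] <= phantom_setup.cfg.detector.fpr_target

    def test_training_positive_accepted_background_rejected(self, phantom_setup):
        from spinecurve.phantom import generate_training_patches

        spec = phantom_setup.train_specs[0]
        patches, labels = generate_training_patches(
            spec, 6, 6, window=phantom_setup.cfg.features.window
        )
        accepted_pos = sum(
            classify_window(phantom_setup.model, p)[0] for p in patches[labels == 1]
        )
        assert accepted_pos >= 5  # TPR target 0.9 per stage
        uniform = np.full(phantom_setup.cfg.features.window, 0.3)
        assert not classify_window(phantom_setup.model, uniform)[0]

    def test_rejection_is_monotone_in_stages(self, phantom_setup):
        import copy

        model = phantom_setup.model
        if len(model.stages) < 2:
            pytest.skip("cascade trained a single stage")
        truncated = copy.deepcopy(model)
        truncated.stages = truncated.stages[:1]
        rng = np.random.default_rng(9)
        for _ in range(10):
            patch = rng.random(model.window)
            full_ok, _ = classify_window(model, patch)
            trunc_ok, _ = classify_window(truncated, patch)
            if not trunc_ok:
                assert not full_ok  # a later stage can never un-reject

    def test_detection_numbers_follow_raster_order(self, phantom_setup):
        spec = sc.spec_for_angle(15.0, seed=500)
        image, truth = sc.generate_spine_phantom(spec)
        dets = detect(phantom_setup.model, image, phantom_setup.cfg.detector)
        assert [d.number for d in dets] == list(range(1, len(dets) + 1))
        tops = [d.top for d in dets]
        assert tops == sorted(tops)
        assert sc.detection_recall(dets, truth, 0.5) >= 0.9

    def test_pure_noise_image_yields_no_detections(self, phantom_setup):
        rng = np.random.default_rng(10)
        noise = np.clip(rng.normal(0.25, 0.05, (128, 96)), 0, 1)
        assert detect(phantom_setup.model, noise, phantom_setup.cfg.detector) == []

    def test_translation_equivariance(self, phantom_setup):
        spec = sc.spec_for_angle(5.0, seed=501)
        image, _ = sc.generate_spine_phantom(spec)
        stride = phantom_setup.cfg.detector.stride
        shift = 2 * stride
        shifted = np.full_like(image, float(np.median(image)))
        shifted[shift:] = image[:-shift]
        d0 = detect(phantom_setup.model, image, phantom_setup.cfg.detector)
        d1 = detect(phantom_setup.model, shifted, phantom_setup.cfg.detector)
        tops0 = sorted(d.top for d in d0 if d.top + shift < image.shape[0] - 40)
        tops1 = sorted(d.top for d in d1 if d.top > shift + 8)
        matched = sum(
            any(abs((t0 + shift) - t1) <= stride for t1 in tops1) for t0 in tops0
        )
        assert matched >= len(tops0) - 1

    def test_image_smaller_than_window_rejected(self, phantom_setup):
        with pytest.raises(ValueError):
            detect(phantom_setup.model, np.zeros((10, 10)), phantom_setup.cfg.detector)

    def test_model_roundtrip_is_lossless(self, phantom_setup, tmp_path):
        path = tmp_path / "model.json"
        save_model(phantom_setup.model, path)
        back = load_model(path)
        assert back.feature_config == phantom_setup.model.feature_config
        np.testing.assert_array_equal(back.normalizer.mean, phantom_setup.model.normalizer.mean)
        np.testing.assert_array_equal(back.normalizer.std, phantom_setup.model.normalizer.std)
        assert len(back.stages) == len(phantom_setup.model.stages)
        for s1, s2 in zip(back.stages, phantom_setup.model.stages):
            assert s1.threshold == s2.threshold
            assert [(a.feature, a.threshold, a.polarity, a.alpha) for a in s1.stumps] == [
                (a.feature, a.threshold, a.polarity, a.alpha) for a in s2.stumps
            ]

    def test_cascade_fpr_bounded_by_stage_product(self, phantom_setup):
        # conjunction of stage tests: overall FPR on any pool cannot exceed
        # the product bound of the per-stage false-alarm targets
        from spinecurve.features import FeatureExtractor
        from spinecurve.phantom import make_background_sampler

        model = phantom_setup.model
        cfg = phantom_setup.cfg
        sampler = make_background_sampler(phantom_setup.train_specs, model.window)
        rng = np.random.default_rng(11)
        batch = sampler(300, rng)
        fx = FeatureExtractor(model.feature_config)
        X = model.normalizer.transform(fx.extract_many(batch))
        accepted, _ = model.evaluate(X)
        bound = cfg.detector.fpr_target ** len(model.stages)
        # statistical check on a fresh pool: allow a generous margin over
        # the training-pool bound
        assert accepted.mean() <= max(5 * bound, 0.05)
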