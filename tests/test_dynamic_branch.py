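"""Soft voting, calibration, and the dynamic ensemble."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitfusion import (
    EnsembleConfig,
    EnsembleWeights,
    DynamicEnsemble,
    FeatureOptions,
    GaitParams,
    PipelineConfig,
    PlattCalibrator,
    TemperatureScaler,
    assemble_features,
    simulate_activity,
    soft_vote,
)
from gaitfusion.preprocessing import preprocess_recording, segment_windows
from gaitfusion.types import DYNAMIC_ACTIVITIES


def _dynamic_dataset(seconds=12, seed=0):
    feats, labels, raw_p, raw_e = [], [], [], []
    for act in DYNAMIC_ACTIVITIES:
        rec = simulate_activity(GaitParams.for_activity(act), seconds,
                                seed=seed)
        rec = preprocess_recording(rec, PipelineConfig().sg_config())
        for w in segment_windows(rec):
            feats.append(assemble_features(w).values)
            labels.append(w.label)
            raw_p.append(w.pressure)
            raw_e.append(w.euler)
    return (np.array(feats), np.array(labels), np.stack(raw_p),
            np.stack(raw_e))


class TestSoftVote:
    def test_degenerate_single_model_weight(self):
        p = [np.array([[0.7, 0.1, 0.1, 0.1]]),
             np.array([[0.25, 0.25, 0.25, 0.25]]),
             np.array([[0.1, 0.1, 0.7, 0.1]])]
        out = soft_vote(p, [1.0, 0.0, 0.0])
        np.testing.assert_allclose(out, p[0])

    def test_hand_evaluated_two_model_vote(self):
        out = soft_vote([np.array([[1.0, 0, 0, 0]]),
                         np.array([[0, 1.0, 0, 0]])], [0.5, 0.5])
        np.testing.assert_allclose(out, [[0.5, 0.5, 0, 0]])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
                    min_size=2, max_size=4),
           st.lists(st.floats(0.01, 1.0), min_size=2, max_size=4))
    def test_output_is_probability_vector(self, rows, w):
        m = min(len(rows), len(w))
        probs = [np.array([r]) / np.sum(r) for r in rows[:m]]
        weights = np.array(w[:m]) / np.sum(w[:m])
        out = soft_vote(probs, weights)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(out >= 0)

    def test_invalid_inputs_rejected(self):
        p = [np.array([[0.5, 0.5, 0, 0]])] * 2
        with pytest.raises(ValueError):
            soft_vote(p, [0.7, 0.5])  # not normalized
        with pytest.raises(ValueError):
            soft_vote(p, [1.5, -0.5])  # negative weight
        with pytest.raises(ValueError):
            soft_vote([np.array([[0.9, 0.3, 0, 0]])], [1.0])  # not a pmf

    def test_unanimous_argmax_preserved_for_any_weights(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            probs = []
            for _ in range(3):
                p = rng.dirichlet(np.ones(4))
                p[2] += 1.0  # force a shared argmax
                probs.append((p / p.sum())[None, :])
            w = rng.dirichlet(np.ones(3))
            assert soft_vote(probs, w).argmax() == 2

    def test_weights_validation(self):
        with pytest.raises(ValueError):
            EnsembleWeights({"a": 0.6, "b": 0.6})
        with pytest.raises(ValueError):
            EnsembleWeights({"a": 1.5, "b": -0.5})


class TestCalibrators:
    def test_temperature_scaling_preserves_ranking(self):
        rng = np.random.default_rng(1)
        logits = rng.standard_normal((50, 4)) * 3
        y = rng.integers(0, 4, 50)
        ts = TemperatureScaler().fit(logits, y)
        before = logits.argmax(axis=1)
        after = ts.transform(logits).argmax(axis=1)
        np.testing.assert_array_equal(before, after)

    def test_temperature_reduces_overconfidence_nll(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 4, 400)
        logits = rng.standard_normal((400, 4))
        logits[np.arange(400), y] += 1.0
        logits *= 8.0  # overconfident
        ts = TemperatureScaler().fit(logits, y)
        assert ts.temperature_ > 1.5

        def nll(p):
            return -np.mean(np.log(p[np.arange(400), y] + 1e-12))

        raw = TemperatureScaler._softmax(logits)
        assert nll(ts.transform(logits)) < nll(raw)

    def test_platt_outputs_normalized_probabilities(self):
        rng = np.random.default_rng(3)
        scores = rng.standard_normal((100, 4))
        y = scores.argmax(axis=1)
        cal = PlattCalibrator().fit(scores, y)
        p = cal.transform(scores)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert (p.argmax(axis=1) == y).mean() > 0.9


class TestEnsemble:
    @pytest.fixture(scope="class")
    def data(self):
        return _dynamic_dataset()

    @pytest.fixture(scope="class")
    def trained(self, data):
        feats, labels, _, _ = data
        return DynamicEnsemble(seed=0).fit(feats, labels)

    def test_separable_dynamic_classes_recovered(self, data, trained):
        feats, labels, _, _ = data
        test_f, test_y, _, _ = _dynamic_dataset(seconds=8, seed=99)
        acc = (trained.predict(test_f) == test_y).mean()
        assert acc >= 0.95

    def test_vote_weights_form_convex_combination(self, trained):
        w = np.array(list(trained.weights_.weights.values()))
        assert np.all(w >= 0)
        assert w.sum() == pytest.approx(1.0)
        assert set(trained.weights_.weights) == {"rf", "gbdt"}

    def test_same_seed_identical_weights_and_predictions(self, data):
        feats, labels, _, _ = data
        a = DynamicEnsemble(seed=5).fit(feats, labels)
        b = DynamicEnsemble(seed=5).fit(feats, labels)
        assert a.weights_.weights == b.weights_.weights
        np.testing.assert_array_equal(a.predict(feats), b.predict(feats))

    def test_missing_class_rejected(self, data):
        feats, labels, _, _ = data
        mask = labels != "running"
        with pytest.raises(ValueError, match="missing"):
            DynamicEnsemble(seed=0).fit(feats[mask], labels[mask],
                                        expected_classes=DYNAMIC_ACTIVITIES)

    def test_misaligned_inputs_rejected(self, data):
        feats, labels, raw_p, raw_e = data
        cfg = EnsembleConfig(use_deep=True)
        with pytest.raises(ValueError, match="misaligned|missing"):
            DynamicEnsemble(cfg, seed=0).fit(feats, labels, raw_p[:-3], raw_e)

    def test_untrained_predict_rejected(self):
        with pytest.raises(ValueError):
            DynamicEnsemble().predict(np.zeros((1, 510)))

    def test_ensemble_not_much_worse_than_best_base(self, data, trained):
        feats, labels, _, _ = data
        test_f, test_y, _, _ = _dynamic_dataset(seconds=8, seed=99)
        ens_acc = (trained.predict(test_f) == test_y).mean()
        base_accs = []
        for name in trained.models_:
            p = trained._base_probs(name, test_f, None, None)
            base_accs.append((trained.classes_[p.argmax(axis=1)]
                              == test_y).mean())
        assert ens_acc >= max(base_accs) - 0.02

    def test_dual_support_feature_separates_walking_from_running(self, data):
        feats, labels, _, _ = data
        from gaitfusion.features import FeatureOptions, feature_names
        names = feature_names(FeatureOptions(modality="fused"))
        ds_col = names.index("glob_dual_support_ratio")
        walking = feats[labels == "walking", ds_col]
        running = feats[labels == "running", ds_col]
        # both feet never load simultaneously when running
        assert np.all(running == 0.0)
        assert np.all(walking > 0.0)
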