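import numpy as np
import pytest

from wheelbouts import _lstm, ddr, synthetic
from wheelbouts.classify import (
    BaselineANNClassifier,
    BiLSTMMotionClassifier,
    MotionLabels,
    SegmentSeries,
    label_from_truth,
    segment,
)
from wheelbouts.ddr import NormalizedSequence, ddr_pipeline
from wheelbouts.errors import InsufficientDataError, ValidationError
from wheelbouts.io import IntervalTruth
from wheelbouts.postprocess import smooth


def _seq(values, dt=0.1):
    values = np.asarray(values, dtype=float)
    return NormalizedSequence(v=values, t_s=np.arange(len(values)) * dt)


class TestSegmentation:
    def test_remainder_dropped(self):
        segs = segment(_seq(np.linspace(0, 1, 25)), 10)
        assert len(segs) == 2
        assert segs.width == 10

    def test_exact_fit_single_segment(self):
        segs = segment(_seq(np.linspace(0, 1, 10)), 10)
        assert len(segs) == 1
        assert segs.start_s[0] == 0.0
        assert segs.end_s[0] == pytest.approx(0.9)

    def test_concatenation_reconstructs_prefix(self, rng):
        vals = rng.uniform(size=37)
        segs = segment(_seq(vals), 10)
        np.testing.assert_array_equal(segs.values.ravel(), vals[:30])

    def test_too_short_rejected(self):
        with pytest.raises(InsufficientDataError):
            segment(_seq(np.zeros(9)), 10)


class TestLabelFromTruth:
    def _segs(self):
        # two 1-s segments: [0, 0.9] and [1.0, 1.9]
        return segment(_seq(np.zeros(20)), 10)

    def test_fully_moving_and_fully_stationary(self):
        truth = IntervalTruth([0.0, 1.0], [1.0, 2.0], ["moving", "stationary"])
        labels = label_from_truth(self._segs(), truth)
        assert list(labels.labels) == [1, 0]

    @pytest.mark.parametrize("boundary,expected", [(0.6, 1), (0.4, 0), (0.45, 1)])
    def test_majority_overlap_with_tie_to_moving(self, boundary, expected):
        # one segment [0, 0.9]; moving share of covered time crosses 50%
        segs = segment(_seq(np.zeros(10)), 10)
        truth = IntervalTruth([0.0, boundary], [boundary, 2.0], ["moving", "stationary"])
        assert label_from_truth(segs, truth).labels[0] == expected

    def test_uncovered_span_rejected(self):
        truth = IntervalTruth([0.0], [1.2], ["moving"])
        with pytest.raises(ValidationError):
            label_from_truth(self._segs(), truth)


class TestNetwork:
    def test_gradients_match_finite_differences(self):
        """Analytic BPTT through both bidirectional layers and the dense
        head agrees with central finite differences."""
        rng = np.random.default_rng(0)
        p = _lstm.init_params(rng, in_dim=3, hidden=4, n_layers=2, dense=5)
        X = rng.normal(size=(2, 6, 3))
        Y = rng.integers(0, 2, size=(2, 6)).astype(float)
        P, cache = _lstm.forward(X, p, 2)
        grads = _lstm.backward(P, Y, cache, p, 2)
        eps = 1e-5
        for key in p:
            flat = p[key].reshape(-1)
            idxs = rng.choice(flat.size, size=min(6, flat.size), replace=False)
            for i in idxs:
                orig = flat[i]
                flat[i] = orig + eps
                lp = _lstm.bce_loss(_lstm.forward(X, p, 2)[0], Y)
                flat[i] = orig - eps
                lm = _lstm.bce_loss(_lstm.forward(X, p, 2)[0], Y)
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[key].reshape(-1)[i] == pytest.approx(num, abs=1e-7)

    def test_shape_contract_and_sigmoid_range(self):
        model = BiLSTMMotionClassifier(hidden_units=8, random_state=0).build()
        proba = model.predict_proba(np.zeros((50, 10)))
        assert proba.shape == (50, 2)
        assert np.all((proba > 0) & (proba < 1))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_same_seed_builds_identical_models(self, rng):
        X = rng.uniform(size=(30, 10))
        a = BiLSTMMotionClassifier(hidden_units=8, random_state=5).build()
        b = BiLSTMMotionClassifier(hidden_units=8, random_state=5).build()
        np.testing.assert_array_equal(a.predict_proba(X), b.predict_proba(X))


def _toy_stream(rng, n=240, w=10):
    """Synthetic segment stream with an obvious moving/stationary contrast."""
    y = np.zeros(n, dtype=int)
    i = 0
    state = 0
    while i < n:
        run = int(rng.integers(8, 20))
        y[i : i + run] = state
        state = 1 - state
        i += run
    X = rng.uniform(0.0, 0.08, size=(n, w))
    X[y == 1] = rng.uniform(0.2, 1.0, size=(int(y.sum()), w))
    return X, y


def _small_model(**kw):
    defaults = dict(hidden_units=8, dense_units=8, chunk_len=20, max_epochs=40,
                    patience=10, random_state=0)
    defaults.update(kw)
    return BiLSTMMotionClassifier(**defaults)


class TestTraining:
    def test_single_class_data_rejected(self, rng):
        X = rng.uniform(size=(60, 10))
        with pytest.raises(ValidationError):
            _small_model().fit(X, np.zeros(60, dtype=int))

    def test_patience_zero_stops_at_first_non_improving_epoch(self, rng):
        X, y = _toy_stream(rng)
        model = _small_model(patience=0, max_epochs=40).fit(X, y)
        accs = [h["val_accuracy"] for h in model.history_]
        best_before_last = max(accs[:-1], default=-1)
        assert accs[-1] <= best_before_last  # stopped exactly on the first plateau epoch
        assert model.n_epochs_ < 40

    def test_training_is_reproducible(self, rng):
        X, y = _toy_stream(rng)
        pa = _small_model(max_epochs=8).fit(X, y).predict_proba(X)
        pb = _small_model(max_epochs=8).fit(X, y).predict_proba(X)
        np.testing.assert_array_equal(pa, pb)

    def test_label_flip_symmetry(self, rng):
        """Training on complemented labels yields comparable skill on the
        complemented task (the architecture has no class asymmetry)."""
        X, y = _toy_stream(rng)
        cut = 160
        normal = _small_model(max_epochs=25).fit(X[:cut], y[:cut])
        acc_normal = np.mean(normal.predict(X[cut:]) == y[cut:])
        flipped = _small_model(max_epochs=25).fit(X[:cut], 1 - y[:cut])
        acc_flipped = np.mean(flipped.predict(X[cut:]) == 1 - y[cut:])
        assert abs(acc_normal - acc_flipped) <= 0.1

    def test_heldout_accuracy_on_simulated_trials(self, reference_model):
        """Study-protocol training reaches >= 0.95 accuracy on the held-out
        75% of the second simulated trial."""
        assert reference_model.holdout_accuracy_ >= 0.95

    def test_save_load_round_trip(self, tmp_path, rng):
        X, y = _toy_stream(rng)
        model = _small_model(max_epochs=5).fit(X, y)
        path = tmp_path / "model.npz"
        model.save(path)
        back = BiLSTMMotionClassifier.load(path)
        np.testing.assert_array_equal(back.predict_proba(X), model.predict_proba(X))
        assert back.segment_width == model.segment_width


class TestPrediction:
    def test_zero_motion_input_is_all_stationary(self, reference_model):
        """An all-zero normalized sequence is the DDR signature of a parked
        wheelchair; the trained model must call every segment stationary."""
        labels = reference_model.predict(np.zeros((80, 10)))
        assert np.all(labels == 0)

    def test_prediction_is_deterministic(self, reference_model, rng):
        X = rng.uniform(size=(60, 10))
        np.testing.assert_array_equal(reference_model.predict(X), reference_model.predict(X))

    def test_width_mismatch_rejected(self, reference_model):
        segs = SegmentSeries(values=np.zeros((4, 5)), start_s=np.arange(4.0), end_s=np.arange(4.0) + 0.5)
        with pytest.raises(ValidationError):
            reference_model.predict_labels(segs)


class TestBaselineANN:
    def _train_pair(self, reference_model):
        sc = synthetic.preset_scenario("series1")
        prof = synthetic.device_catalog()[0]
        rec, truth = synthetic.generate_recording(sc, prof, 321)
        segs = segment(ddr_pipeline(rec), 10)
        y = np.asarray(label_from_truth(segs, truth).labels)
        ann = BaselineANNClassifier(random_state=0).fit(segs.values, y)
        return ann

    def test_shape_and_determinism(self, rng):
        X, y = _toy_stream(rng)
        ann = BaselineANNClassifier(random_state=0).fit(X, y)
        proba = ann.predict_proba(X)
        assert proba.shape == (len(X), 2)
        ann2 = BaselineANNClassifier(random_state=0).fit(X, y)
        np.testing.assert_array_equal(proba, ann2.predict_proba(X))

    def test_ann_labels_switch_at_least_as_often_as_rnn(self, reference_model):
        """On a disturbance-heavy run the context-free baseline produces at
        least as many label transitions as the recurrent model."""
        ann = self._train_pair(reference_model)
        sc = synthetic.preset_scenario("disturbed")
        prof = synthetic.device_catalog()[3]
        rec, _ = synthetic.generate_recording(sc, prof, 99)
        segs = segment(ddr_pipeline(rec), 10)
        rnn_labels = np.asarray(reference_model.predict_labels(segs).labels)
        ann_labels = np.asarray(ann.predict_labels(segs).labels)
        assert np.sum(np.diff(ann_labels) != 0) >= np.sum(np.diff(rnn_labels) != 0)
        # smoothing reduces transition counts for both, never increases
        for labels in (rnn_labels, ann_labels):
            sm = np.asarray(smooth(MotionLabels(labels=labels)).labels)
            assert np.sum(np.diff(sm) != 0) <= np.sum(np.diff(labels) != 0)
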