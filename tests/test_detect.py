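import numpy as np
import pytest

from glyco import detect, nn
from glyco.detect import (ARCHITECTURES, DetectorConfig, SequenceBatch,
                          TrainedDetector, build_model, build_sequences,
                          class_weights, evaluate, predict_events,
                          recurrent_param_count)
from glyco.features import FeatureTable


def table_with_labels(n=60, F=3, invalid=()):
    rng = np.random.default_rng(0)
    vals = rng.standard_normal((n, F))
    valid = np.ones(n, dtype=bool)
    for i in invalid:
        valid[i] = False
    tbl = FeatureTable(names=[f"f{i}" for i in range(F)], values=vals,
                       valid_mask=valid)
    labels = rng.integers(0, 4, n)
    return tbl, labels


SMALL = DetectorConfig(lstm_units=8, dense_units=6, conv_filters=(4, 6),
                       dropout=0.0, recurrent_dropout=0.0)


class TestSequences:
    def test_exactly_one_window_from_24_rows(self):
        tbl, labels = table_with_labels(n=24)
        b = build_sequences(tbl, labels)
        assert b.n == 1
        assert b.targets[0] == labels[23]  # label of the window's last sample

    def test_windows_never_span_invalid_rows(self):
        tbl, labels = table_with_labels(n=60, invalid=[30])
        b = build_sequences(tbl, labels)
        for e in b.end_index:
            assert not (e - 23 <= 30 <= e)

    def test_class_weights_inverse_proportional(self):
        targets = np.repeat([0, 1, 2, 3], [800, 100, 80, 20])
        w = class_weights(targets)
        total = len(targets)
        for c, size in zip(range(4), [800, 100, 80, 20]):
            np.testing.assert_allclose(w[targets == c], total / (4 * size))

    def test_too_short_is_fatal(self):
        tbl, labels = table_with_labels(n=10)
        with pytest.raises(ValueError):
            build_sequences(tbl, labels)


class TestModels:
    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_forward_probabilities_on_simplex(self, arch):
        m = build_model(arch, (24, 5), SMALL, seed=0)
        x = np.random.default_rng(1).standard_normal((7, 24, 5))
        p = m.predict_proba(x)
        assert np.all(np.isfinite(p))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_bilstm_recurrent_params_exceed_lstm_by_54pct(self):
        b = build_model("conv1d_lstm", (24, 5), SMALL, seed=0)
        d = build_model("conv1d_bilstm", (24, 5), SMALL, seed=0)
        assert recurrent_param_count(d) >= 1.54 * recurrent_param_count(b)

    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_param_count_invariant_across_seeds(self, arch):
        counts = {build_model(arch, (24, 5), SMALL, seed=s).n_params()
                  for s in range(3)}
        assert len(counts) == 1

    def test_unknown_architecture_fatal(self):
        with pytest.raises(ValueError):
            build_model("transformer", (24, 5), SMALL)

    def test_masking_holds_state_through_flagged_steps(self):
        """A masked (all-zero) timestep must not change the LSTM output."""
        m = build_model("lstm", (24, 3), SMALL, seed=0)
        rng = np.random.default_rng(2)
        x = rng.standard_normal((1, 24, 3))
        x[0, 10] = 0.0  # masked step
        x_alt = x.copy()
        base = m.forward(x, training=False)
        np.testing.assert_allclose(m.forward(x_alt, training=False), base)

    def test_convlstm_accepts_5d_input(self):
        m = nn.ConvLSTM(4, 6, rng=np.random.default_rng(0))
        x = np.random.default_rng(1).standard_normal((3, 10, 1, 1, 4))
        out = m.forward(x)
        assert out.shape == (3, 6)


class TestTrainingDeterminism:
    def test_identical_seed_identical_history(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 24, 4))
        y = rng.integers(0, 4, 40)
        hists = []
        for _ in range(2):
            m = build_model("lstm", (24, 4), SMALL, seed=5)
            hists.append(m.fit(X, y, epochs=3, batch_size=16, lr=1e-3, seed=5))
        assert hists[0] == hists[1]  # bitwise

    def test_duplicated_window_identical_prediction(self):
        m = build_model("conv1d_lstm", (24, 4), SMALL, seed=0)
        x = np.random.default_rng(4).standard_normal((1, 24, 4))
        p = m.predict_proba(np.concatenate([x, x]))
        np.testing.assert_array_equal(p[0], p[1])


class TestEvaluate:
    def test_perfect_prediction(self):
        y = np.array([0, 1, 2, 3, 0, 1])
        m = evaluate(y, y)
        assert m["accuracy"] == 1.0 and m["weighted_f1"] == 1.0
        conf = np.array(m["confusion"])
        assert (conf.sum() == conf.trace())

    def test_hand_built_example(self):
        truth = np.array([0, 0, 0, 0, 1, 1, 2, 2, 3, 3])
        pred = truth.copy()
        pred[0] = 1   # one C00 -> C01 error
        pred[6] = 3   # one C10 -> C11 error
        m = evaluate(pred, truth)
        assert m["accuracy"] == pytest.approx(0.8)
        # hand confusion arithmetic: recall per class 3/4, 2/2, 1/2, 2/2
        assert m["recall"] == pytest.approx([0.75, 1.0, 0.5, 1.0])
        # precision: 3/3, 2/3, 1/1, 2/3
        assert m["precision"] == pytest.approx([1.0, 2 / 3, 1.0, 2 / 3])
        f1 = m["f1"]
        wf1 = (4 * f1[0] + 2 * f1[1] + 2 * f1[2] + 2 * f1[3]) / 10
        assert m["weighted_f1"] == pytest.approx(wf1)

    def test_single_class_truth(self):
        truth = np.zeros(6, dtype=int)
        pred = np.array([0, 0, 0, 0, 1, 0])
        m = evaluate(pred, truth)
        assert m["weighted_f1"] == pytest.approx(m["f1"][0])

    def test_confusion_rows_equal_supports(self):
        rng = np.random.default_rng(5)
        truth = rng.integers(0, 4, 100)
        pred = rng.integers(0, 4, 100)
        m = evaluate(pred, truth)
        np.testing.assert_array_equal(np.array(m["confusion"]).sum(axis=1),
                                      m["support"])

    def test_empty_is_fatal(self):
        with pytest.raises(ValueError):
            evaluate(np.array([]), np.array([]))


def imbalanced_sequences(seed, n_major=260, n_minor=20):
    """Majority class 0 vs a subtle minority class 1."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for _ in range(n_major):
        X.append(rng.standard_normal((24, 4)))
        y.append(0)
    for _ in range(n_minor):
        w = rng.standard_normal((24, 4))
        w[:, 0] += 0.9
        X.append(w)
        y.append(1)
    X, y = np.stack(X), np.array(y)
    idx = rng.permutation(len(y))
    return X[idx], y[idx]


class TestClassWeighting:
    def test_weights_raise_minority_recall(self):
        """Inverse-class-size weighting should recover more of the rare
        class than unweighted training (paired over seeds)."""
        diffs = []
        for seed in range(5):
            Xtr, ytr = imbalanced_sequences(seed)
            Xte, yte = imbalanced_sequences(seed + 100)
            recalls = []
            for weighted in (True, False):
                m = build_model("lstm", (24, 4), SMALL, seed=seed)
                sw = class_weights(ytr) if weighted else None
                m.fit(Xtr, ytr, sample_weight=sw, epochs=15, batch_size=32,
                      lr=3e-3, seed=seed, patience=15)
                pred = m.predict_proba(Xte).argmax(1)
                minority = yte == 1
                recalls.append((pred[minority] == 1).mean())
            diffs.append(recalls[0] - recalls[1])
        assert np.mean(diffs) > 0


class TestTrainProtocol:
    def test_train_detector_end_to_end_report(self):
        rng = np.random.default_rng(7)
        n = 160
        X = rng.standard_normal((n, 24, 4))
        y = rng.integers(0, 4, n)
        # make classes separable so CV metrics are meaningful
        for c in range(4):
            X[y == c, :, c % 4] += 2.0
        tbl = FeatureTable(names=list("abcd"),
                           values=np.zeros((n + 23, 4)),
                           valid_mask=np.ones(n + 23, dtype=bool))
        batch = SequenceBatch(inputs=X, targets=y,
                              sample_weights=class_weights(y),
                              end_index=np.arange(n))
        cfg = DetectorConfig(lstm_units=8, dense_units=6, conv_filters=(4, 6),
                             epochs=10, patience=5, folds=2, seeds=2,
                             dropout=0.0, recurrent_dropout=0.0)
        dets, report = detect.train_detector(batch, "lstm", cfg, seed=1)
        assert report["n_models"] == 4  # 2 folds x 2 seeds
        assert 0 <= report["cv_accuracy_mean"] <= 1
        assert report["test"] is not None
        proba, pred = predict_events(dets[0], batch)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
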