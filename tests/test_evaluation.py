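"""Probes, balanced softmax, metrics and fine-tuning contracts."""

import numpy as np
import pytest

from wearssl.data import ValidationError
from wearssl.evaluation import (FineTuneConfig, balanced_softmax_ce,
                                balanced_softmax_ce_and_grad,
                                encode_representations, fine_tune, knn_probe,
                                linear_probe, metrics_report,
                                stratified_label_subset)


def _blobs(rng, n_per=30, sep=5.0, n_classes=3, dim=4):
    X = np.concatenate([rng.normal(sep * k, 1.0, (n_per, dim)) for k in range(n_classes)])
    y = np.repeat(np.arange(n_classes), n_per)
    return X, y


class TestKNN:
    def test_unanimous_neighbourhood_predicts_its_label(self):
        train = np.vstack([np.zeros((10, 2)), np.ones((10, 2)) * 9])
        labels = np.array([1] * 10 + [0] * 10)
        rep = knn_probe(train, labels, np.zeros((1, 2)) + 0.1, np.array([1]), k=10)
        assert rep.accuracy == 1.0

    def test_self_evaluation_with_k1_is_perfect(self):
        X = np.array([[0.0], [5.0], [10.0]])
        y = np.array([0, 1, 2])
        rep = knn_probe(X, y, X, y, k=1)
        assert rep.accuracy == 1.0 and rep.macro_f1 == 1.0

    def test_separated_gaussian_blobs_high_f1(self):
        """5-sigma separated blobs: macro-F1 >= 0.95 over 5 seeds."""
        f1s = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            Xtr, ytr = _blobs(rng)
            Xte, yte = _blobs(rng)
            f1s.append(knn_probe(Xtr, ytr, Xte, yte, k=10).macro_f1)
        assert np.mean(f1s) >= 0.95

    def test_k_larger_than_train_rejected(self):
        with pytest.raises(ValidationError):
            knn_probe(np.zeros((3, 2)), [0, 1, 0], np.zeros((1, 2)), [0], k=5)

    def test_vote_tie_broken_by_mean_distance(self):
        train = np.array([[0.0], [0.5], [10.0], [10.5]])
        labels = np.array([0, 0, 1, 1])
        rep = knn_probe(train, labels, np.array([[1.0]]), np.array([0]), k=4)
        assert rep.accuracy == 1.0            # class 0 is nearer on average


class TestLinearProbe:
    def test_separable_blobs_fit_perfectly(self):
        rng = np.random.default_rng(0)
        X, y = _blobs(rng, n_classes=2, sep=8.0)
        rep = linear_probe(X, y, X, y)
        assert rep.accuracy == 1.0

    def test_permuted_labels_are_at_chance(self):
        """Random labels over 4 balanced classes: eval macro-F1 ~ 0.25."""
        f1s = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((200, 6))
            y = rng.permutation(np.repeat(np.arange(4), 50))
            f1s.append(linear_probe(X[:100], y[:100], X[100:], y[100:]).macro_f1)
        assert abs(np.mean(f1s) - 0.25) < 0.1

    def test_indistinguishable_classes_score_half(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 3))
        Xdup = np.vstack([X, X])
        y = np.array([0] * 40 + [1] * 40)
        rep = linear_probe(Xdup, y, Xdup, y)
        assert rep.macro_f1 == pytest.approx(0.5, abs=0.17)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            linear_probe(np.zeros((5, 2)), [1] * 5, np.zeros((2, 2)), [1, 1])


class TestBalancedSoftmax:
    def test_equal_counts_reduce_to_cross_entropy(self):
        rng = np.random.default_rng(0)
        logits = rng.standard_normal((16, 4))
        labels = rng.integers(0, 4, 16)
        counts = np.full(4, 25.0)
        bs = balanced_softmax_ce(logits, labels, counts)
        m = logits.max(axis=1, keepdims=True)
        p = np.exp(logits - m)
        p /= p.sum(axis=1, keepdims=True)
        ce = float(np.mean(-np.log(p[np.arange(16), labels])))
        assert bs == pytest.approx(ce, abs=1e-12)

    def test_minority_class_toy_value(self):
        """Counts (9,1), zero logits, true = minority: -ln(1/10) = 2.30259."""
        loss = balanced_softmax_ce(np.zeros((1, 2)), np.array([1]), np.array([9.0, 1.0]))
        assert loss == pytest.approx(np.log(10), abs=1e-9)
        assert loss == pytest.approx(2.30259, abs=1e-5)

    def test_confident_true_class_drives_loss_to_zero(self):
        logits = np.array([[30.0, 0.0]])
        loss = balanced_softmax_ce(logits, np.array([0]), np.array([5.0, 5.0]))
        assert loss < 1e-10

    def test_zero_count_for_present_label_rejected(self):
        with pytest.raises(ValidationError):
            balanced_softmax_ce(np.zeros((1, 2)), np.array([1]), np.array([5.0, 0.0]))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        logits = rng.standard_normal((4, 3))
        labels = np.array([0, 2, 1, 2])
        counts = np.array([10.0, 3.0, 7.0])
        L, g = balanced_softmax_ce_and_grad(logits, labels, counts)
        for i in range(4):
            for j in range(3):
                l2 = logits.copy()
                l2[i, j] += 1e-7
                L2 = balanced_softmax_ce(l2, labels, counts)
                assert (L2 - L) / 1e-7 == pytest.approx(g[i, j], abs=1e-5)


class TestMetricsReport:
    def test_hand_computed_confusion(self):
        """Confusion [[2,0],[1,1]]: class F1s {0.8, 0.6667}, macro 0.73333."""
        y_true = np.array([0, 0, 1, 1])
        y_pred = np.array([0, 0, 0, 1])
        rep = metrics_report(y_true, y_pred)
        assert rep.per_class[0]["f1"] == pytest.approx(0.8)
        assert rep.per_class[1]["f1"] == pytest.approx(2 / 3)
        assert rep.macro_f1 == pytest.approx(0.73333, abs=1e-5)
        assert np.array_equal(rep.confusion, [[2, 0], [1, 1]])

    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        rep = metrics_report(y, y, np.eye(3)[y])
        assert rep.macro_f1 == rep.accuracy == rep.auroc == 1.0

    def test_all_one_class_on_balanced_pair(self):
        """Predicting one class on 2 balanced classes: macro-F1 = (2/3)/2."""
        y_true = np.array([0, 0, 1, 1])
        rep = metrics_report(y_true, np.zeros(4, dtype=int))
        assert rep.macro_f1 == pytest.approx(1 / 3, abs=1e-9)

    def test_macro_f1_invariant_to_relabeling(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 3, 60)
        y_pred = rng.integers(0, 3, 60)
        base = metrics_report(y_true, y_pred).macro_f1
        perm = np.array([2, 0, 1])
        assert metrics_report(perm[y_true], perm[y_pred]).macro_f1 == pytest.approx(base)

    def test_unknown_predicted_label_rejected(self):
        with pytest.raises(ValidationError):
            metrics_report([0, 1], [0, 7])

    def test_confusion_rows_equal_support(self):
        rng = np.random.default_rng(1)
        y_true = rng.integers(0, 4, 80)
        y_pred = rng.integers(0, 4, 80)
        rep = metrics_report(y_true, y_pred)
        assert np.array_equal(rep.confusion.sum(axis=1), np.bincount(y_true))


class TestFineTune:
    def test_stratified_subset_counts_and_determinism(self):
        labels = np.repeat(np.arange(4), 100)
        rng = np.random.default_rng(0)
        sel = stratified_label_subset(labels, 0.1, rng)
        assert len(sel) == 40
        assert all((labels[sel] == c).sum() == 10 for c in range(4))
        sel2 = stratified_label_subset(labels, 0.1, np.random.default_rng(0))
        assert np.array_equal(sel, sel2)

    def test_fraction_one_uses_every_label(self):
        labels = np.repeat(np.arange(3), 7)
        sel = stratified_label_subset(labels, 1.0, np.random.default_rng(0))
        assert np.array_equal(np.sort(sel), np.arange(21))

    def test_vanishing_fraction_rejected_naming_class(self):
        labels = np.repeat(np.arange(2), 4)
        with pytest.raises(ValidationError, match="class 0"):
            stratified_label_subset(labels, 0.05, np.random.default_rng(0))

    def test_fine_tune_runs_and_preserves_input_model(self, small_dataset):
        from wearssl.nn import EncoderSpec, build_encoder
        spec = EncoderSpec(widths=(4, 8), kernels=(5, 3), strides=(2, 2),
                           proj_hidden=8, proj_dim=6)
        model = build_encoder(spec, np.random.default_rng(0))
        before = model.state_dict()
        _, _, rep = fine_tune(model, small_dataset, label_fraction=1.0,
                              cfg=FineTuneConfig(epochs=2, seed=0))
        for k, v in model.state_dict().items():
            assert np.array_equal(v, before[k])       # input untouched
        assert 0.0 <= rep.macro_f1 <= 1.0


def test_probes_do_not_modify_backbone(small_dataset):
    from wearssl.nn import EncoderSpec, build_encoder
    model = build_encoder(EncoderSpec(widths=(4, 8), kernels=(5, 3), strides=(2, 2),
                                      proj_hidden=8, proj_dim=6),
                          np.random.default_rng(1))
    before = model.state_dict()
    tr, te = small_dataset.subset("train"), small_dataset.subset("test")
    h_tr = encode_representations(model, tr.signal_array())
    h_te = encode_representations(model, te.signal_array())
    knn_probe(h_tr, tr.labels, h_te, te.labels, k=3)
    linear_probe(h_tr, tr.labels, h_te, te.labels)
    for k, v in model.state_dict().items():
        assert np.array_equal(v, before[k])
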