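import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import jaccard_score, precision_score, recall_score

import grapetex as gx
from grapetex.datasets import generate_synthetic_dataset, split_dataset
from grapetex.estimators import GrapeDiseaseClassifier
from grapetex.exceptions import ContractError
from grapetex.networks import ArchitectureConfig, build_model
from grapetex.train_eval import (
    ConfusionMatrix,
    SequenceScaler,
    TrainingConfig,
    confusion,
    evaluate,
    train_model,
)


def metrics_brute(C):
    """Independent per-class implementation of the five metrics (0-100)."""
    C = np.asarray(C, dtype=float)
    total = C.sum()
    out = {}
    for k in range(C.shape[0]):
        tp = C[k, k]
        fp = C[:, k].sum() - tp
        fn = C[k, :].sum() - tp
        tn = total - tp - fp - fn
        pr = 100 * tp / (tp + fp) if tp + fp else 0.0
        re = 100 * tp / (tp + fn) if tp + fn else 0.0
        out[k] = dict(
            pr=pr,
            re=re,
            acc=100 * (tp + tn) / total,
            iou=100 * tp / (tp + fp + fn) if tp + fp + fn else 0.0,
            fm=2 * pr * re / (pr + re) if pr + re else 0.0,
            support=tp + fn,
        )
    return out


class TestConfusion:
    def test_all_correct_diagonal(self):
        y = np.repeat(np.arange(5), 2)
        C = confusion(y, y)
        assert np.trace(C.C) == 10 and C.total == 10

    def test_all_predicted_class_zero(self):
        true = np.repeat(np.arange(5), 2)
        C = confusion(np.zeros(10, dtype=int), true)
        np.testing.assert_array_equal(C.C[:, 0], [2, 2, 2, 2, 2])
        assert C.C[:, 1:].sum() == 0

    def test_misclassified_equals_total_minus_trace(self, rng):
        pred = rng.integers(0, 5, 100)
        true = rng.integers(0, 5, 100)
        C = confusion(pred, true)
        assert (pred != true).sum() == C.total - np.trace(C.C)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractError):
            confusion(np.array([0, 1]), np.array([0]))

    def test_per_class_counts_sum_to_total(self, rng):
        C = confusion(rng.integers(0, 5, 60), rng.integers(0, 5, 60))
        counts = C.per_class_counts()
        for _, r in counts.iterrows():
            assert r.tp + r.fp + r.fn + r.tn == C.total


class TestEvaluate:
    def test_binary_style_worked_example(self):
        rep = evaluate(ConfusionMatrix(np.array([[8, 2], [2, 8]])))
        row = rep.per_class.iloc[0]
        assert row.precision == 80 and row.recall == 80
        assert row.f_measure == pytest.approx(80)
        assert row.iou == pytest.approx(66.67, abs=0.01)
        assert rep.accuracy == 80

    def test_perfect_predictions_all_100(self):
        rep = evaluate(ConfusionMatrix(np.diag([3, 4, 5, 6, 7])))
        for v in (rep.precision, rep.recall, rep.accuracy, rep.iou, rep.f_measure):
            assert v == 100.0

    def test_zero_support_class_scores_zero_and_drops_out(self):
        C = np.zeros((5, 5), dtype=int)
        C[0, 0] = 5
        C[1, 1] = 5
        rep = evaluate(ConfusionMatrix(C))
        assert rep.per_class.iloc[4].precision == 0.0
        assert rep.per_class.iloc[4].support == 0
        assert rep.precision == 100.0  # weight 0 for the empty class

    def test_empty_matrix_rejected(self):
        with pytest.raises(ContractError):
            evaluate(ConfusionMatrix(np.zeros((5, 5), dtype=int)))

    def test_brute_force_equivalence_500_matrices(self, rng):
        """Eqs-level oracle + sklearn cross-check + structural identities."""
        for trial in range(500):
            C = rng.integers(0, 20, (5, 5)) + np.eye(5, dtype=int)
            rep = evaluate(ConfusionMatrix(C))
            ref = metrics_brute(C)
            support = np.array([ref[k]["support"] for k in range(5)], dtype=float)
            w = support / support.sum()
            for col, key in (
                ("precision", "pr"), ("recall", "re"), ("iou", "iou"),
                ("f_measure", "fm"),
            ):
                percls = rep.per_class[col].to_numpy()
                np.testing.assert_allclose(
                    percls, [ref[k][key] for k in range(5)], atol=1e-10
                )
                np.testing.assert_allclose(
                    getattr(rep, col), percls @ w, atol=1e-10
                )
            # weighted recall == overall accuracy, every trial
            np.testing.assert_allclose(rep.recall, rep.accuracy, atol=1e-10)
            # IoU <= min(Pr, Re) per class
            pc = rep.per_class
            assert (pc.iou <= np.minimum(pc.precision, pc.recall) + 1e-10).all()

    def test_matches_sklearn_weighted_metrics(self, rng):
        for _ in range(20):
            true = rng.integers(0, 5, 200)
            pred = rng.integers(0, 5, 200)
            rep = evaluate(confusion(pred, true))
            assert rep.precision == pytest.approx(
                100 * precision_score(true, pred, average="weighted", zero_division=0)
            )
            assert rep.recall == pytest.approx(
                100 * recall_score(true, pred, average="weighted", zero_division=0)
            )
            assert rep.iou == pytest.approx(
                100 * jaccard_score(true, pred, average="weighted", zero_division=0)
            )

    @given(st.lists(st.integers(0, 30), min_size=25, max_size=25))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_fm_is_harmonic_mean_property(self, entries):
        C = np.array(entries).reshape(5, 5)
        if C.sum() == 0:
            C[0, 0] = 1
        rep = evaluate(ConfusionMatrix(C))
        for _, row in rep.per_class.iterrows():
            pr, re = row.precision, row.recall
            expected = 2 * pr * re / (pr + re) if pr + re > 0 else 0.0
            assert row.f_measure == pytest.approx(expected, abs=1e-10)


class TestSequenceScaler:
    def test_scales_train_features_to_unit_interval(self, rng):
        seq = rng.uniform(-5, 120, (10, 8, 6))
        s = SequenceScaler().fit(seq)
        out = s.transform(seq)
        np.testing.assert_allclose(out.min(axis=(0, 1)), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.max(axis=(0, 1)), 1.0, atol=1e-12)

    def test_roundtrip_through_dict(self, rng):
        seq = rng.uniform(0, 10, (4, 8, 6))
        s = SequenceScaler().fit(seq)
        s2 = SequenceScaler.from_dict(s.to_dict())
        np.testing.assert_allclose(s.transform(seq), s2.transform(seq))


@pytest.fixture(scope="module")
def tiny_split_data():
    data = generate_synthetic_dataset(4, 64, seed=21)
    return split_dataset(data, 0.8, seed=21)


class TestTraining:
    @pytest.mark.parametrize("family", ["dnn", "cnn", "dnn_lstm", "cnn_lstm"])
    def test_all_families_train_and_loss_decreases(self, family, tiny_split_data):
        """Every family trains on a 20-image set without numerical failure
        and its training loss decreases over a short horizon.

        Classic Adadelta (lr = 1) overshoots transiently while its gradient
        accumulators warm up, so the decrease is asserted from epoch 1 to
        epoch 5 rather than between the first two epochs.
        """
        data = tiny_split_data
        cfg = ArchitectureConfig(family=family, backbone="tiny", seed=3)
        model = build_model(cfg)
        seqs = None
        if family.endswith("_lstm"):
            clf = GrapeDiseaseClassifier(family=family, backbone="tiny")
            seqs = SequenceScaler().fit(
                clf._sequences(data.images)
            ).transform(clf._sequences(data.images))
        model, hist = train_model(
            model, data, TrainingConfig(epochs=5, seed=3), sequences=seqs
        )
        assert len(hist) == 5
        assert np.isfinite(hist.train_loss).all()
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_history_reproducible_same_seed(self, tiny_split_data):
        runs = []
        for _ in range(2):
            model = build_model(
                ArchitectureConfig(family="dnn", backbone="tiny", seed=5)
            )
            _, hist = train_model(
                model, tiny_split_data, TrainingConfig(epochs=3, seed=5)
            )
            runs.append(hist)
        assert runs[0].train_loss == runs[1].train_loss
        assert runs[0].val_acc == runs[1].val_acc

    def test_missing_split_rejected(self):
        data = generate_synthetic_dataset(2, 64, seed=0)
        model = build_model(ArchitectureConfig(family="dnn", backbone="tiny"))
        with pytest.raises(ContractError):
            train_model(model, data, TrainingConfig(epochs=1))

    def test_fused_requires_sequences(self, tiny_split_data):
        model = build_model(ArchitectureConfig(family="cnn_lstm", backbone="tiny"))
        with pytest.raises(ContractError):
            train_model(model, tiny_split_data, TrainingConfig(epochs=1))

    def test_full_cnn_one_step(self, tiny_split_data):
        """The Table-style CNN (backbone=none) runs a training step."""
        sub = tiny_split_data.subset(np.arange(6))
        sub.split = ["train"] * 5 + ["validation"]
        model = build_model(
            ArchitectureConfig(family="cnn", backbone="none", seed=1)
        )
        model, hist = train_model(model, sub, TrainingConfig(epochs=1, seed=1))
        assert np.isfinite(hist.train_loss[0])

    def test_early_stopping_halts(self, tiny_split_data):
        model = build_model(ArchitectureConfig(family="dnn", backbone="tiny", seed=2))
        _, hist = train_model(
            model,
            tiny_split_data,
            TrainingConfig(epochs=50, seed=2, early_stopping_patience=2),
        )
        assert len(hist) < 50


class TestEvalReportSerialization:
    def test_json_roundtrip(self, tmp_path, rng):
        rep = evaluate(confusion(rng.integers(0, 5, 50), rng.integers(0, 5, 50)))
        p = tmp_path / "report.json"
        rep.to_json(str(p))
        import json

        loaded = json.loads(p.read_text())
        assert loaded["accuracy"] == pytest.approx(rep.accuracy)
        assert np.array(loaded["confusion"]).sum() == 50

    def test_history_csv(self, tmp_path):
        hist = gx.History([1.0, 0.5], [0.5, 0.8], [1.1, 0.6], [0.4, 0.7])
        p = tmp_path / "h.csv"
        hist.to_csv(str(p))
        import pandas as pd

        df = pd.read_csv(p)
        assert list(df.columns) == [
            "epoch", "train_acc", "train_loss", "val_acc", "val_loss",
        ]
        assert len(df) == 2
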