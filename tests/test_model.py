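"""Classifier metrics, training behaviour and evaluation protocol."""

import numpy as np
import pytest

import epichannel as ec
from epichannel.features import FeatureSequence
from epichannel.model import ConfusionMatrix, confusion_metrics

GROUP1 = ("mean", "min", "skew", "kurt", "theta")


def metric_oracle(tp, fn, fp, tn):
    """Brute-force ratios, independent of the implementation."""
    def pct(a, b):
        return 100.0 * a / b if b else float("nan")
    return {
        "accuracy": pct(tp + tn, tp + tn + fp + fn),
        "sensitivity": pct(tp, tp + fn),
        "specificity": pct(tn, tn + fp),
        "ppv": pct(tp, tp + fp),
        "npv": pct(tn, tn + fn),
    }


def make_sequences(n_per_class, shift=10.0, seed=0, t=19, d=5):
    """Two Gaussian sequence classes separated on the last feature by
    ``shift`` standard deviations; one subject per sequence."""
    rng = np.random.default_rng(seed)
    names = tuple(f"f{i}" for i in range(d))
    out = []
    for label, offset in (("normal", 0.0), ("epileptic", shift)):
        for k in range(n_per_class):
            vectors = rng.standard_normal((t, d))
            vectors[:, -1] += offset
            out.append(
                FeatureSequence(
                    channel_label="ch",
                    feature_names=names,
                    vectors=vectors,
                    label=label,
                    subject_id=f"{label}-{k}",
                )
            )
    return out


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            # published confusion counts for the three feature groups
            ((38, 1, 3, 62),
             {"accuracy": 96.2, "sensitivity": 97.4, "specificity": 95.4,
              "ppv": 92.7, "npv": 98.4}),
            ((35, 6, 4, 59),
             {"accuracy": 90.4, "sensitivity": 85.4, "specificity": 93.7,
              "ppv": 89.7, "npv": 90.8}),
            ((40, 1, 8, 55),
             {"accuracy": 91.3, "sensitivity": 97.6, "specificity": 87.3,
              "ppv": 83.3, "npv": 98.2}),
            ((50, 0, 0, 50),
             {"accuracy": 100.0, "sensitivity": 100.0, "specificity": 100.0,
              "ppv": 100.0, "npv": 100.0}),
        ],
    )
    def test_worked_examples(self, counts, expected):
        tp, fn, fp, tn = counts
        m = confusion_metrics(ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn))
        for name, value in expected.items():
            assert round(m[name], 1) == value

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            tp, fn, fp, tn = rng.integers(0, 100, size=4)
            if tp + fn + fp + tn == 0:
                continue
            m = confusion_metrics(ConfusionMatrix(tp, fn, fp, tn))
            o = metric_oracle(tp, fn, fp, tn)
            for name in m:
                if np.isnan(o[name]):
                    assert np.isnan(m[name])
                else:
                    assert m[name] == pytest.approx(o[name])

    def test_label_swap_symmetry(self, rng):
        """Swapping classes swaps sensitivity/specificity and PPV/NPV."""
        for _ in range(50):
            tp, fn, fp, tn = rng.integers(1, 100, size=4)
            a = confusion_metrics(ConfusionMatrix(tp, fn, fp, tn))
            b = confusion_metrics(ConfusionMatrix(tn, fp, fn, tp))
            assert a["sensitivity"] == pytest.approx(b["specificity"])
            assert a["ppv"] == pytest.approx(b["npv"])
            assert a["accuracy"] == pytest.approx(b["accuracy"])

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_zero_denominator_flagged_not_clamped(self):
        m = confusion_metrics(ConfusionMatrix(tp=0, fn=0, fp=2, tn=8))
        assert np.isnan(m["sensitivity"])  # TP + FN = 0
        assert m["ppv"] == 0.0  # defined: 0 of 2 positive calls correct


class TestTraining:
    CONFIG = ec.NetworkConfig(
        hidden_units=16, max_epochs=20, minibatch_size=200, seed=1
    )

    def test_separable_classes_reach_perfect_training_accuracy(self):
        seqs = make_sequences(40)
        results = ec.ChannelSequenceClassifier(seqs, self.CONFIG).fit()
        predicted = results.predict_labels(seqs)
        assert all(p == s.label for p, s in zip(predicted, seqs))

    def test_training_sequence_predicted_with_its_label_and_probs(self):
        seqs = make_sequences(40)
        results = ec.ChannelSequenceClassifier(seqs, self.CONFIG).fit()
        label, probs = results.predict(seqs[0])
        assert label == seqs[0].label
        assert probs["normal"] >= 0 and probs["epileptic"] >= 0
        assert probs["normal"] + probs["epileptic"] == pytest.approx(1.0, abs=1e-6)

    def test_probabilities_sum_to_one_on_arbitrary_input(self, rng):
        seqs = make_sequences(10)
        results = ec.ChannelSequenceClassifier(seqs, self.CONFIG).fit()
        probe = FeatureSequence(
            channel_label="x",
            feature_names=seqs[0].feature_names,
            vectors=rng.normal(scale=50, size=(19, 5)),
        )
        p = results.predict_proba([probe])[0]
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_same_seed_identical_predictions(self):
        seqs = make_sequences(20)
        a = ec.ChannelSequenceClassifier(seqs, self.CONFIG).fit()
        b = ec.ChannelSequenceClassifier(seqs, self.CONFIG).fit()
        probe = make_sequences(5, seed=9)
        np.testing.assert_array_equal(
            a.predict_proba(probe), b.predict_proba(probe)
        )

    def test_duplicating_training_set_leaves_predictions_unchanged(self):
        """With full-batch training the mean gradient of the duplicated
        set equals the original's, so the fitted model is identical."""
        seqs = make_sequences(20)
        probe = make_sequences(10, seed=7)
        a = ec.ChannelSequenceClassifier(seqs, self.CONFIG).fit()
        b = ec.ChannelSequenceClassifier(seqs + seqs, self.CONFIG).fit()
        np.testing.assert_allclose(
            a.predict_proba(probe), b.predict_proba(probe), atol=1e-10
        )

    def test_shuffled_labels_give_chance_level_holdout(self):
        """Held-out accuracy under a permutation null averages ~50%."""
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            seqs = make_sequences(40, seed=seed)
            labels = [s.label for s in seqs]
            rng.shuffle(labels)
            shuffled = [
                FeatureSequence(
                    channel_label=s.channel_label,
                    feature_names=s.feature_names,
                    vectors=s.vectors,
                    label=lab,
                    subject_id=s.subject_id,
                )
                for s, lab in zip(seqs, labels)
            ]
            report = ec.evaluate(
                shuffled,
                config=ec.NetworkConfig(
                    hidden_units=8, max_epochs=10, minibatch_size=200, seed=seed
                ),
                n_splits=1,
                seed=seed,
            )
            accs.append(report.metrics["accuracy"])
        assert abs(np.mean(accs) - 50.0) <= 15.0

    def test_single_class_rejected(self):
        seqs = [s for s in make_sequences(5) if s.label == "normal"]
        with pytest.raises(ValueError, match="class"):
            ec.ChannelSequenceClassifier(seqs, self.CONFIG)

    def test_inconsistent_lengths_rejected(self):
        seqs = make_sequences(3)
        short = FeatureSequence(
            channel_label="ch",
            feature_names=seqs[0].feature_names,
            vectors=seqs[0].vectors[:10],
            label="epileptic",
            subject_id="short",
        )
        with pytest.raises(ValueError, match="length"):
            ec.ChannelSequenceClassifier(seqs + [short], self.CONFIG)

    def test_wrong_feature_subset_named_in_error(self):
        seqs = make_sequences(5)
        results = ec.ChannelSequenceClassifier(seqs, self.CONFIG).fit()
        probe = FeatureSequence(
            channel_label="x",
            feature_names=("a", "b", "c", "d", "e"),
            vectors=np.zeros((19, 5)),
        )
        with pytest.raises(ValueError, match="expects"):
            results.predict(probe)

    def test_checkpoint_roundtrip(self, tmp_path):
        seqs = make_sequences(10)
        results = ec.ChannelSequenceClassifier(seqs, self.CONFIG).fit()
        path = tmp_path / "model.npz"
        results.save(path)
        loaded = ec.ClassifierResults.load(path)
        probe = make_sequences(4, seed=3)
        np.testing.assert_array_equal(
            results.predict_proba(probe), loaded.predict_proba(probe)
        )
        assert loaded.feature_subset == results.feature_subset
        assert loaded.config == results.config


class TestEvaluate:
    CONFIG = ec.NetworkConfig(
        hidden_units=16, max_epochs=15, minibatch_size=200, seed=0
    )

    def test_single_split_on_separable_data_is_perfect(self):
        report = ec.evaluate(
            make_sequences(20), config=self.CONFIG, n_splits=1, seed=4
        )
        assert report.metrics["accuracy"] == 100.0

    def test_test_fold_size_is_fraction_of_subjects(self):
        seqs = make_sequences(50)  # 100 single-sequence subjects
        report = ec.evaluate(
            seqs, config=self.CONFIG, n_splits=1, test_fraction=0.2, seed=0
        )
        assert report.pooled.total == 20

    def test_same_seed_identical_report(self):
        seqs = make_sequences(20, shift=1.0)
        a = ec.evaluate(seqs, config=self.CONFIG, n_splits=2, seed=5)
        b = ec.evaluate(seqs, config=self.CONFIG, n_splits=2, seed=5)
        assert a.to_dict() == b.to_dict()

    def test_pooled_accuracy_bounded_by_split_accuracies(self):
        seqs = make_sequences(25, shift=1.5, seed=2)
        report = ec.evaluate(seqs, config=self.CONFIG, n_splits=4, seed=2)
        per_split = [m["accuracy"] for m in report.per_split_metrics]
        assert min(per_split) - 1e-9 <= report.metrics["accuracy"] <= max(per_split) + 1e-9

    def test_no_subject_leaks_across_a_split(self, monkeypatch):
        """Subjects contributing several sequences never appear on both
        sides of a split."""
        seqs = []
        for s in make_sequences(12, seed=1):
            for copy in range(2):  # two channels per subject
                seqs.append(
                    FeatureSequence(
                        channel_label=f"ch{copy}",
                        feature_names=s.feature_names,
                        vectors=s.vectors,
                        label=s.label,
                        subject_id=s.subject_id,
                    )
                )
        seen = []
        import epichannel.model as model_mod

        original = model_mod.ChannelSequenceClassifier

        class Spy(original):
            def __init__(self, train_seqs, config):
                seen.append({s.subject_id for s in train_seqs})
                super().__init__(train_seqs, config)

        monkeypatch.setattr(model_mod, "ChannelSequenceClassifier", Spy)
        report = model_mod.evaluate(seqs, config=self.CONFIG, n_splits=2, seed=3)
        all_subjects = {s.subject_id for s in seqs}
        for cm, train_subjects in zip(report.per_split, seen):
            test_subjects = all_subjects - train_subjects
            assert cm.total == 2 * len(test_subjects)
            assert train_subjects & test_subjects == set()

    def test_kfold_partition_covers_every_subject_once(self):
        seqs = make_sequences(10, seed=4)
        report = ec.evaluate(
            seqs, config=self.CONFIG, n_splits=4, cv="kfold", seed=6
        )
        assert sum(cm.total for cm in report.per_split) == len(seqs)
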