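"""Sequence classification of LB channels and its evaluation.

The classifier is a five-layer bidirectional LSTM network (sequence
input, BiLSTM, fully connected, softmax, cross-entropy output) trained on
per-segment feature sequences.  It follows the familiar model/results
split: :class:`ChannelSequenceClassifier` is built from labelled
:class:`~epichannel.features.FeatureSequence` objects and its
:meth:`~ChannelSequenceClassifier.fit` returns a
:class:`ClassifierResults` carrying the trained parameters, the training
normalization and prediction methods.

Evaluation uses repeated stratified 80/20 splits grouped by subject (no
subject contributes sequences to both sides of a split), pooling test
confusion counts across splits; classical grouped k-fold is available
via ``cv="kfold"``.  Performance is summarized by the five standard
screening metrics computed from TP/FN/FP/TN counts:

* sensitivity = TP / (TP + FN) x 100
* specificity = TN / (TN + FP) x 100
* accuracy    = (TP + TN) / (TP + TN + FP + FN) x 100
* PPV         = TP / (TP + FP) x 100
* NPV         = TN / (TN + FN) x 100

The positive class is "epileptic" throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _bilstm
from .features import FeatureSequence

#: Class order: index 0 = negative (normal), 1 = positive (epileptic).
CLASSES = ("normal", "epileptic")

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "ppv", "npv")


@dataclass
class NetworkConfig:
    """Architecture and training options of the BiLSTM classifier."""

    hidden_units: int = 200
    bidirectional: bool = True
    output_mode: str = "last"
    optimizer: str = "adam"
    max_epochs: int = 30
    minibatch_size: int = 150
    initial_learn_rate: float = 0.01
    gradient_threshold: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.hidden_units, self.max_epochs, self.minibatch_size) < 1:
            raise ValueError("counts must be positive")
        if self.initial_learn_rate <= 0:
            raise ValueError("initial_learn_rate must be positive")
        if self.output_mode != "last":
            raise ValueError("only output_mode='last' is implemented")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the Adam optimizer is implemented")


@dataclass
class ConfusionMatrix:
    """TP/FN/FP/TN counts with 'epileptic' as the positive class."""

    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.fn + other.fn,
            self.fp + other.fp,
            self.tn + other.tn,
        )


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """The five screening metrics (percent) from a confusion matrix.

    A metric whose denominator is zero is reported as NaN rather than
    silently clamped; an all-zero matrix is an error.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix has no counts")

    def ratio(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    return {
        "accuracy": ratio(cm.tp + cm.tn, cm.total),
        "sensitivity": ratio(cm.tp, cm.tp + cm.fn),
        "specificity": ratio(cm.tn, cm.tn + cm.fp),
        "ppv": ratio(cm.tp, cm.tp + cm.fp),
        "npv": ratio(cm.tn, cm.tn + cm.fn),
    }


def _stack_sequences(sequences: list[FeatureSequence]) -> np.ndarray:
    names = sequences[0].feature_names
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent sequence lengths: {sorted(lengths)}")
    for s in sequences:
        if s.feature_names != names:
            raise ValueError(
                f"inconsistent feature subsets: {s.feature_names} vs {names}"
            )
    return np.stack([s.vectors for s in sequences])


class ChannelSequenceClassifier:
    """BiLSTM model over labelled per-channel feature sequences.

    Parameters
    ----------
    sequences : list of FeatureSequence
        Training channels; each must carry a label in ``{"epileptic",
        "normal"}`` and a common feature subset.
    config : NetworkConfig, optional
    """

    def __init__(self, sequences, config: NetworkConfig | None = None):
        self.config = config or NetworkConfig()
        self.sequences = list(sequences)
        if not self.sequences:
            raise ValueError("no training sequences")
        labels = [s.label for s in self.sequences]
        bad = sorted(set(labels) - set(CLASSES))
        if bad:
            raise ValueError(f"unknown labels {bad}; expected {CLASSES}")
        counts = {c: labels.count(c) for c in CLASSES}
        lacking = [c for c, k in counts.items() if k < 2]
        if lacking:
            raise ValueError(
                f"need at least 2 sequences per class; short of {lacking} "
                f"(counts: {counts})"
            )
        self.feature_subset = self.sequences[0].feature_names
        self.X = _stack_sequences(self.sequences)
        if not np.all(np.isfinite(self.X)):
            raise ValueError("training features contain non-finite values")
        self.y = np.array([CLASSES.index(lab) for lab in labels])

    def fit(self) -> "ClassifierResults":
        """Train the network; deterministic for a given config seed."""
        mu = self.X.reshape(-1, self.X.shape[2]).mean(axis=0)
        sd = self.X.reshape(-1, self.X.shape[2]).std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xn = (self.X - mu) / sd
        rng = np.random.default_rng(self.config.seed)
        params = _bilstm.train(
            Xn,
            self.y,
            hidden_units=self.config.hidden_units,
            n_classes=len(CLASSES),
            max_epochs=self.config.max_epochs,
            minibatch_size=self.config.minibatch_size,
            learn_rate=self.config.initial_learn_rate,
            gradient_threshold=self.config.gradient_threshold,
            rng=rng,
        )
        return ClassifierResults(
            params=params,
            feature_subset=self.feature_subset,
            norm_mean=mu,
            norm_scale=sd,
            config=self.config,
        )


@dataclass
class ClassifierResults:
    """A fitted channel classifier: parameters, normalization, config."""

    params: dict
    feature_subset: tuple[str, ...]
    norm_mean: np.ndarray
    norm_scale: np.ndarray
    config: NetworkConfig

    def _prepare(self, sequences: list[FeatureSequence]) -> np.ndarray:
        for s in sequences:
            if tuple(s.feature_names) != tuple(self.feature_subset):
                raise ValueError(
                    f"sequence uses features {s.feature_names}; the model "
                    f"expects {self.feature_subset}"
                )
        X = _stack_sequences(sequences)
        return (X - self.norm_mean) / self.norm_scale

    def predict_proba(self, sequences) -> np.ndarray:
        """Class probabilities, columns ordered (normal, epileptic)."""
        return _bilstm.predict_proba(self.params, self._prepare(sequences))

    def predict(self, sequence: FeatureSequence):
        """Label one sequence; ties resolve to "normal".

        Returns ``(label, {"normal": p0, "epileptic": p1})``.
        """
        probs = self.predict_proba([sequence])[0]
        label = CLASSES[1] if probs[1] > probs[0] else CLASSES[0]
        return label, {CLASSES[0]: float(probs[0]), CLASSES[1]: float(probs[1])}

    def predict_labels(self, sequences) -> list[str]:
        probs = self.predict_proba(sequences)
        return [
            CLASSES[1] if p[1] > p[0] else CLASSES[0] for p in probs
        ]

    def summary(self) -> str:
        c = self.config
        lines = [
            "Channel sequence classifier (BiLSTM)",
            "=" * 40,
            f"features:        {', '.join(self.feature_subset)}",
            f"hidden units:    {c.hidden_units}",
            f"epochs:          {c.max_epochs}",
            f"minibatch size:  {c.minibatch_size}",
            f"learn rate:      {c.initial_learn_rate}",
            f"grad threshold:  {c.gradient_threshold}",
            f"seed:            {c.seed}",
            f"positive class:  {CLASSES[1]}",
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        """Serialize parameters + normalization + config to an .npz."""
        meta = {
            "format_version": 1,
            "feature_subset": list(self.feature_subset),
            "config": asdict(self.config),
        }
        np.savez(
            path,
            meta=json.dumps(meta),
            norm_mean=self.norm_mean,
            norm_scale=self.norm_scale,
            **{f"param_{k}": v for k, v in self.params.items()},
        )

    @classmethod
    def load(cls, path) -> "ClassifierResults":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["meta"]))
            params = {
                k[len("param_"):]: archive[k]
                for k in archive.files
                if k.startswith("param_")
            }
            return cls(
                params=params,
                feature_subset=tuple(meta["feature_subset"]),
                norm_mean=archive["norm_mean"],
                norm_scale=archive["norm_scale"],
                config=NetworkConfig(**meta["config"]),
            )


@dataclass
class PerformanceReport:
    """Pooled and per-split evaluation results."""

    pooled: ConfusionMatrix
    per_split: list[ConfusionMatrix] = field(default_factory=list)
    split_seeds: list[int] = field(default_factory=list)

    @property
    def metrics(self) -> dict[str, float]:
        return confusion_metrics(self.pooled)

    @property
    def per_split_metrics(self) -> list[dict[str, float]]:
        return [confusion_metrics(cm) for cm in self.per_split]

    def summary(self) -> str:
        m = self.metrics
        lines = [
            "Evaluation (pooled over "
            f"{len(self.per_split)} split(s), positive = epileptic)",
            "=" * 56,
            f"TP {self.pooled.tp}  FN {self.pooled.fn}  "
            f"FP {self.pooled.fp}  TN {self.pooled.tn}",
            "-" * 56,
        ]
        for name in METRIC_NAMES:
            lines.append(f"{name:<12} {m[name]:6.1f} %")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "pooled": asdict(self.pooled),
            "pooled_metrics": self.metrics,
            "per_split": [asdict(cm) for cm in self.per_split],
            "per_split_metrics": self.per_split_metrics,
            "split_seeds": self.split_seeds,
        }


def _subject_table(sequences, split_unit):
    """Map split groups -> (class index, sequence indices)."""
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(sequences):
        key = s.subject_id if split_unit == "subject" else f"seq-{i}"
        groups.setdefault(key, []).append(i)
    labels = {}
    for key, idxs in groups.items():
        labs = [sequences[i].label for i in idxs]
        labels[key] = int(labs.count(CLASSES[1]) * 2 >= len(labs))
    return groups, labels


def _holdout_split(keys_by_class, test_fraction, rng):
    test, train = [], []
    for cls_keys in keys_by_class:
        keys = list(cls_keys)
        rng.shuffle(keys)
        n_test = max(1, int(round(test_fraction * len(keys))))
        if n_test >= len(keys):
            raise ValueError(
                "test_fraction leaves no training subjects for a class"
            )
        test.extend(keys[:n_test])
        train.extend(keys[n_test:])
    return train, test


def evaluate(
    sequences,
    config: NetworkConfig | None = None,
    n_splits: int = 10,
    test_fraction: float = 0.2,
    split_unit: str = "subject",
    seed: int = 0,
    cv: str = "repeated_holdout",
) -> PerformanceReport:
    """Estimate classifier performance by repeated grouped splits.

    ``cv="repeated_holdout"`` (default) draws ``n_splits`` independent
    stratified splits with ``test_fraction`` of the subjects held out
    each time; ``cv="kfold"`` partitions subjects into ``n_splits``
    disjoint stratified folds instead.  Confusion counts are pooled over
    all test folds and also reported per split.
    """
    sequences = list(sequences)
    config = config or NetworkConfig()
    if split_unit not in ("subject", "sequence"):
        raise ValueError("split_unit must be 'subject' or 'sequence'")
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    groups, group_label = _subject_table(sequences, split_unit)
    keys_by_class = [
        [k for k, lab in group_label.items() if lab == c] for c in (0, 1)
    ]
    if min(len(ks) for ks in keys_by_class) < 2:
        raise ValueError("need at least 2 split groups per class")

    master = np.random.SeedSequence(seed)
    folds: list[tuple[list[str], list[str]]] = []
    if cv == "repeated_holdout":
        for child in master.spawn(n_splits):
            rng = np.random.default_rng(child)
            folds.append(_holdout_split(keys_by_class, test_fraction, rng))
    elif cv == "kfold":
        rng = np.random.default_rng(master.spawn(1)[0])
        assignment: dict[str, int] = {}
        for cls_keys in keys_by_class:
            keys = list(cls_keys)
            rng.shuffle(keys)
            for i, k in enumerate(keys):
                assignment[k] = i % n_splits
        for f in range(n_splits):
            test = [k for k, fold in assignment.items() if fold == f]
            train = [k for k, fold in assignment.items() if fold != f]
            folds.append((train, test))
    else:
        raise ValueError("cv must be 'repeated_holdout' or 'kfold'")

    per_split, split_seeds = [], []
    pooled = ConfusionMatrix()
    fit_seeds = np.random.SeedSequence(seed + 1).generate_state(len(folds))
    for (train_keys, test_keys), fit_seed in zip(folds, fit_seeds):
        test_labels = {group_label[k] for k in test_keys}
        if len(test_labels) < 2:
            # stratified draws always hold out both classes; a k-fold
            # remainder fold can miss one, in which case it is skipped
            continue
        train_idx = [i for k in train_keys for i in groups[k]]
        test_idx = [i for k in test_keys for i in groups[k]]
        split_config = NetworkConfig(
            **{**asdict(config), "seed": int(fit_seed % (2**31 - 1))}
        )
        results = ChannelSequenceClassifier(
            [sequences[i] for i in train_idx], split_config
        ).fit()
        predicted = results.predict_labels([sequences[i] for i in test_idx])
        cm = ConfusionMatrix()
        for i, pred in zip(test_idx, predicted):
            actual = sequences[i].label
            if actual == CLASSES[1]:
                cm.tp += pred == CLASSES[1]
                cm.fn += pred == CLASSES[0]
            else:
                cm.fp += pred == CLASSES[1]
                cm.tn += pred == CLASSES[0]
        per_split.append(cm)
        split_seeds.append(int(fit_seed % (2**31 - 1)))
        pooled = pooled + cm
    if pooled.total == 0:
        raise ValueError("no usable evaluation splits")
    return PerformanceReport(
        pooled=pooled, per_split=per_split, split_seeds=split_seeds
    )
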