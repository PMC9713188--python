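"""Negative sampling, cross-validated evaluation and metric computation.

Known drug-disease associations are the positive class; negatives are drawn
uniformly at random from the unobserved drug x disease pairs, matching the
positive count so the classification task is balanced. Evaluation uses
stratified k-fold cross-validation (k=10 by default): each fold is held out
in turn, a classifier is refit on the rest, and the per-fold accuracy,
precision, recall, F1 and AUC are averaged. AUC is the Mann-Whitney rank
statistic with tie mid-ranks. F1 is defined as 0 when precision + recall
is 0; the classification threshold is 0.5.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .exceptions import ConfigError
from .fusion import PairSample, predict_scores, train_classifier
from .hetnet import AssociationTable


@dataclass(frozen=True)
class Metrics:
    """Single-fold (or single-run) classification metrics, each in [0, 1]."""

    acc: float
    prec: float
    recall: float
    f1: float
    auc: float

    FIELDS = ("acc", "prec", "recall", "f1", "auc")

    def as_array(self) -> np.ndarray:
        return np.array([self.acc, self.prec, self.recall, self.f1, self.auc])


def compute_metrics(labels: Sequence[int], scores: Sequence[float], threshold: float = 0.5) -> Metrics:
    """Thresholded confusion-matrix metrics plus rank-statistic AUC.

    Labels must be binary with both classes present (AUC is undefined
    otherwise); scores are probabilities in [0, 1].
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ConfigError("labels and scores differ in length")
    if not set(np.unique(y)) <= {0, 1}:
        raise ConfigError("labels must be binary 0/1")
    if len(set(np.unique(y))) < 2:
        raise ConfigError("AUC undefined: labels contain a single class")
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    acc = (tn + tp) / (fp + tp + fn + tn)
    prec = tp / (fp + tp) if (fp + tp) > 0 else 0.0
    recall = tp / (fn + tp) if (fn + tp) > 0 else 0.0
    f1 = 2 * prec * recall / (prec + recall) if (prec + recall) > 0 else 0.0
    # Mann-Whitney AUC with tie mid-ranks
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return Metrics(acc, prec, recall, f1, float(auc))


@dataclass(frozen=True)
class MetricsReport:
    """Per-fold metrics plus their mean and standard deviation."""

    folds: tuple[Metrics, ...]

    @property
    def mean(self) -> Metrics:
        m = np.stack([f.as_array() for f in self.folds]).mean(axis=0)
        return Metrics(*map(float, m))

    @property
    def std(self) -> Metrics:
        m = np.stack([f.as_array() for f in self.folds]).std(axis=0)
        return Metrics(*map(float, m))

    def to_tsv(self) -> str:
        """Per-fold rows plus a summary row, full float precision."""
        lines = ["fold\t" + "\t".join(Metrics.FIELDS)]
        for i, f in enumerate(self.folds):
            lines.append(f"{i}\t" + "\t".join(repr(x) for x in f.as_array()))
        mean, std = self.mean, self.std
        lines.append(
            "mean±sd\t"
            + "\t".join(f"{m!r}±{s!r}" for m, s in zip(mean.as_array(), std.as_array()))
        )
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        mean, std = self.mean, self.std
        return json.dumps(
            {
                "folds": [f.as_array().tolist() for f in self.folds],
                "mean": dict(zip(Metrics.FIELDS, mean.as_array().tolist())),
                "std": dict(zip(Metrics.FIELDS, std.as_array().tolist())),
            },
            indent=2,
        )


def sample_negatives(
    positives: AssociationTable,
    drugs: Sequence[str],
    diseases: Sequence[str],
    seed: int = 0,
) -> AssociationTable:
    """Random unobserved drug-disease pairs, one negative per positive.

    Sampled without replacement from the enumerated complement of the
    positive set, so there are no duplicates and no overlap with positives.
    """
    n = len(positives.pairs)
    complement = sorted(
        (d, i) for d in sorted(set(drugs)) for i in sorted(set(diseases))
        if (d, i) not in positives.pairs
    )
    if len(complement) < n:
        raise ConfigError(
            f"cannot sample {n} negatives from {len(complement)} unobserved pairs"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(complement), size=n, replace=False)
    return AssociationTable("drug", "disease", frozenset(complement[i] for i in sorted(idx)))


def make_folds(labels: Sequence[int], k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Stratified fold test-index lists: disjoint, covering, sizes within 1."""
    if k < 2:
        raise ConfigError("k must be >= 2")
    y = np.asarray(labels)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [test for _, test in skf.split(np.zeros(len(y)), y)]
    for test in folds:
        train = np.setdiff1d(np.arange(len(y)), test)
        if len(np.unique(y[train])) < 2:
            raise ConfigError("class-degenerate training fold; need both classes")
    return folds


def kfold_cv(
    samples: Sequence[PairSample],
    k: int = 10,
    classifier_name: str = "RF",
    seed: int = 0,
) -> MetricsReport:
    """Stratified k-fold cross-validation of a pair classifier."""
    labels = np.array([s.label for s in samples])
    folds = make_folds(labels, k, seed)
    per_fold = []
    for test_idx in folds:
        test_set = set(test_idx.tolist())
        train = [s for i, s in enumerate(samples) if i not in test_set]
        test = [samples[i] for i in test_idx]
        model = train_classifier(train, classifier_name, seed)
        scores = predict_scores(model, test)
        per_fold.append(compute_metrics([s.label for s in test], scores))
    return MetricsReport(tuple(per_fold))


def permute_labels(samples: Sequence[PairSample], seed: int = 0) -> list[PairSample]:
    """Null-control copy of the samples with labels randomly shuffled."""
    rng = np.random.default_rng(seed)
    labels = np.array([s.label for s in samples])
    shuffled = labels[rng.permutation(len(labels))]
    return [
        PairSample(s.drug_id, s.disease_id, s.features, int(l))
        for s, l in zip(samples, shuffled)
    ]


def cross_dataset_validate(
    train_samples: Sequence[PairSample],
    test_samples: Sequence[PairSample],
    classifier_name: str = "RF",
    seed: int = 0,
) -> Metrics:
    """Train on one labelled pair set, evaluate once on another.

    The two sets must share some drugs or diseases (a shared feature space);
    test positives must not occur among the training positives, except in the
    degenerate train==test upper-bound check, which is allowed but flagged
    with a leakage warning.
    """
    train_pos = {(s.drug_id, s.disease_id) for s in train_samples if s.label == 1}
    test_pos = {(s.drug_id, s.disease_id) for s in test_samples if s.label == 1}
    train_all = {(s.drug_id, s.disease_id) for s in train_samples}
    test_all = {(s.drug_id, s.disease_id) for s in test_samples}
    if train_all == test_all:
        warnings.warn(
            "train and test sets are identical: metrics are a leakage upper bound",
            stacklevel=2,
        )
    elif train_pos & test_pos:
        raise ConfigError("test positives overlap training positives")
    train_nodes = {s.drug_id for s in train_samples} | {s.disease_id for s in train_samples}
    test_nodes = {s.drug_id for s in test_samples} | {s.disease_id for s in test_samples}
    if not (train_nodes & test_nodes):
        raise ConfigError("train and test sets share no drugs or diseases")
    model = train_classifier(train_samples, classifier_name, seed)
    scores = predict_scores(model, test_samples)
    return compute_metrics([s.label for s in test_samples], scores)
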