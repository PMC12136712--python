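"""Random-forest family classification of phage tail proteins.

Tail-morphology proteins carry a strong family-level compositional
signature, so a forest trained on per-protein physicochemical vectors
can assign a phage family to each tail protein; a genome-level call is
then made by majority vote over that genome's tail proteins.

The evaluation protocol is stratified k-fold cross-validation over
proteins (not genomes); a genome-grouped mode is available for users
worried about within-genome leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold, StratifiedGroupKFold

from .errors import ValidationError
from .seq_features import N_FEATURES, FEATURE_NAMES, ProteinRecord, featurize_many

logger = logging.getLogger(__name__)

#: Default seed for every stochastic component in the package.
DEFAULT_SEED = 37


@dataclass
class LabeledDataset:
    """Aligned feature matrix, family labels and provenance ids."""

    feature_matrix: np.ndarray
    labels: list[str]
    protein_ids: list[str]
    genome_ids: list[str]

    def __post_init__(self) -> None:
        n = self.feature_matrix.shape[0]
        if not (len(self.labels) == len(self.protein_ids) == len(self.genome_ids) == n):
            raise ValidationError("dataset fields are not row-aligned")
        if self.feature_matrix.shape[1] != N_FEATURES:
            raise ValidationError(
                f"expected {N_FEATURES} feature columns, got {self.feature_matrix.shape[1]}"
            )
        if not np.all(np.isfinite(self.feature_matrix)):
            raise ValidationError("feature matrix contains missing values")

    @property
    def n_classes(self) -> int:
        return len(set(self.labels))


@dataclass
class CVReport:
    """Cross-validation outcome: per-fold and pooled accuracies."""

    fold_accuracies: list[float]
    overall_accuracy: float
    confusion_matrix: np.ndarray
    class_labels: list[str]
    per_class_recall: dict[str, float]
    seed: int
    k: int = field(default=10)
    fold_test_indices: list[list[int]] = field(default_factory=list, repr=False)

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "fold_accuracies": self.fold_accuracies,
            "overall_accuracy": self.overall_accuracy,
            "class_labels": self.class_labels,
            "confusion_matrix": self.confusion_matrix.tolist(),
            "per_class_recall": self.per_class_recall,
        }


def select_tail_proteins(records: list[ProteinRecord]) -> list[ProteinRecord]:
    """Keep records whose product annotation mentions "tail" (any case)."""
    out = [r for r in records if "tail" in r.product.lower()]
    if not out:
        logger.warning("no tail proteins found among %d records", len(records))
    return out


def assemble_dataset(
    records: list[ProteinRecord], label_map: dict[str, str]
) -> LabeledDataset:
    """Featurize records and attach family labels by genome id.

    Records from genomes absent in ``label_map`` are dropped (count
    logged).  Raises :class:`ValidationError` if fewer than two families
    remain — an untrainable dataset.
    """
    labeled = [r for r in records if r.genome_id in label_map]
    n_dropped = len(records) - len(labeled)
    if n_dropped:
        logger.warning("dropped %d record(s) from unlabeled genomes", n_dropped)
    matrix, kept_ids = featurize_many(labeled)
    by_id = {r.id: r for r in labeled}
    labels = [label_map[by_id[i].genome_id] for i in kept_ids]
    genome_ids = [by_id[i].genome_id for i in kept_ids]
    if len(set(labels)) < 2:
        raise ValidationError("untrainable: fewer than 2 distinct families")
    return LabeledDataset(matrix, labels, kept_ids, genome_ids)


def train_forest(
    ds: LabeledDataset, n_estimators: int = 1000, seed: int = DEFAULT_SEED
) -> RandomForestClassifier:
    """Fit the random-forest family classifier (reproducible per seed)."""
    counts = {lab: ds.labels.count(lab) for lab in set(ds.labels)}
    singletons = [lab for lab, c in counts.items() if c == 1]
    if singletons:
        logger.warning(
            "classes with a single sample (stratification impossible): %s",
            singletons,
        )
    model = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    model.fit(ds.feature_matrix, ds.labels)
    train_acc = float(model.score(ds.feature_matrix, ds.labels))
    logger.info("training accuracy %.4f on %d samples", train_acc, len(ds.labels))
    model.feature_names_ = list(FEATURE_NAMES)
    return model


def stratified_cv(
    ds: LabeledDataset,
    k: int = 10,
    seed: int = DEFAULT_SEED,
    n_estimators: int = 1000,
    group_by_genome: bool = False,
) -> CVReport:
    """Stratified k-fold cross-validation of the forest.

    Every sample lands in exactly one test fold; fold class proportions
    match the global proportions to within one sample.  If the rarest
    class has fewer than ``k`` members, k is reduced (logged).
    ``group_by_genome`` switches to stratified *group* folds so proteins
    of one genome never straddle a train/test split.
    """
    if k < 2:
        raise ValidationError("k must be at least 2")
    labels = np.asarray(ds.labels)
    min_class = min(np.unique(labels, return_counts=True)[1])
    if min_class < k:
        logger.warning("reducing k from %d to %d (smallest class)", k, min_class)
        k = int(min_class)
        if k < 2:
            raise ValidationError("smallest class too small for cross-validation")
    class_labels = sorted(set(ds.labels))
    if group_by_genome:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(ds.feature_matrix, labels, groups=ds.genome_ids)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(ds.feature_matrix, labels)

    y_true = np.empty(len(labels), dtype=object)
    y_pred = np.empty(len(labels), dtype=object)
    fold_accs = []
    fold_test_indices = []
    for train_idx, test_idx in splits:
        fold_test_indices.append([int(i) for i in test_idx])
        model = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
        model.fit(ds.feature_matrix[train_idx], labels[train_idx])
        pred = model.predict(ds.feature_matrix[test_idx])
        y_true[test_idx] = labels[test_idx]
        y_pred[test_idx] = pred
        fold_accs.append(float(np.mean(pred == labels[test_idx])))

    cm = _sk_confusion(list(y_true), list(y_pred), labels=class_labels)
    overall = float(np.trace(cm) / cm.sum())
    recall = {
        lab: float(cm[i, i] / cm[i].sum()) if cm[i].sum() else float("nan")
        for i, lab in enumerate(class_labels)
    }
    return CVReport(
        fold_accuracies=fold_accs,
        overall_accuracy=overall,
        confusion_matrix=cm,
        class_labels=class_labels,
        per_class_recall=recall,
        seed=seed,
        k=k,
        fold_test_indices=fold_test_indices,
    )


def predict_genome_family(
    model: RandomForestClassifier, tail_records: list[ProteinRecord]
) -> tuple[str, dict[str, float]]:
    """Aggregate per-protein family predictions into one genome-level call.

    Majority vote over tail proteins; a tie is broken by the highest mean
    predicted class probability, then lexicographically.  Returns the
    winning family and the vote fractions.
    """
    matrix, kept = featurize_many(tail_records)
    if matrix.shape[0] == 0:
        raise ValidationError("unclassifiable: no usable tail proteins")
    preds = model.predict(matrix)
    probs = model.predict_proba(matrix)
    classes = list(model.classes_)
    votes: dict[str, float] = {c: 0.0 for c in classes}
    for p in preds:
        votes[p] += 1.0 / len(preds)
    top = max(votes.values())
    tied = sorted(c for c, v in votes.items() if v == top)
    if len(tied) > 1:
        mean_prob = probs.mean(axis=0)
        best = max(tied, key=lambda c: (mean_prob[classes.index(c)], ), default=tied[0])
        # lexicographic fallback on exact probability ties
        cand = [c for c in tied if mean_prob[classes.index(c)] == mean_prob[classes.index(best)]]
        winner = sorted(cand)[0]
    else:
        winner = tied[0]
    return winner, votes
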