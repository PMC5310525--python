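"""Multi-gene transcriptomic classifiers: random forest on all expression features.

One forest per drug, trained on exactly the same cell lines as the drug's
single-gene marker but on the full expression vector instead of a single
mutation status.  Hyperparameters are fixed — 1000 trees and
mtry = floor(sqrt(p)) candidate features per split — so cross-validation is
purely an evaluation device, never model selection.  The forest itself is
scikit-learn's; this module fixes the contract (tree count, mtry, the
majority-vote rule with ties broken toward resistant, and seeding).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .io_gdsc import DrugDataset
from .metrics import ConfusionCounts, confusion

logger = logging.getLogger(__name__)

__all__ = [
    "ForestSpec",
    "TrainedClassifier",
    "default_mtry",
    "train_rf",
    "predict_rf",
    "cross_validate_rf",
]


def default_mtry(p: int) -> int:
    """floor(sqrt(p)) candidate features per split, minimum 1 (115 for 13,321 genes)."""
    if p < 1:
        raise ValueError(f"feature count must be >= 1, got {p}")
    return max(1, math.isqrt(int(p)))


@dataclass(frozen=True)
class ForestSpec:
    """Fixed random-forest hyperparameters: tree count, mtry, seed.

    ``mtry=None`` resolves to floor(sqrt(p)) at fit time.
    """

    n_trees: int = 1000
    mtry: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")

    def resolve_mtry(self, p: int) -> int:
        if self.mtry is None:
            return default_mtry(p)
        if self.mtry > p:
            raise ValueError(f"mtry={self.mtry} exceeds feature count {p}")
        return self.mtry


@dataclass
class TrainedClassifier:
    """A fitted ensemble bound to its training feature order.

    Prediction requires exactly the training feature ids in the same
    order; both classes were present at fit time.
    """

    model: object  # fitted classifier exposing predict_proba and classes_
    gene_ids: list[str] = field(default_factory=list)


def train_rf(train: DrugDataset, labels, spec: ForestSpec = ForestSpec()) -> TrainedClassifier:
    """Fit the per-drug random forest on the training cell lines.

    ``labels`` are boolean (True = sensitive).  Raises ``ValueError`` when
    the training labels contain a single class (no classifier can be
    fitted for the drug).  Reproducible given ``spec.seed``.
    """
    y = np.asarray(labels, dtype=bool)
    if y.shape[0] != train.n:
        raise ValueError("label count does not match training records")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError(
            f"{train.drug_id}: training labels need >=2 cell lines per class "
            f"(got {dict(zip(classes.tolist(), counts.tolist()))})"
        )
    p = train.expression.shape[1]
    forest = RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_features=spec.resolve_mtry(p),
        random_state=spec.seed,
        n_jobs=1,
    )
    forest.fit(train.expression, y)
    return TrainedClassifier(model=forest, gene_ids=list(train.gene_ids))


def predict_rf(classifier: TrainedClassifier, data: DrugDataset) -> np.ndarray:
    """Majority-vote sensitivity predictions (True = sensitive).

    A cell line is predicted sensitive iff strictly more than half of the
    trees vote sensitive; an exact tie goes to resistant, consistent with
    the threshold tie rule in labelling.  Feature ids must match training
    exactly; mismatches raise with the offending genes listed.
    """
    if list(data.gene_ids) != list(classifier.gene_ids):
        missing = sorted(set(classifier.gene_ids) - set(data.gene_ids))
        extra = sorted(set(data.gene_ids) - set(classifier.gene_ids))
        detail = f"missing={missing[:5]}, extra={extra[:5]}" if (missing or extra) else "order differs"
        raise ValueError(f"feature mismatch with training genes: {detail}")
    model = classifier.model
    proba = model.predict_proba(data.expression)
    classes = list(np.asarray(model.classes_))
    if True not in classes:
        return np.zeros(len(proba), dtype=bool)
    p_sensitive = proba[:, classes.index(True)]
    return p_sensitive > 0.5


def cross_validate_rf(
    train: DrugDataset,
    labels,
    spec: ForestSpec = ForestSpec(),
    k: int = 10,
    seed: int | None = None,
    pooled: bool = True,
) -> ConfusionCounts | list[ConfusionCounts]:
    """Stratified k-fold cross-validation of the per-drug forest.

    Each fold's forest is trained on the other k-1 folds and predicts its
    held-out cells; predictions are pooled into a single confusion count
    (``pooled=False`` returns the per-fold counts instead).  A fold whose
    training part degenerates to a single class triggers a re-fold with a
    new seed, at most 5 attempts.
    """
    y = np.asarray(labels, dtype=bool)
    if train.n < k:
        raise ValueError(f"{train.drug_id}: n={train.n} < k={k} folds")
    base_seed = spec.seed if seed is None else seed
    for attempt in range(5):
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=base_seed + attempt)
        folds = list(splitter.split(train.expression, y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
            break
        logger.warning("%s: degenerate CV fold, re-folding (attempt %d)", train.drug_id, attempt + 1)
    else:
        raise ValueError(f"{train.drug_id}: could not build {k} folds with both classes")
    counts: list[ConfusionCounts] = []
    for fold_idx, (tr, held) in enumerate(folds):
        sub = DrugDataset(
            drug_id=train.drug_id,
            cell_line_ids=[train.cell_line_ids[i] for i in tr],
            logic50=train.logic50[tr],
            expression=train.expression[tr],
            gene_ids=train.gene_ids,
        )
        fitted = train_rf(sub, y[tr], ForestSpec(spec.n_trees, spec.mtry, base_seed + 1000 + fold_idx))
        held_set = DrugDataset(
            drug_id=train.drug_id,
            cell_line_ids=[train.cell_line_ids[i] for i in held],
            logic50=train.logic50[held],
            expression=train.expression[held],
            gene_ids=train.gene_ids,
        )
        counts.append(confusion(predict_rf(fitted, held_set), y[held]))
    if pooled:
        total = counts[0]
        for c in counts[1:]:
            total = total + c
        return total
    return counts
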