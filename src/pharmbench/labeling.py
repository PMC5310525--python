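"""Chronological train/test splits and median-threshold binarization.

For each drug, the training set is the release-1 cell lines with
expression data; the test set is the cell lines newly tested in release 2.
The sensitivity threshold is the median training logIC50, fixed once and
applied unchanged to the test set — test measurements never influence it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_gdsc import DrugDataset, ExpressionMatrix, ResponseTable

logger = logging.getLogger(__name__)

__all__ = ["DrugSplit", "SplitError", "chronological_split", "median_threshold", "binarize"]


class SplitError(ValueError):
    """A drug cannot be split (empty train or test set); carries the reason."""

    def __init__(self, drug_id: str, reason: str):
        self.drug_id = drug_id
        self.reason = reason
        super().__init__(f"{drug_id}: {reason}")


@dataclass
class DrugSplit:
    """Per-drug chronological train/test partition with its fixed threshold."""

    drug_id: str
    train: DrugDataset
    test: DrugDataset
    threshold: float

    def __post_init__(self) -> None:
        overlap = set(self.train.cell_line_ids) & set(self.test.cell_line_ids)
        if overlap:
            raise ValueError(f"{self.drug_id}: train/test cell lines overlap: {sorted(overlap)}")

    @property
    def train_labels(self) -> np.ndarray:
        return binarize(self.train.logic50, self.threshold)

    @property
    def test_labels(self) -> np.ndarray:
        return binarize(self.test.logic50, self.threshold)


def median_threshold(values) -> float:
    """Median logIC50 (mean of the central pair for even n)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot take the median of an empty set of logIC50 values")
    return float(np.median(arr))


def binarize(logic50, threshold: float) -> np.ndarray:
    """Label cell lines sensitive (True) iff logIC50 < threshold.

    Values exactly at the threshold are labelled resistant — the
    conservative call for a sensitivity classifier, and deterministic for
    the measure-zero tie case.
    """
    arr = np.asarray(logic50, dtype=float)
    if not (np.isfinite(arr).all() and np.isfinite(threshold)):
        raise ValueError("non-finite logIC50 or threshold")
    return arr < threshold


def _dataset_for(drug_id: str, series, expression: ExpressionMatrix) -> DrugDataset:
    cells = [c for c in expression.cell_line_ids if c in set(series.index)]
    block = expression.frame.loc[cells]
    return DrugDataset(
        drug_id=drug_id,
        cell_line_ids=cells,
        logic50=series.loc[cells].to_numpy(dtype=float),
        expression=block.to_numpy(dtype=np.float32),
        gene_ids=expression.gene_ids,
    )


def chronological_split(
    drug_id: str,
    response_r1: ResponseTable,
    response_r2: ResponseTable,
    expression: ExpressionMatrix,
) -> DrugSplit:
    """Build the release-ordered train/test split for one drug.

    Train: cells tested in release 1 that have expression data.  Test:
    cells with expression data tested in release 2 but not in release 1
    (new measurements only).  Raises :class:`SplitError` when either side
    is empty, so callers can skip the drug with a logged reason.
    """
    expr_cells = set(expression.cell_line_ids)
    r1 = response_r1.for_drug(drug_id)
    train_series = r1[r1.index.isin(expr_cells)]
    if train_series.empty:
        raise SplitError(drug_id, "empty training set (no release-1 cell with expression)")
    r2 = response_r2.for_drug(drug_id)
    new_cells = expr_cells - set(r1.index)
    test_series = r2[r2.index.isin(new_cells)]
    if test_series.empty:
        raise SplitError(drug_id, "empty test set (release 2 adds no new cell lines)")
    threshold = median_threshold(train_series.to_numpy())
    split = DrugSplit(
        drug_id=drug_id,
        train=_dataset_for(drug_id, train_series, expression),
        test=_dataset_for(drug_id, test_series, expression),
        threshold=threshold,
    )
    logger.debug(
        "%s: %d training / %d test cell lines, threshold %.4f",
        drug_id, split.train.n, split.test.n, threshold,
    )
    return split
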