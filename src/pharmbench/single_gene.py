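"""Single-gene mutation markers of drug sensitivity.

A single-gene marker is the drug-gene association with the lowest p-value
for a drug, used as a one-feature classifier: cell lines mutated in the
marker gene are predicted sensitive, wild-type lines resistant.  On real
GDSC data the association p-values come from the consortium's published
MANOVA output and are ingested as-is; for synthetic cohorts this module
provides a stand-in association test (Welch's two-sample t on logIC50,
mutant vs wild-type, vectorised over genes).

Cohort-wide significance uses the Benjamini-Hochberg step-up rule at a
configurable FDR (default 20%): associations with p-values at or below the
largest qualifying order statistic are flagged significant.  A drug's best
marker is selected even when not significant — otherwise multi-gene models
would win those drugs by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_gdsc import AssociationTable, MutationTable, ResponseTable

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerModel",
    "test_associations",
    "bh_threshold",
    "select_best_marker",
    "predict_single_gene",
]


@dataclass(frozen=True)
class MarkerModel:
    """One drug's best single-gene marker.

    ``gene_id`` attains the minimal p-value among the drug's associations;
    ``significant`` records whether that p-value passes the cohort-wide BH
    threshold.  The prediction rule is mutant → sensitive.
    """

    drug_id: str
    gene_id: str
    p_value: float
    significant: bool
    effect_direction: str = "unknown"


def _welch_pvalues(y: np.ndarray, status: np.ndarray) -> np.ndarray:
    """Two-sided Welch t-test p-values, one per column of ``status``.

    ``y`` (n,) holds logIC50; ``status`` (n, G) boolean mutant flags.
    Columns must have >=2 members per group.  Degenerate cases: zero
    variance in both groups gives p=1 for equal means and the smallest
    positive float for perfectly separated means.
    """
    s = status.astype(float)
    n1 = s.sum(axis=0)
    n0 = len(y) - n1
    sum1 = s.T @ y
    sumsq1 = s.T @ (y * y)
    mean1 = sum1 / n1
    mean0 = (y.sum() - sum1) / n0
    var1 = (sumsq1 - n1 * mean1**2) / (n1 - 1)
    var0 = ((y * y).sum() - sumsq1 - n0 * mean0**2) / (n0 - 1)
    var1 = np.maximum(var1, 0.0)
    var0 = np.maximum(var0, 0.0)
    se2 = var1 / n1 + var0 / n0
    diff = mean1 - mean0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((var1 / n1) ** 2 / (n1 - 1) + (var0 / n0) ** 2 / (n0 - 1))
    p = np.ones_like(t)
    ok = se2 > 0
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    p[~ok & (diff != 0)] = np.finfo(float).tiny  # perfect separation
    return np.clip(p, np.finfo(float).tiny, 1.0)


def test_associations(
    response_train: ResponseTable,
    mutations: MutationTable,
    min_mutants: int = 3,
) -> AssociationTable:
    """Stand-in drug-gene association test for cohorts without published p-values.

    For every (drug, gene) pair with at least ``min_mutants`` mutant and
    ``min_mutants`` wild-type cell lines among the drug's tested lines, a
    Welch two-sample t-test compares logIC50 between the two groups.
    ``effect_direction`` is ``sensitising`` when mutants have the lower
    mean logIC50, ``resistance`` when higher, ``unknown`` on an exact tie.
    Pairs failing the count filter are omitted.
    """
    min_mutants = max(int(min_mutants), 2)  # Welch needs >=2 per group
    frames: list[pd.DataFrame] = []
    gene_ids = np.asarray(mutations.gene_ids)
    for drug_id in response_train.drug_ids():
        series = response_train.for_drug(drug_id)
        cells = [c for c in series.index if c in mutations.status.index]
        if len(cells) < 2 * min_mutants:
            continue
        y = series.loc[cells].to_numpy(dtype=float)
        status = mutations.status.loc[cells].to_numpy(dtype=bool)
        n_mut = status.sum(axis=0)
        keep = (n_mut >= min_mutants) & (len(y) - n_mut >= min_mutants)
        if not keep.any():
            continue
        p = _welch_pvalues(y, status[:, keep])
        mean_mut = (status[:, keep].T.astype(float) @ y) / n_mut[keep]
        mean_wt = (y.sum() - n_mut[keep] * mean_mut) / (len(y) - n_mut[keep])
        direction = np.where(
            mean_mut < mean_wt, "sensitising", np.where(mean_mut > mean_wt, "resistance", "unknown")
        )
        frames.append(
            pd.DataFrame(
                {
                    "drug_id": drug_id,
                    "gene_id": gene_ids[keep],
                    "p_value": p,
                    "effect_direction": direction,
                }
            )
        )
    if not frames:
        raise ValueError(
            f"no (drug, gene) pair has >= {min_mutants} mutant and wild-type cell lines"
        )
    table = AssociationTable(pd.concat(frames, ignore_index=True))
    logger.info("tested %d drug-gene associations", len(table.rows))
    return table


def bh_threshold(p_values, fdr: float = 0.20) -> float:
    """Benjamini-Hochberg step-up p-value threshold at the given FDR.

    Returns the largest order statistic p_(k) with p_(k) <= (k/m)·fdr, or
    0.0 when no k qualifies (nothing significant).  Associations with
    p-values at or below the returned threshold form the BH rejection set.
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    if p.size == 0:
        raise ValueError("empty p-value list")
    if not ((p > 0) & (p <= 1)).all():
        raise ValueError("p-values must lie in (0, 1]")
    k = np.arange(1, p.size + 1)
    qualifying = p[p <= k / p.size * fdr]
    return float(qualifying[-1]) if qualifying.size else 0.0


def select_best_marker(
    drug_id: str,
    associations: AssociationTable,
    fdr: float = 0.20,
    threshold: float | None = None,
) -> MarkerModel:
    """Select the drug's minimal-p association as its single-gene marker.

    The marker is selected even when not significant (the best available
    classifier for the drug); ``significant`` is set against the BH
    threshold computed over *all* associations in the table jointly, or
    against a precomputed ``threshold`` when given.  Exact p-value ties
    break toward the lexicographically smaller gene id.
    """
    rows = associations.for_drug(drug_id)
    if rows.empty:
        raise KeyError(f"drug {drug_id!r} has no association rows")
    if threshold is None:
        threshold = bh_threshold(associations.p_values, fdr=fdr)
    best = rows.sort_values(["p_value", "gene_id"], kind="stable").iloc[0]
    return MarkerModel(
        drug_id=drug_id,
        gene_id=str(best["gene_id"]),
        p_value=float(best["p_value"]),
        significant=bool(best["p_value"] <= threshold),
        effect_direction=str(best["effect_direction"]),
    )


def predict_single_gene(
    marker: MarkerModel,
    mutations: MutationTable,
    cell_ids,
    direction_aware: bool = False,
) -> np.ndarray:
    """Predict sensitivity labels (True = sensitive) from one marker gene.

    Default rule: mutated in the marker gene → predicted sensitive.  With
    ``direction_aware=True``, markers whose association points to
    resistance flip the rule (mutant → resistant); the default keeps the
    uniform mutant→sensitive convention under which a marker gene with no
    mutant cell in the evaluation set yields zero positive predictions
    (TP=FP=0).
    """
    status = mutations.status_of(marker.gene_id, list(cell_ids))
    if direction_aware and marker.effect_direction == "resistance":
        return ~status
    return status
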