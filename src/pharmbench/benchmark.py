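"""Per-drug comparison of single-gene vs multi-gene markers, end to end.

For every drug the pipeline builds the chronological train/test split,
fixes the training-median threshold, selects the best single-gene marker
from training-release associations, trains the random forest on exactly
the same training records, and evaluates both models on the training set,
under 10-fold cross-validation (forest only) and on the time-split test
set.  The headline aggregate is the fraction of drugs whose test-set MCC
is higher for the multi-gene model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_gdsc import (
    AssociationTable,
    ExpressionMatrix,
    MutationTable,
    ResponseTable,
    align_cohort,
    read_expression_csv,
    read_mutation_csv,
    read_response_csv,
)
from .labeling import SplitError, chronological_split
from .metrics import MetricSet, confusion
from .multi_gene import ForestSpec, cross_validate_rf, predict_rf, train_rf
from .single_gene import bh_threshold, predict_single_gene, select_best_marker, test_associations
from .synthetic import GeneratorConfig, SyntheticTruth, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "BenchmarkRow", "BenchmarkResult", "run_benchmark", "write_report"]

WINNER_TIE_TOL = 1e-12


@dataclass
class RunConfig:
    """Inputs and knobs for one benchmark run.

    Exactly one of ``generator`` (synthetic cohort) or ``input_dir`` (CSV
    tables as written by the synthetic module / io_gdsc dialect) must be
    provided.  ``associations_csv`` optionally supplies published
    drug-gene p-values, bypassing the stand-in association test.
    """

    generator: GeneratorConfig | None = None
    input_dir: str | Path | None = None
    associations_csv: str | Path | None = None
    forest: ForestSpec = field(default_factory=ForestSpec)
    fdr: float = 0.20
    cv_folds: int = 10
    min_mutants: int = 3
    direction_aware: bool = False
    run_cv: bool = True
    seed: int = 0
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.input_dir is None):
            raise ValueError("provide exactly one of generator config or input_dir")


@dataclass
class BenchmarkRow:
    """One drug's full comparison record."""

    drug_id: str
    archetype: str
    n_train: int
    n_test: int
    threshold: float
    marker_gene: str
    marker_p: float
    marker_significant: bool
    single_train: MetricSet
    single_test: MetricSet
    rf_train: MetricSet
    rf_cv: MetricSet | None
    rf_test: MetricSet
    winner_by_test_mcc: str

    def flat(self) -> dict:
        out = {
            "drug_id": self.drug_id,
            "archetype": self.archetype,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "threshold": self.threshold,
            "marker_gene": self.marker_gene,
            "marker_p": self.marker_p,
            "marker_significant": self.marker_significant,
        }
        for prefix, ms in (
            ("single_train", self.single_train),
            ("single_test", self.single_test),
            ("rf_train", self.rf_train),
            ("rf_cv", self.rf_cv),
            ("rf_test", self.rf_test),
        ):
            for name in ("mcc", "precision", "recall", "f1"):
                out[f"{prefix}_{name}"] = getattr(ms, name) if ms is not None else np.nan
        out["winner_by_test_mcc"] = self.winner_by_test_mcc
        return out


@dataclass
class BenchmarkResult:
    rows: list[BenchmarkRow]
    summary: dict
    skipped: list[tuple[str, str]]
    config_echo: dict


def _decide_winner(single_mcc: float, multi_mcc: float) -> str:
    if abs(single_mcc - multi_mcc) <= WINNER_TIE_TOL:
        return "tie"
    return "multi" if multi_mcc > single_mcc else "single"


def _load_inputs(config: RunConfig):
    if config.generator is not None:
        cohort = generate_cohort(config.generator)
        return cohort.expression, cohort.mutations, cohort.response_r1, cohort.response_r2, cohort.truth
    d = Path(config.input_dir)
    expression = read_expression_csv(d / "expression.csv")
    mutations = read_mutation_csv(d / "mutations.csv")
    r1 = read_response_csv(d / "response_r1.csv")
    r2 = read_response_csv(d / "response_r2.csv")
    truth = None
    if (d / "truth.csv").exists():
        truth = SyntheticTruth(pd.read_csv(d / "truth.csv", keep_default_na=False))
    return expression, mutations, r1, r2, truth


def _summarise(rows: list[BenchmarkRow], truth: SyntheticTruth | None) -> dict:
    frame = pd.DataFrame([r.flat() for r in rows])
    n = len(frame)
    multi_wins = int((frame["winner_by_test_mcc"] == "multi").sum())
    summary = {
        "n_drugs": n,
        "multi_better_count": multi_wins,
        "multi_better_fraction": multi_wins / n,
        "mean_mcc_single_train": float(frame["single_train_mcc"].mean()),
        "mean_mcc_single_test": float(frame["single_test_mcc"].mean()),
        "mean_mcc_rf_train": float(frame["rf_train_mcc"].mean()),
        "mean_mcc_rf_cv": float(frame["rf_cv_mcc"].mean()),
        "mean_mcc_rf_test": float(frame["rf_test_mcc"].mean()),
    }
    if truth is not None:
        for archetype, sub in frame.groupby("archetype"):
            wins = int((sub["winner_by_test_mcc"] == "multi").sum())
            summary[f"n_{archetype}"] = len(sub)
            summary[f"multi_better_{archetype}"] = wins
    return summary


def run_benchmark(config: RunConfig) -> BenchmarkResult:
    """Run the full single-gene vs multi-gene comparison.

    Deterministic given ``config.seed``: per-drug forest seeds are spawned
    from it in sorted drug order, so any one drug's result can be
    re-derived in isolation.  Drugs with an empty train or test set, a
    single training class, or no association row are skipped with a
    logged reason.
    """
    expression, mutations, r1, r2, truth = _load_inputs(config)
    expression, mutations, r1, r2 = align_cohort(expression, mutations, r1, r2)

    if config.associations_csv is not None:
        assoc_frame = pd.read_csv(config.associations_csv)
        associations = AssociationTable(assoc_frame)
        logger.info("using %d supplied associations (stand-in test bypassed)", len(associations.rows))
    else:
        associations = test_associations(r1, mutations, min_mutants=config.min_mutants)
    bh = bh_threshold(associations.p_values, fdr=config.fdr)

    drug_ids = r1.drug_ids()
    children = np.random.SeedSequence(config.seed).spawn(len(drug_ids))
    rows: list[BenchmarkRow] = []
    skipped: list[tuple[str, str]] = []
    for drug_id, child in zip(drug_ids, children):
        drug_seed = int(child.generate_state(1)[0] % (2**31))
        try:
            row = _run_one_drug(
                drug_id, r1, r2, expression, mutations, associations, bh, truth, config, drug_seed
            )
        except (SplitError, ValueError, KeyError) as exc:
            reason = getattr(exc, "reason", str(exc))
            logger.info("skipping %s: %s", drug_id, reason)
            skipped.append((drug_id, reason))
            continue
        rows.append(row)
    if not rows:
        raise RuntimeError("no drug survived the split and training filters")
    summary = _summarise(rows, truth)
    echo = {
        "seed": config.seed,
        "fdr": config.fdr,
        "cv_folds": config.cv_folds,
        "min_mutants": config.min_mutants,
        "direction_aware": config.direction_aware,
        "forest": asdict(config.forest),
        "generator": asdict(config.generator) if config.generator else None,
        "input_dir": str(config.input_dir) if config.input_dir else None,
        "bh_threshold": bh,
    }
    result = BenchmarkResult(rows=rows, summary=summary, skipped=skipped, config_echo=echo)
    if config.outdir is not None:
        write_report(result, config.outdir)
    return result


def _run_one_drug(
    drug_id: str,
    r1: ResponseTable,
    r2: ResponseTable,
    expression: ExpressionMatrix,
    mutations: MutationTable,
    associations: AssociationTable,
    bh: float,
    truth: SyntheticTruth | None,
    config: RunConfig,
    drug_seed: int,
) -> BenchmarkRow:
    split = chronological_split(drug_id, r1, r2, expression)
    y_train = split.train_labels
    y_test = split.test_labels

    marker = select_best_marker(drug_id, associations, fdr=config.fdr, threshold=bh)
    sg_train = predict_single_gene(
        marker, mutations, split.train.cell_line_ids, direction_aware=config.direction_aware
    )
    sg_test = predict_single_gene(
        marker, mutations, split.test.cell_line_ids, direction_aware=config.direction_aware
    )

    spec = ForestSpec(config.forest.n_trees, config.forest.mtry, drug_seed)
    forest = train_rf(split.train, y_train, spec)
    rf_train_pred = predict_rf(forest, split.train)
    rf_test_pred = predict_rf(forest, split.test)
    rf_cv_metrics = None
    if config.run_cv:
        cv_counts = cross_validate_rf(
            split.train, y_train, spec, k=config.cv_folds, seed=drug_seed + 1
        )
        rf_cv_metrics = MetricSet.from_counts(cv_counts)

    single_test_metrics = MetricSet.from_counts(confusion(sg_test, y_test))
    rf_test_metrics = MetricSet.from_counts(confusion(rf_test_pred, y_test))
    return BenchmarkRow(
        drug_id=drug_id,
        archetype=truth.archetype_of(drug_id) if truth is not None else "unknown",
        n_train=split.train.n,
        n_test=split.test.n,
        threshold=split.threshold,
        marker_gene=marker.gene_id,
        marker_p=marker.p_value,
        marker_significant=marker.significant,
        single_train=MetricSet.from_counts(confusion(sg_train, y_train)),
        single_test=single_test_metrics,
        rf_train=MetricSet.from_counts(confusion(rf_train_pred, y_train)),
        rf_cv=rf_cv_metrics,
        rf_test=rf_test_metrics,
        winner_by_test_mcc=_decide_winner(single_test_metrics.mcc, rf_test_metrics.mcc),
    )


def write_report(result: BenchmarkResult, outdir: str | Path) -> dict[str, Path]:
    """Write per-drug CSV, aggregate CSV, scatter data and a run log.

    The scatter file pairs each drug's single-gene and multi-gene test
    metrics (one row per drug), ready for metric-vs-metric plots.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    per_drug = pd.DataFrame([r.flat() for r in result.rows])
    paths = {
        "per_drug": outdir / "per_drug.csv",
        "summary": outdir / "summary.csv",
        "scatter": outdir / "scatter_test_metrics.csv",
        "log": outdir / "run_log.txt",
    }
    per_drug.to_csv(paths["per_drug"], index=False)
    pd.DataFrame([result.summary]).to_csv(paths["summary"], index=False)
    scatter_cols = ["drug_id", "archetype"] + [
        f"{m}_{s}" for m in ("single_test", "rf_test") for s in ("mcc", "precision", "recall", "f1")
    ]
    per_drug[scatter_cols].to_csv(paths["scatter"], index=False)
    with open(paths["log"], "w", encoding="utf-8") as fh:
        fh.write("# benchmark run log\n")
        for key, value in result.config_echo.items():
            fh.write(f"{key}: {value}\n")
        fh.write(f"n_rows: {len(result.rows)}\n")
        for drug_id, reason in result.skipped:
            fh.write(f"skipped: {drug_id}: {reason}\n")
    return paths
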