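"""End-to-end benchmark: determinism, leakage, reporting, CLI."""

import filecmp

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import pharmbench as pb
from pharmbench.cli import main as cli_main


def _small_run_config(seed=11, **kwargs):
    generator = pb.GeneratorConfig(
        n_genes=150,
        n_cells_release1=60,
        n_cells_new_release2=40,
        drug_specs=pb.default_drug_panel(2, 1, 1),
        seed=seed,
    )
    defaults = dict(
        generator=generator,
        forest=pb.ForestSpec(n_trees=25),
        cv_folds=4,
        seed=seed,
    )
    defaults.update(kwargs)
    return pb.RunConfig(**defaults)


@pytest.fixture(scope="module")
def small_result():
    return pb.run_benchmark(_small_run_config())


def test_every_drug_scored_once(small_result):
    ids = [r.drug_id for r in small_result.rows]
    assert len(ids) == len(set(ids)) == 4
    assert small_result.summary["n_drugs"] == 4


def test_winner_consistent_with_test_mcc(small_result):
    for row in small_result.rows:
        diff = row.rf_test.mcc - row.single_test.mcc
        if abs(diff) <= 1e-12:
            assert row.winner_by_test_mcc == "tie"
        else:
            assert row.winner_by_test_mcc == ("multi" if diff > 0 else "single")


def test_archetype_counts_sum_to_total(small_result):
    s = small_result.summary
    total = sum(v for k, v in s.items() if k.startswith("n_") and k != "n_drugs")
    assert total == s["n_drugs"]


def test_rf_training_metrics_overfit(small_result):
    for row in small_result.rows:
        assert row.rf_train.mcc >= 0.99


def test_config_requires_exactly_one_source():
    with pytest.raises(ValueError):
        pb.RunConfig(generator=None, input_dir=None)
    with pytest.raises(ValueError):
        pb.RunConfig(generator=pb.GeneratorConfig(), input_dir="somewhere")


def test_reports_are_byte_identical_across_runs(tmp_path):
    out1, out2 = tmp_path / "run1", tmp_path / "run2"
    pb.run_benchmark(_small_run_config(outdir=out1))
    pb.run_benchmark(_small_run_config(outdir=out2))
    for name in ("per_drug.csv", "summary.csv", "scatter_test_metrics.csv"):
        assert filecmp.cmp(out1 / name, out2 / name, shallow=False), name


def test_report_round_trip(small_result, tmp_path):
    paths = pb.write_report(small_result, tmp_path)
    frame = pd.read_csv(paths["per_drug"])
    assert len(frame) == len(small_result.rows)
    for row in small_result.rows:
        rec = frame[frame["drug_id"] == row.drug_id].iloc[0]
        assert rec["rf_test_mcc"] == pytest.approx(row.rf_test.mcc)
        assert rec["single_test_mcc"] == pytest.approx(row.single_test.mcc)
        assert rec["threshold"] == pytest.approx(row.threshold)


def test_permuting_test_responses_leaks_nothing(tmp_path):
    """Test-set values may change test metrics only: thresholds, markers and
    training metrics are derived from release 1 alone."""
    cohort = pb.generate_cohort(
        pb.GeneratorConfig(
            n_genes=150,
            n_cells_release1=60,
            n_cells_new_release2=40,
            drug_specs=pb.default_drug_panel(1, 1, 1),
            seed=4,
        )
    )
    base_dir = tmp_path / "base"
    perm_dir = tmp_path / "perm"
    cohort.write_csvs(base_dir)
    cohort.write_csvs(perm_dir)
    r2 = pd.read_csv(perm_dir / "response_r2.csv")
    r2["logic50"] = r2["logic50"].sample(frac=1, random_state=9).to_numpy()
    r2.to_csv(perm_dir / "response_r2.csv", index=False)

    cfg = dict(forest=pb.ForestSpec(n_trees=25), cv_folds=4, seed=2)
    res_a = pb.run_benchmark(pb.RunConfig(input_dir=base_dir, **cfg))
    res_b = pb.run_benchmark(pb.RunConfig(input_dir=perm_dir, **cfg))
    changed = False
    for a, b in zip(res_a.rows, res_b.rows):
        assert a.threshold == b.threshold
        assert a.marker_gene == b.marker_gene and a.marker_p == b.marker_p
        assert a.single_train == b.single_train
        assert a.rf_train == b.rf_train and a.rf_cv == b.rf_cv
        changed |= a.rf_test != b.rf_test or a.single_test != b.single_test
    assert changed  # the permutation did alter test metrics


def test_skipped_drug_reported_with_reason(tmp_path):
    cohort = pb.generate_cohort(
        pb.GeneratorConfig(
            n_genes=150,
            n_cells_release1=60,
            n_cells_new_release2=40,
            drug_specs=pb.default_drug_panel(1, 1, 1),
            seed=8,
        )
    )
    d = tmp_path / "cohort"
    cohort.write_csvs(d)
    r2 = pd.read_csv(d / "response_r2.csv")
    r2[r2["drug_id"] != "drug_01"].to_csv(d / "response_r2.csv", index=False)

    out = tmp_path / "report"
    result = pb.run_benchmark(
        pb.RunConfig(input_dir=d, forest=pb.ForestSpec(n_trees=25), cv_folds=4, seed=2, outdir=out)
    )
    assert [r.drug_id for r in result.rows] == ["drug_02", "drug_03"]
    assert result.skipped and result.skipped[0][0] == "drug_01"
    assert "empty test set" in result.skipped[0][1]
    log = (out / "run_log.txt").read_text()
    assert "drug_01" in log and "empty test set" in log


def test_cli_simulate_then_run(tmp_path):
    runner = CliRunner()
    cohort_dir = tmp_path / "cohort"
    sim = runner.invoke(
        cli_main,
        ["simulate", "--seed", "3", "--outdir", str(cohort_dir)],
        catch_exceptions=False,
        env={"COLUMNS": "200"},
    )
    # keep the CLI invocation itself tiny via a config file
    cfg = tmp_path / "cfg.yaml"
    cfg.write_text(
        "n_genes: 120\nn_cells_release1: 50\nn_cells_new_release2: 30\n"
        "n_monogenic: 1\nn_polygenic: 1\nn_null: 1\n"
    )
    sim = runner.invoke(
        cli_main,
        ["simulate", "--config", str(cfg), "--seed", "3", "--outdir", str(cohort_dir)],
        catch_exceptions=False,
    )
    assert sim.exit_code == 0 and (cohort_dir / "expression.csv").exists()
    out = tmp_path / "report"
    run = runner.invoke(
        cli_main,
        [
            "run", "--input-dir", str(cohort_dir), "--seed", "3", "--outdir", str(out),
            "--trees", "20", "--folds", "3",
        ],
        catch_exceptions=False,
    )
    assert run.exit_code == 0 and (out / "per_drug.csv").exists()
    rep = runner.invoke(
        cli_main,
        ["report", "--per-drug", str(out / "per_drug.csv"), "--outdir", str(tmp_path / "agg")],
        catch_exceptions=False,
    )
    assert rep.exit_code == 0
    summary = pd.read_csv(tmp_path / "agg" / "summary.csv")
    assert summary["n_drugs"].iloc[0] == 3
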