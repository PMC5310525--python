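"""Association testing, BH threshold and single-gene marker behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import pharmbench as pb
from pharmbench.single_gene import _welch_pvalues
from conftest import make_response


def _mutation_table(status: pd.DataFrame) -> pb.MutationTable:
    raw = status.map(lambda m: "p.MUT::0<cn<8" if m else "wt::0<cn<8")
    return pb.MutationTable(raw)


# ---------------------------------------------------------------------------
# stand-in association test
# ---------------------------------------------------------------------------


def test_welch_pvalues_match_scipy(rng):
    y = rng.normal(size=60)
    status = rng.random((60, 25)) < 0.4
    ok = (status.sum(0) >= 2) & ((~status).sum(0) >= 2)
    ours = _welch_pvalues(y, status[:, ok])
    for j, col in enumerate(np.nonzero(ok)[0]):
        ref = stats.ttest_ind(y[status[:, col]], y[~status[:, col]], equal_var=False).pvalue
        assert ours[j] == pytest.approx(ref, rel=1e-9)


def test_identical_groups_give_p_one():
    # constant response: no location difference whatsoever
    cells = [f"CL{i}" for i in range(10)]
    resp = make_response("1", [("d", c, 1.5) for c in cells])
    status = pd.DataFrame({"g1": [True] * 5 + [False] * 5}, index=cells)
    table = pb.test_associations(resp, _mutation_table(status), min_mutants=3)
    assert table.rows["p_value"].iloc[0] == 1.0


def test_count_filter_omits_rare_genes():
    cells = [f"CL{i}" for i in range(10)]
    resp = make_response("1", [("d", c, float(i)) for i, c in enumerate(cells)])
    status = pd.DataFrame(
        {"common": [True] * 5 + [False] * 5, "rare": [True] + [False] * 9}, index=cells
    )
    table = pb.test_associations(resp, _mutation_table(status), min_mutants=3)
    assert set(table.rows["gene_id"]) == {"common"}


def test_no_testable_pair_raises():
    cells = ["CL0", "CL1"]
    resp = make_response("1", [("d", c, 0.0) for c in cells])
    status = pd.DataFrame({"g1": [True, False]}, index=cells)
    with pytest.raises(ValueError):
        pb.test_associations(resp, _mutation_table(status), min_mutants=3)


def test_effect_direction_sensitising_when_mutants_lower(rng):
    cells = [f"CL{i}" for i in range(40)]
    mutant = np.arange(40) < 15
    y = np.where(mutant, -2.0, 0.0) + 0.1 * rng.standard_normal(40)
    resp = make_response("1", [("d", c, v) for c, v in zip(cells, y)])
    status = pd.DataFrame({"g1": mutant}, index=cells)
    table = pb.test_associations(resp, _mutation_table(status))
    assert table.rows["effect_direction"].iloc[0] == "sensitising"


def test_null_type_one_error_calibrated(rng):
    """On unrelated data, roughly 5% of associations reach p<0.05."""
    n_cells, n_genes = 50, 250
    cells = [f"CL{i}" for i in range(n_cells)]
    pvals = []
    for rep in range(4):
        y = rng.standard_normal(n_cells)
        status = pd.DataFrame(
            rng.random((n_cells, n_genes)) < 0.3,
            index=cells,
            columns=[f"g{j}" for j in range(n_genes)],
        )
        resp = make_response("1", [("d", c, v) for c, v in zip(cells, y)])
        table = pb.test_associations(resp, _mutation_table(status))
        pvals.append(table.rows["p_value"].to_numpy())
    frac = float(np.mean(np.concatenate(pvals) < 0.05))
    assert 0.03 <= frac <= 0.07


# ---------------------------------------------------------------------------
# Benjamini-Hochberg threshold
# ---------------------------------------------------------------------------


def _bh_oracle(p, fdr):
    """Naive step-up: scan the sorted list for the largest qualifying p_(k)."""
    p = sorted(p)
    m = len(p)
    best = 0.0
    for k, pk in enumerate(p, start=1):
        if pk <= k / m * fdr:
            best = pk
    return best


def test_bh_threshold_worked_example():
    # 0.02 <= (2/3)*0.2 qualifies; 0.9 does not
    assert pb.bh_threshold([0.01, 0.02, 0.9], fdr=0.2) == 0.02


def test_bh_threshold_nothing_significant():
    assert pb.bh_threshold([1.0, 1.0, 1.0], fdr=0.2) == 0.0


def test_bh_threshold_rejects_invalid_p():
    with pytest.raises(ValueError):
        pb.bh_threshold([0.0, 0.5])
    with pytest.raises(ValueError):
        pb.bh_threshold([])


@given(
    st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=60),
    st.sampled_from([0.05, 0.1, 0.2, 0.5]),
)
def test_bh_threshold_matches_oracle(p, fdr):
    assert pb.bh_threshold(p, fdr=fdr) == _bh_oracle(p, fdr)


@given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=60))
def test_bh_rejection_set_matches_statsmodels(p):
    """Our p <= threshold rule reproduces the reference BH rejection set."""
    from statsmodels.stats.multitest import multipletests

    thr = pb.bh_threshold(p, fdr=0.2)
    reject = multipletests(p, alpha=0.2, method="fdr_bh")[0]
    ours = np.asarray(p) <= thr if thr > 0 else np.zeros(len(p), dtype=bool)
    assert (ours == reject).all()


# ---------------------------------------------------------------------------
# marker selection and prediction
# ---------------------------------------------------------------------------


def _assoc(rows):
    return pb.AssociationTable(
        pd.DataFrame(rows, columns=["drug_id", "gene_id", "p_value", "effect_direction"])
    )


def test_select_best_marker_is_argmin():
    table = _assoc([("d", "gA", 0.002, "sensitising"), ("d", "gB", 0.3, "resistance")])
    marker = pb.select_best_marker("d", table)
    assert marker.gene_id == "gA" and marker.p_value == 0.002


def test_select_best_marker_kept_even_if_not_significant():
    table = _assoc([("d", "gA", 0.9, "unknown")])
    marker = pb.select_best_marker("d", table)
    assert marker.gene_id == "gA" and not marker.significant


def test_select_best_marker_tie_breaks_lexicographically():
    table = _assoc([("d", "gB", 0.01, "unknown"), ("d", "gA", 0.01, "unknown")])
    assert pb.select_best_marker("d", table).gene_id == "gA"


def test_select_best_marker_missing_drug():
    table = _assoc([("d", "gA", 0.01, "unknown")])
    with pytest.raises(KeyError):
        pb.select_best_marker("other", table)


def test_predict_mutant_means_sensitive():
    cells = [f"CL{i}" for i in range(5)]
    status = pd.DataFrame({"g1": [True, True, False, False, False]}, index=cells)
    marker = pb.MarkerModel("d", "g1", 0.01, True)
    pred = pb.predict_single_gene(marker, _mutation_table(status), cells)
    assert pred.sum() == 2 and pred.tolist() == [True, True, False, False, False]


def test_no_mutant_cells_give_zero_positive_predictions():
    """A marker with no mutant test cell yields TP=FP=0, hence MCC=PR=0."""
    cells = [f"CL{i}" for i in range(5)]
    status = pd.DataFrame({"g1": [False] * 5}, index=cells)
    marker = pb.MarkerModel("d", "g1", 0.01, True)
    pred = pb.predict_single_gene(marker, _mutation_table(status), cells)
    truth = np.array([True, True, False, False, True])
    c = pb.confusion(pred, truth)
    assert (c.tp, c.fp) == (0, 0)
    assert pb.mcc(c) == 0.0
    assert pb.precision_recall_f1(c)[0] == 0.0


def test_predict_missing_cell_named():
    status = pd.DataFrame({"g1": [True]}, index=["CL0"])
    marker = pb.MarkerModel("d", "g1", 0.01, True)
    with pytest.raises(KeyError, match="CL_missing"):
        pb.predict_single_gene(marker, _mutation_table(status), ["CL0", "CL_missing"])


def test_direction_aware_mode_flips_resistance_markers():
    cells = ["CL0", "CL1"]
    status = pd.DataFrame({"g1": [True, False]}, index=cells)
    marker = pb.MarkerModel("d", "g1", 0.01, True, effect_direction="resistance")
    default = pb.predict_single_gene(marker, _mutation_table(status), cells)
    aware = pb.predict_single_gene(marker, _mutation_table(status), cells, direction_aware=True)
    assert default.tolist() == [True, False]
    assert aware.tolist() == [False, True]


def test_marker_selection_ignores_test_release(small_cohort):
    """Recomputing markers after permuting test responses changes nothing."""
    assoc = pb.test_associations(small_cohort.response_r1, small_cohort.mutations)
    drug = small_cohort.response_r1.drug_ids()[0]
    before = pb.select_best_marker(drug, assoc)
    shuffled = small_cohort.response_r2.entries.copy()
    shuffled["logic50"] = shuffled["logic50"].sample(frac=1, random_state=0).to_numpy()
    # associations are computed from release 1 only; release 2 never enters
    assoc_after = pb.test_associations(small_cohort.response_r1, small_cohort.mutations)
    after = pb.select_best_marker(drug, assoc_after)
    assert before == after
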