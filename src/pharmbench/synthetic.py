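"""Two-release synthetic pharmacogenomic cohorts with known ground truth.

The generator emulates the structure of consecutive GDSC data releases at
desk scale: a gene-expression matrix and a mutation table over a shared
cell-line panel, plus one sparse logIC50 response table per release, where
the second release contributes only newly tested cell lines (so the
chronological split has a genuinely prospective test set).  Each drug
follows one of three archetypes with recorded ground truth:

* ``monogenic`` — logIC50 = baseline + β·m(causal gene) + noise, where m is
  the binary mutation status.  Negative β is a sensitising effect (mutants
  respond at lower concentration).
* ``polygenic`` — logIC50 = baseline + Σ_k w_k·z_k + noise over n_causal
  standardized expression values, weights w_k ~ N(0, weight_scale²).
* ``null`` — logIC50 = baseline + noise; no causal genes.

An optional ``coupling`` shifts the expression of a causal gene in mutated
cells by coupling·σ_g, so genomic and transcriptomic signal overlap (as in
real tumours, where driver mutations perturb expression programmes);
``batch_shift`` adds a constant to every release-2 measurement, emulating
the time-dependent batch effects that make cross-validation optimistic
relative to time-split testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_gdsc import (
    ExpressionMatrix,
    MutationTable,
    ResponseTable,
    write_expression_csv,
    write_mutation_csv,
    write_response_csv,
)

__all__ = [
    "DrugSpec",
    "GeneratorConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "default_drug_panel",
    "generate_cohort",
    "inject_batch_shift",
]

ARCHETYPES = ("monogenic", "polygenic", "null")


@dataclass(frozen=True)
class DrugSpec:
    """Archetype and effect parameters for one synthetic drug.

    ``effect`` is the monogenic logIC50 shift in mutated cell lines
    (negative = sensitising) or, for polygenic drugs, the weight scale of
    the per-gene N(0, effect²) weights.  ``n_causal`` applies to polygenic
    drugs only.
    """

    archetype: str
    effect: float = -2.0
    n_causal: int = 20

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.archetype == "polygenic" and self.n_causal < 1:
            raise ValueError("polygenic drugs need n_causal >= 1")


def default_drug_panel(
    n_monogenic: int = 3,
    n_polygenic: int = 3,
    n_null: int = 3,
    effect: float = -2.0,
    weight_scale: float = 0.25,
    n_causal: int = 20,
) -> list[DrugSpec]:
    """A mixed panel of drug specs, one list entry per drug."""
    return (
        [DrugSpec("monogenic", effect)] * n_monogenic
        + [DrugSpec("polygenic", weight_scale, n_causal)] * n_polygenic
        + [DrugSpec("null", 0.0)] * n_null
    )


@dataclass
class GeneratorConfig:
    """Cohort dimensions, effect sizes and nuisance parameters.

    Defaults are sized for desk-scale analysis: 2,000 genes, 300 release-1
    cell lines and 150 new release-2 lines (the full 13,321-gene scale is
    supported but not default).  ``mutation_freq_range`` spans the
    per-gene mutation frequencies; the default (0.10, 0.50) mirrors panels
    of frequently mutated cancer genes.  ``noise_sd`` and ``batch_shift``
    are in logIC50 (log10 µM) units; ``coupling`` is the expression shift
    of a causal gene in mutated cells, in units of that gene's SD.
    """

    n_genes: int = 2000
    n_cells_release1: int = 300
    n_cells_new_release2: int = 150
    mutation_freq_range: tuple[float, float] = (0.10, 0.50)
    drug_specs: list[DrugSpec] = field(default_factory=default_drug_panel)
    noise_sd: float = 0.5
    batch_shift: float = 0.0
    coupling: float = 1.0
    missing_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_cells_release1, self.n_cells_new_release2) < 1:
            raise ValueError("counts must be positive")
        lo, hi = self.mutation_freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("mutation_freq_range must lie inside (0, 1)")
        if not (0 <= self.missing_fraction < 1):
            raise ValueError("missing_fraction must lie in [0, 1)")
        if not self.drug_specs:
            raise ValueError("at least one drug spec required")
        for spec in self.drug_specs:
            if spec.archetype == "polygenic" and spec.n_causal > self.n_genes:
                raise ValueError(
                    f"n_causal={spec.n_causal} exceeds n_genes={self.n_genes}"
                )


@dataclass
class SyntheticTruth:
    """Ground truth per drug: archetype, causal genes, effects, baseline.

    ``rows`` has one row per (drug, causal gene) — null drugs appear once
    with an empty causal gene.
    """

    rows: pd.DataFrame

    COLUMNS = ("drug_id", "archetype", "causal_gene", "effect", "baseline")

    def archetype_of(self, drug_id: str) -> str:
        sub = self.rows[self.rows["drug_id"] == drug_id]
        if sub.empty:
            raise KeyError(drug_id)
        return str(sub["archetype"].iloc[0])

    def causal_genes(self, drug_id: str) -> list[str]:
        sub = self.rows[self.rows["drug_id"] == drug_id]
        return [g for g in sub["causal_gene"] if g]

    def to_csv(self, path: str | Path) -> None:
        self.rows.to_csv(path, index=False)


@dataclass
class SyntheticCohort:
    """Everything the generator emits for one two-release cohort.

    ``mutation_freq`` records the generative per-gene mutation
    probability f_g (indexed by gene id), for calibration checks.
    """

    expression: ExpressionMatrix
    mutations: MutationTable
    response_r1: ResponseTable
    response_r2: ResponseTable
    truth: SyntheticTruth
    mutation_freq: pd.Series = None  # type: ignore[assignment]

    def write_csvs(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_expression_csv(self.expression, outdir / "expression.csv")
        write_mutation_csv(self.mutations, outdir / "mutations.csv")
        write_response_csv(self.response_r1, outdir / "response_r1.csv")
        write_response_csv(self.response_r2, outdir / "response_r2.csv")
        self.truth.to_csv(outdir / "truth.csv")


def _drop_missing(entries: pd.DataFrame, fraction: float, rng: np.random.Generator) -> pd.DataFrame:
    if fraction == 0:
        return entries
    keep = rng.random(len(entries)) >= fraction
    return entries[keep].reset_index(drop=True)


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a reproducible two-release cohort from ``config.seed``.

    Expression is N(μ_g, σ_g²) with per-gene μ_g ~ U(4, 10) and σ_g ~
    U(0.3, 1.5) (RMA-like log-intensity scale); mutation statuses are
    Bernoulli(f_g) with f_g ~ U(mutation_freq_range).  Causal genes are
    drawn without replacement and disjointly across drugs so each drug's
    ground truth is unambiguous.  Release-2 response covers only the new
    cell lines and carries the configured batch shift; a
    ``missing_fraction`` of drug-cell pairs is removed at random from each
    release.
    """
    rng = np.random.default_rng(config.seed)
    n_cells = config.n_cells_release1 + config.n_cells_new_release2
    width = max(4, len(str(n_cells)))
    cells = [f"CL{i:0{width}d}" for i in range(1, n_cells + 1)]
    r1_cells = cells[: config.n_cells_release1]
    genes = [f"G{i:0{max(4, len(str(config.n_genes)))}d}" for i in range(1, config.n_genes + 1)]

    mu = rng.uniform(4.0, 10.0, size=config.n_genes)
    sigma = rng.uniform(0.3, 1.5, size=config.n_genes)
    freq = rng.uniform(*config.mutation_freq_range, size=config.n_genes)

    mutated = rng.random((n_cells, config.n_genes)) < freq
    expr = mu + sigma * rng.standard_normal((n_cells, config.n_genes))

    # causal genes: disjoint across drugs so the truth table is unambiguous
    n_needed = sum(
        1 if s.archetype == "monogenic" else s.n_causal if s.archetype == "polygenic" else 0
        for s in config.drug_specs
    )
    if n_needed > config.n_genes:
        raise ValueError(f"drug specs require {n_needed} causal genes but only {config.n_genes} exist")
    causal_pool = list(rng.choice(config.n_genes, size=n_needed, replace=False))

    truth_rows: list[dict] = []
    response_rows: list[pd.DataFrame] = []
    n_drugs = len(config.drug_specs)
    for d, spec in enumerate(config.drug_specs):
        drug_id = f"drug_{d + 1:0{max(2, len(str(n_drugs)))}d}"
        baseline = rng.uniform(-1.0, 2.0)
        y = np.full(n_cells, baseline)
        if spec.archetype == "monogenic":
            g = causal_pool.pop()
            if config.coupling != 0.0:
                expr[:, g] += config.coupling * sigma[g] * mutated[:, g]
            y = y + spec.effect * mutated[:, g]
            truth_rows.append(
                dict(drug_id=drug_id, archetype="monogenic", causal_gene=genes[g],
                     effect=spec.effect, baseline=baseline)
            )
        elif spec.archetype == "polygenic":
            gs = [causal_pool.pop() for _ in range(spec.n_causal)]
            weights = rng.normal(0.0, spec.effect, size=spec.n_causal)
            for g, w in zip(gs, weights):
                if config.coupling != 0.0:
                    expr[:, g] += config.coupling * sigma[g] * mutated[:, g]
                truth_rows.append(
                    dict(drug_id=drug_id, archetype="polygenic", causal_gene=genes[g],
                         effect=w, baseline=baseline)
                )
            z = (expr[:, gs] - mu[gs]) / sigma[gs]
            y = y + z @ weights
        else:
            truth_rows.append(
                dict(drug_id=drug_id, archetype="null", causal_gene="", effect=0.0,
                     baseline=baseline)
            )
        y = y + config.noise_sd * rng.standard_normal(n_cells)
        response_rows.append(
            pd.DataFrame({"drug_id": drug_id, "cell_line_id": cells, "logic50": y})
        )

    all_resp = pd.concat(response_rows, ignore_index=True)
    in_r1 = all_resp["cell_line_id"].isin(set(r1_cells))
    r1_entries = _drop_missing(all_resp[in_r1].reset_index(drop=True), config.missing_fraction, rng)
    r2_entries = _drop_missing(all_resp[~in_r1].reset_index(drop=True), config.missing_fraction, rng)
    r2_entries = r2_entries.assign(logic50=r2_entries["logic50"] + config.batch_shift)

    raw = pd.DataFrame(
        np.where(mutated, "p.MUT::0<cn<8", "wt::0<cn<8"), index=cells, columns=genes
    )
    cohort = SyntheticCohort(
        expression=ExpressionMatrix(pd.DataFrame(expr, index=cells, columns=genes)),
        mutations=MutationTable(raw),
        response_r1=ResponseTable("1", r1_entries),
        response_r2=ResponseTable("2", r2_entries),
        truth=SyntheticTruth(pd.DataFrame(truth_rows, columns=list(SyntheticTruth.COLUMNS))),
        mutation_freq=pd.Series(freq, index=genes, name="mutation_freq"),
    )
    return cohort


def inject_batch_shift(response: ResponseTable, shift: float) -> ResponseTable:
    """Add a constant logIC50 shift to every measurement of a release.

    Models a time-dependent batch effect: applied to the later release it
    degrades time-split test performance while leaving within-release
    cross-validation untouched.
    """
    if not np.isfinite(shift):
        raise ValueError("batch shift must be finite")
    return response.shifted(float(shift))
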