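"""Data model and CSV readers/writers for GDSC-style pharmacogenomic tables.

The GDSC (Genomics of Drug Sensitivity in Cancer) distributes, per data
release, a normalized gene-expression matrix, a table of mutation
annotations for frequently mutated cancer genes, and a sparse drug x
cell-line table of IC50 measurements.  This module defines in-memory
containers for those tables, the mutation-annotation dialect, and the
response-value conversion from natural-log to log10 µM units.

CSV dialect: comma-separated, UTF-8, one header row and one header column.
Expression files are oriented genes-as-columns by default (one row per cell
line); response tables are long-form ``drug_id,cell_line_id,logic50``;
mutation tables are wide (cell lines x genes) holding raw ``x::y`` strings.

Real-file ingestion note (untested adapter): in the released
``gdsc_manova_input_w1.csv`` the first columns identify the cell line and
tissue, mutation annotations occupy one column per cancer gene (``x::y``
strings plus translocation and ``msi`` columns), and per-drug natural-log
IC50 columns are named ``<drug>_IC_50``.  Such a file can be split into the
three tables below with ordinary pandas indexing, converting IC50 columns
through :func:`convert_ln_to_log10`.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "MutationTable",
    "ResponseTable",
    "AssociationTable",
    "DrugDataset",
    "MutationAnnotationError",
    "parse_mutation_annotation",
    "convert_ln_to_log10",
    "read_expression_csv",
    "write_expression_csv",
    "read_response_csv",
    "write_response_csv",
    "read_mutation_csv",
    "write_mutation_csv",
    "deduplicate_drugs",
    "align_cohort",
]


class MutationAnnotationError(ValueError):
    """Raised when a mutation annotation string cannot be interpreted."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Normalized expression levels, cell lines x genes.

    ``frame`` is indexed by cell-line identifier with one column per gene
    symbol.  Values are unitless log-scale intensities (RMA-normalized
    upstream); no re-normalization is applied here.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        idx, cols = self.frame.index, self.frame.columns
        for axis_name, labels in (("cell line", idx), ("gene", cols)):
            if labels.has_duplicates:
                dups = sorted(labels[labels.duplicated()].unique())
                raise ValueError(f"duplicate {axis_name} identifiers: {dups}")
        if self.frame.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape


@dataclass
class MutationTable:
    """Raw ``x::y`` annotations plus derived binary wt/mutated statuses.

    ``raw`` is a cell-line x gene frame of annotation strings (point
    mutations in ``x::y`` form, translocation tokens, msi tokens); ``status``
    is the boolean frame derived from it (True = mutated), aligned to the
    same axes.
    """

    raw: pd.DataFrame
    status: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.raw.index.has_duplicates or self.raw.columns.has_duplicates:
            raise ValueError("duplicate identifiers in mutation table")
        if self.status is None:
            self.status = self.raw.map(parse_mutation_annotation)
        if self.status.isna().any().any():
            raise ValueError("mutation status undefined for some (cell, gene) pair")

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.raw.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.raw.columns)

    def status_of(self, gene_id: str, cell_ids: Sequence[str]) -> np.ndarray:
        """Boolean mutated-status vector for one gene over ``cell_ids``.

        Raises ``KeyError`` naming any cell line without a recorded status.
        """
        missing = [c for c in cell_ids if c not in self.status.index]
        if missing:
            raise KeyError(f"no mutation status for cell line(s): {missing}")
        return self.status.loc[list(cell_ids), gene_id].to_numpy(dtype=bool)


@dataclass
class ResponseTable:
    """Sparse drug x cell-line logIC50 measurements for one data release.

    ``entries`` is a long-form frame with columns ``drug_id``,
    ``cell_line_id`` and ``logic50`` (log10 µM).  Not every drug-cell pair
    is present; every stored value is finite.
    """

    release_tag: str
    entries: pd.DataFrame

    COLUMNS = ("drug_id", "cell_line_id", "logic50")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.entries.columns]
        if missing:
            raise ValueError(f"response table missing columns {missing}")
        self.entries = self.entries[list(self.COLUMNS)].reset_index(drop=True)
        if self.entries.duplicated(["drug_id", "cell_line_id"]).any():
            raise ValueError("duplicate (drug, cell line) pairs in response table")
        if not np.isfinite(self.entries["logic50"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite logIC50 value in response table")

    @property
    def n_pairs(self) -> int:
        return len(self.entries)

    def drug_ids(self) -> list[str]:
        return sorted(self.entries["drug_id"].unique())

    def cell_line_ids(self) -> list[str]:
        return sorted(self.entries["cell_line_id"].unique())

    def for_drug(self, drug_id: str) -> pd.Series:
        """logIC50 values for one drug, indexed by cell line."""
        sub = self.entries[self.entries["drug_id"] == drug_id]
        return pd.Series(
            sub["logic50"].to_numpy(), index=sub["cell_line_id"].to_numpy(), name=drug_id
        )

    def restrict_cells(self, cell_ids: Iterable[str]) -> "ResponseTable":
        keep = self.entries["cell_line_id"].isin(set(cell_ids))
        return ResponseTable(self.release_tag, self.entries[keep].copy())

    def shifted(self, shift: float) -> "ResponseTable":
        out = self.entries.copy()
        out["logic50"] = out["logic50"] + shift
        return ResponseTable(self.release_tag, out)


@dataclass
class AssociationTable:
    """Drug-gene association statistics: one row per (drug, gene) pair."""

    rows: pd.DataFrame

    COLUMNS = ("drug_id", "gene_id", "p_value", "effect_direction")
    DIRECTIONS = frozenset({"sensitising", "resistance", "unknown"})

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"association table missing columns {missing}")
        self.rows = self.rows[list(self.COLUMNS)].reset_index(drop=True)
        p = self.rows["p_value"].to_numpy(dtype=float)
        if not ((p > 0) & (p <= 1)).all():
            raise ValueError("association p-values must lie in (0, 1]")
        if self.rows.duplicated(["drug_id", "gene_id"]).any():
            raise ValueError("more than one row for some (drug, gene) pair")
        bad = set(self.rows["effect_direction"]) - self.DIRECTIONS
        if bad:
            raise ValueError(f"unknown effect direction(s): {sorted(bad)}")

    def for_drug(self, drug_id: str) -> pd.DataFrame:
        return self.rows[self.rows["drug_id"] == drug_id]

    @property
    def p_values(self) -> np.ndarray:
        return self.rows["p_value"].to_numpy(dtype=float)


@dataclass
class DrugDataset:
    """Paired (logIC50, expression-vector) records for one drug.

    The expression block is stored float32: forests on thousands of genes
    fit markedly faster and the precision is ample for tree splits.
    """

    drug_id: str
    cell_line_ids: list[str]
    logic50: np.ndarray
    expression: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        if len(set(self.cell_line_ids)) != len(self.cell_line_ids):
            raise ValueError(f"duplicate cell lines in dataset for {self.drug_id}")
        self.logic50 = np.asarray(self.logic50, dtype=float)
        self.expression = np.asarray(self.expression, dtype=np.float32)
        if not (len(self.cell_line_ids) == len(self.logic50) == len(self.expression)):
            raise ValueError("record count mismatch in drug dataset")

    @property
    def n(self) -> int:
        return len(self.cell_line_ids)


# ---------------------------------------------------------------------------
# Mutation-annotation dialect
# ---------------------------------------------------------------------------

# Tokens seen outside the x::y dialect: translocation columns hold either the
# identified fusion (e.g. "BCR_ABL") or "not-detected"; the msi column flags
# microsatellite instability.
_WT_TOKENS = frozenset({"wt", "na", "not-detected", "nd", "mss", "msi-l", "stable"})
_MUT_TOKENS = frozenset({"msi", "msi-h", "unstable"})

_CN_RANGE = re.compile(r"^(-?\d+(?:\.\d+)?)<cn<(-?\d+(?:\.\d+)?)$")
_CN_POINT = re.compile(r"^cn==?(-?\d+(?:\.\d+)?)$")
_CN_LOWER = re.compile(r"^(-?\d+(?:\.\d+)?)(<|<=)cn$")
_CN_UPPER = re.compile(r"^cn(<|<=)(-?\d+(?:\.\d+)?)$")
_CN_GT = re.compile(r"^cn(>|>=)(-?\d+(?:\.\d+)?)$")


def _copy_number_is_wt(descriptor: str) -> bool:
    """True iff the copy-number descriptor lies wholly inside 0 < cn < 8.

    The descriptor is reduced to an interval [lo, hi] with open/closed ends;
    wild-type requires the whole interval inside the open window (0, 8).
    A deletion (cn reaching 0) or amplification (cn reaching 8 or more)
    therefore counts as mutated.
    """
    d = descriptor.replace(" ", "")
    if m := _CN_RANGE.match(d):
        lo, hi = float(m[1]), float(m[2])
        lo_open = hi_open = True
    elif m := _CN_POINT.match(d):
        lo = hi = float(m[1])
        lo_open = hi_open = False
    elif m := _CN_LOWER.match(d):  # "K<cn": unbounded above
        lo, lo_open = float(m[1]), m[2] == "<"
        hi, hi_open = math.inf, True
    elif m := _CN_GT.match(d):  # "cn>K": unbounded above
        lo, lo_open = float(m[2]), m[1] == ">"
        hi, hi_open = math.inf, True
    elif m := _CN_UPPER.match(d):  # "cn<K": copy number is bounded below by 0
        lo, lo_open = 0.0, False
        hi, hi_open = float(m[2]), m[1] == "<"
    else:
        raise MutationAnnotationError(f"unparseable copy-number descriptor: {descriptor!r}")
    lo_inside = lo > 0 or (lo == 0 and lo_open)
    hi_inside = hi < 8 or (hi == 8 and hi_open)
    return lo_inside and hi_inside


def parse_mutation_annotation(raw: str) -> bool:
    """Classify one annotation as mutated (True) or wild-type (False).

    A gene is annotated mutated if (a) a protein sequence variant is
    detected (the ``x`` part of ``x::y`` is neither ``wt`` nor ``na``), or
    (b) the copy-number part ``y`` denotes a deletion/amplification, i.e. a
    range not wholly inside the wild-type window 0<cn<8.  Translocation
    features are mutated iff a fusion is identified (anything other than
    ``not-detected``); msi status is mutated iff instability is flagged.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise MutationAnnotationError(f"unparseable mutation annotation: {raw!r}")
    text = raw.strip()
    if "::" in text:
        x, _, y = text.partition("::")
        x = x.strip().lower()
        y = y.strip()
        if not x:
            raise MutationAnnotationError(f"unparseable mutation annotation: {raw!r}")
        variant = x not in {"wt", "na"}
        if not y:
            return variant
        # y is validated even when the variant rule already decides the call
        return bool(not _copy_number_is_wt(y) or variant)
    token = text.lower()
    if token in _WT_TOKENS:
        return False
    if token in _MUT_TOKENS:
        return True
    # translocation columns name the identified fusion, e.g. "BCR_ABL"
    if re.fullmatch(r"[A-Za-z0-9]+(_[A-Za-z0-9]+)+", text):
        return True
    raise MutationAnnotationError(f"unparseable mutation annotation: {raw!r}")


# ---------------------------------------------------------------------------
# Response-value conversion
# ---------------------------------------------------------------------------

_LN10 = math.log(10.0)


def convert_ln_to_log10(value: float) -> float:
    """Convert a natural-log IC50 (µM) to log10 µM, so logIC50=1 ⇔ IC50=10µM."""
    arr = np.asarray(value, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite IC50 value")
    out = arr / _LN10
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# CSV readers/writers
# ---------------------------------------------------------------------------


def read_expression_csv(path: str | Path, orientation: str = "genes-as-columns") -> ExpressionMatrix:
    """Read an expression CSV; ``orientation`` resolves which axis is which.

    ``genes-as-columns`` (default): rows are cell lines.  ``genes-as-rows``:
    the file is transposed on read.  Duplicate identifiers or non-numeric
    cells are hard errors.
    """
    if orientation not in ("genes-as-columns", "genes-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    # pandas mangles duplicate header names (X, X.1, ...): check the raw header
    import csv

    with open(path, "r", encoding="utf-8", newline="") as fh:
        header = next(csv.reader(fh))[1:]
    if len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate identifiers in header: {dups}")
    frame = pd.read_csv(path, index_col=0)
    if orientation == "genes-as-rows":
        frame = frame.T
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        bad = frame.apply(pd.to_numeric, errors="coerce").isna()
        cells = [(r, c) for r, c in zip(*np.nonzero(bad.to_numpy()))]
        loc = [(frame.index[r], frame.columns[c]) for r, c in cells[:5]]
        raise ValueError(f"non-numeric expression value(s) at {loc}") from exc
    matrix = ExpressionMatrix(frame)
    logger.info(
        "read expression matrix %s: %d cell lines x %d genes", path, *matrix.shape
    )
    return matrix


def write_expression_csv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.frame.to_csv(path)


def read_response_csv(path: str | Path) -> ResponseTable:
    """Read a long-form response CSV with a ``release_tag`` column."""
    frame = pd.read_csv(path, dtype={"drug_id": str, "cell_line_id": str})
    tags = frame["release_tag"].unique()
    if len(tags) != 1:
        raise ValueError(f"response file must carry a single release_tag, found {tags}")
    return ResponseTable(str(tags[0]), frame.drop(columns=["release_tag"]))


def write_response_csv(table: ResponseTable, path: str | Path) -> None:
    out = table.entries.copy()
    out["release_tag"] = table.release_tag
    out.to_csv(path, index=False)


def read_mutation_csv(path: str | Path) -> MutationTable:
    raw = pd.read_csv(path, index_col=0, dtype=str)
    return MutationTable(raw)


def write_mutation_csv(table: MutationTable, path: str | Path) -> None:
    table.raw.to_csv(path)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


def deduplicate_drugs(
    response: ResponseTable, duplicate_groups: Sequence[Sequence[str]] = ()
) -> ResponseTable:
    """Keep, per duplicate-compound group, the most widely tested instance.

    ``duplicate_groups`` lists drug ids known to denote the same compound
    (a synonym map).  Within each group only the instance tested on the
    most cell lines is retained; exact ties are broken toward the lower
    drug id (numerically when ids are numeric, else lexicographically).
    """
    drop: set[str] = set()
    counts = response.entries.groupby("drug_id")["cell_line_id"].nunique()
    for group in duplicate_groups:
        present = [d for d in group if d in counts.index]
        if len(present) < 2:
            continue

        def sort_key(d: str):
            try:
                ident: tuple = (0, float(d))
            except ValueError:
                ident = (1, d)
            return (-counts[d], ident)

        keep = min(present, key=sort_key)
        drop.update(d for d in present if d != keep)
        logger.info("duplicate group %s: keeping %s (%d cell lines)", group, keep, counts[keep])
    if not drop:
        return response
    kept = response.entries[~response.entries["drug_id"].isin(drop)].copy()
    return ResponseTable(response.release_tag, kept)


def align_cohort(
    expression: ExpressionMatrix,
    mutations: MutationTable,
    *responses: ResponseTable,
) -> tuple:
    """Restrict all tables to cell lines with expression data.

    Cell lines in the response or mutation tables without an expression
    profile are dropped (not imputed); row order follows the expression
    matrix.  Raises ``ValueError`` when a response table loses all entries.
    """
    cells = [c for c in expression.cell_line_ids if c in set(mutations.cell_line_ids)]
    if not cells:
        raise ValueError("no cell line has both expression and mutation data")
    dropped_expr = sorted(set(expression.cell_line_ids) - set(cells))
    if dropped_expr:
        logger.info("align_cohort: dropping %d cell lines without mutation data", len(dropped_expr))
    expr = ExpressionMatrix(expression.frame.loc[cells])
    mut = MutationTable(mutations.raw.loc[cells], mutations.status.loc[cells])
    out: list = [expr, mut]
    cell_set = set(cells)
    for resp in responses:
        before = resp.n_pairs
        sub = resp.restrict_cells(cell_set)
        if sub.n_pairs == 0:
            raise ValueError(
                f"release {resp.release_tag}: no tested cell line has expression data"
            )
        if sub.n_pairs < before:
            logger.info(
                "align_cohort: release %s: dropped %d of %d response entries",
                resp.release_tag, before - sub.n_pairs, before,
            )
        out.append(sub)
    return tuple(out)
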