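"""Hit identification and validation.

A cut-off is chosen (from sample/control statistics, an explicit value, or
a rank on the ordered plot), finalized into a 0/1 hit column, and — for
deconvolution screens where each gene is re-tested with several individual
siRNA reagents — validated by Multi Reagent Analysis: each reagent passing
the threshold is mapped to its target gene and the per-gene count of
passing reagents ranks the genes. Requiring at least two independent
reagents guards against siRNA off-target effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .data_model import ScreenTable, derive_table
from .errors import IntegrityError

__all__ = [
    "CutoffSpec",
    "select_cutoff",
    "finalize_threshold",
    "column_arithmetic",
    "filter_rows",
    "multi_reagent_counts",
    "finalize_multireagent",
    "MultiReagentResult",
]

_DIRECTIONS = {"ge", "le", ">=", "<="}


def _norm_direction(direction: str) -> str:
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be 'ge' or 'le', got {direction!r}")
    return "ge" if direction in (">=", "ge") else "le"


@dataclass
class CutoffSpec:
    """How to turn a score column into a threshold.

    mode="stat": threshold = mean(reference wells) + k * SD (minus for
    direction "le"); reference is ``"samples"`` or a control type.
    mode="value": an explicit threshold. mode="rank": the value at the
    given 1-based index of the column sorted descending.
    """

    mode: str
    reference: str | None = None
    k: float | None = None
    value: float | None = None
    rank: int | None = None
    direction: str = "ge"

    def __post_init__(self) -> None:
        self.direction = _norm_direction(self.direction)
        required = {"stat": ("reference", "k"), "value": ("value",), "rank": ("rank",)}
        if self.mode not in required:
            raise ValueError(f"unknown cutoff mode {self.mode!r}")
        for f in required[self.mode]:
            if getattr(self, f) is None:
                raise ValueError(f"cutoff mode {self.mode!r} requires {f!r}")
        for f in ("reference", "k", "value", "rank"):
            if f not in required[self.mode] and getattr(self, f) is not None:
                raise ValueError(f"field {f!r} does not belong to mode {self.mode!r}")
        if self.mode == "stat" and self.k < 0:
            raise ValueError("SD multiplier k must be >= 0")


def select_cutoff(table: ScreenTable, column: str, spec: CutoffSpec) -> float:
    """Resolve a :class:`CutoffSpec` into a numeric threshold on a column."""
    if column not in table.data_columns:
        raise KeyError(f"no data column {column!r}")
    if spec.mode == "value":
        return float(spec.value)
    if spec.mode == "rank":
        v = table.records[column].dropna().sort_values(ascending=False).to_numpy()
        if not 1 <= spec.rank <= len(v):
            raise ValueError(f"rank {spec.rank} out of range 1..{len(v)}")
        return float(v[spec.rank - 1])
    # stat mode
    if spec.reference == "samples":
        ref = table.sample_wells()[column].dropna().to_numpy(dtype=float)
    else:
        ref = table.values_of_type(spec.reference, column)
        if len(ref) == 0:
            raise ValueError(f"reference control {spec.reference!r} has no measured wells")
    if len(ref) < 2:
        raise ValueError("stat-mode cutoff needs >= 2 reference values")
    sign = 1.0 if spec.direction == "ge" else -1.0
    return float(ref.mean() + sign * spec.k * ref.std(ddof=1))


def _passes(values: np.ndarray, threshold: float, direction: str) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return values >= threshold if direction == "ge" else values <= threshold


def finalize_threshold(
    table: ScreenTable, column: str, threshold: float, direction: str = "ge"
) -> tuple[ScreenTable, pd.DataFrame]:
    """Append a 0/1 hit column and return (derived table, passing genes).

    A well scores 1 iff its value passes the threshold in the stated
    direction; missing values score 0. The hit list carries gene symbol,
    Entrez id and score of each passing well.
    """
    direction = _norm_direction(direction)
    if column not in table.data_columns:
        raise KeyError(f"no data column {column!r}")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    v = table.records[column].to_numpy(dtype=float)
    flags = _passes(v, threshold, direction) & ~np.isnan(v)
    child = table.with_column(
        f"{column}_hit",
        flags.astype(float),
        f"hit({column} {'>=' if direction == 'ge' else '<='} {threshold:g})",
    )
    hit_list = (
        table.records.loc[flags, ["gene_symbol", "entrez_id", column]]
        .rename(columns={column: "score"})
        .sort_values("score", ascending=(direction == "le"))
        .reset_index(drop=True)
    )
    return child, hit_list


_OPS: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {
    "+": np.add,
    "-": np.subtract,
    "*": np.multiply,
    "/": np.divide,
}


def column_arithmetic(
    table: ScreenTable, col_a: str, other: str | float, op: str
) -> ScreenTable:
    """Element-wise column arithmetic: ``col_a <op> (column | scalar)``.

    Division by zero yields missing values; their count is recorded in the
    derivation log.
    """
    if op not in _OPS:
        raise ValueError(f"op must be one of {sorted(_OPS)}, got {op!r}")
    if col_a not in table.data_columns:
        raise KeyError(f"no data column {col_a!r}")
    a = table.records[col_a].to_numpy(dtype=float)
    if isinstance(other, str):
        if other not in table.data_columns:
            raise KeyError(f"no data column {other!r}")
        b = table.records[other].to_numpy(dtype=float)
        b_label = other
    else:
        b = np.full_like(a, float(other))
        b_label = f"{other:g}"
    with np.errstate(divide="ignore", invalid="ignore"):
        out = _OPS[op](a, b)
    out[~np.isfinite(out)] = np.nan
    n_div0 = int((b == 0).sum()) if op == "/" else 0
    log = f"{col_a} {op} {b_label}"
    if n_div0:
        log += f"; {n_div0} division(s) by zero -> missing"
    return table.with_column(f"{col_a}{op}{b_label}", out, log)


def filter_rows(table: ScreenTable, predicate: str | Callable[[pd.DataFrame], pd.Series]) -> ScreenTable:
    """Derive the subset of rows satisfying a predicate.

    ``predicate`` is either a pandas query string over the table's columns
    (e.g. ``"Signal_ctrl >= 0.6 and well_type == 'sample'"``) or a callable
    mapping the records DataFrame to a boolean mask. The predicate text is
    recorded in the derivation log.
    """
    if callable(predicate):
        mask = predicate(table.records)
        label = getattr(predicate, "__name__", "callable")
    else:
        try:
            mask = table.records.eval(predicate)
        except Exception as exc:
            raise ValueError(f"malformed predicate {predicate!r}: {exc}") from None
        label = predicate
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (len(table.records),):
        raise ValueError("predicate must yield one boolean per row")
    return derive_table(table, table.records.loc[mask], f"filter({label})")


@dataclass
class MultiReagentResult:
    """Outcome of Multi Reagent Analysis on one score column.

    ``reagent_flags`` has one row per scored reagent with its 0/1 pass
    flag; ``gene_counts`` aggregates per gene (n_total, n_passing), ranked
    by n_passing descending with ties broken by gene symbol.
    """

    column: str
    threshold: float
    direction: str
    reagent_flags: pd.DataFrame
    gene_counts: pd.DataFrame

    def validated_genes(self, min_reagents: int = 2) -> pd.DataFrame:
        """Genes with at least ``min_reagents`` passing reagents."""
        g = self.gene_counts
        return g[g["n_passing"] >= min_reagents].reset_index(drop=True)


def multi_reagent_counts(
    table: ScreenTable, column: str, threshold: float, direction: str = "ge"
) -> MultiReagentResult:
    """Flag each reagent against a threshold and count passes per gene.

    Every scored row must carry a reagent id, and a reagent id must map to
    exactly one gene. Rows with a missing score are excluded from both the
    pass count and the reagent total of their gene, so unmeasured reagents
    do not penalize a gene.
    """
    direction = _norm_direction(direction)
    if column not in table.data_columns:
        raise KeyError(f"no data column {column!r}")
    rec = table.records
    scored = rec[rec[column].notna()].copy()
    no_reagent = scored["reagent_id"].isna()
    if no_reagent.any():
        rows = scored.index[no_reagent].tolist()[:10]
        raise IntegrityError(f"scored rows lacking a reagent id (first rows: {rows})")
    genes_per_reagent = scored.groupby("reagent_id")["entrez_id"].nunique()
    multi = genes_per_reagent[genes_per_reagent > 1]
    if not multi.empty:
        raise IntegrityError(
            f"reagent(s) mapping to more than one gene: {multi.index.tolist()[:5]}"
        )
    v = scored[column].to_numpy(dtype=float)
    scored["passed"] = _passes(v, threshold, direction).astype(int)
    flags = scored[
        ["reagent_id", "entrez_id", "gene_symbol", column, "passed"]
    ].rename(columns={column: "score"}).reset_index(drop=True)
    counts = (
        flags.groupby(["entrez_id", "gene_symbol"], dropna=False)
        .agg(n_total=("passed", "size"), n_passing=("passed", "sum"))
        .reset_index()
        .sort_values(
            ["n_passing", "gene_symbol"], ascending=[False, True], kind="mergesort"
        )
        .reset_index(drop=True)
    )
    return MultiReagentResult(
        column=column,
        threshold=float(threshold),
        direction=direction,
        reagent_flags=flags,
        gene_counts=counts,
    )


def finalize_multireagent(table: ScreenTable, result: MultiReagentResult) -> ScreenTable:
    """Append per-reagent validated flags and per-gene validated counts.

    Adds two columns: ``<column>_validated`` (1 if that row's reagent
    passed, 0 otherwise) and ``<column>_n_validated`` (the constant
    per-gene count of passing reagents, 0 for genes with none).
    """
    col = result.column
    rec = table.records.copy()
    flag_by_reagent = dict(
        zip(result.reagent_flags["reagent_id"], result.reagent_flags["passed"])
    )
    count_by_gene = dict(
        zip(result.gene_counts["entrez_id"], result.gene_counts["n_passing"])
    )
    rec[f"{col}_validated"] = [
        float(flag_by_reagent.get(r, 0)) for r in rec["reagent_id"]
    ]
    rec[f"{col}_n_validated"] = [
        float(count_by_gene.get(g, 0)) for g in rec["entrez_id"]
    ]
    child = derive_table(
        table,
        rec,
        f"multireagent({col} {'>=' if result.direction == 'ge' else '<='} "
        f"{result.threshold:g})",
    )
    return child
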