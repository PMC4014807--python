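"""Per-plate normalizations for arrayed screens.

Four methods are provided, all plate-local so that plate-to-plate drift
never leaks between plates:

* log transform;
* Z score, ``(x_i - mean_p) / sd_p`` with the plate mean and SD over all
  wells of plate *p*;
* control-based score, ``(x_i - mean_pos_p) / (mean_pos_p - mean_neg_p)``,
  which pins the positive-control mean to 0 on every plate (with a single
  control type the formula reduces to fold change relative to that
  control);
* B score: the residual of a two-way median polish of the plate divided by
  the plate's median absolute residual, robust to row and column artifacts
  such as edge effects or dispensing gradients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ScreenTable
from .errors import DegenerateDataError

__all__ = [
    "log_transform",
    "zscore",
    "control_normalize",
    "median_polish",
    "bscore",
    "PolishResult",
]


def _nanmedian(a: np.ndarray, axis=None) -> np.ndarray:
    """np.nanmedian without the all-NaN RuntimeWarning (all-NaN -> NaN)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmedian(a, axis=axis)


def log_transform(table: ScreenTable, column: str, base: float = 10.0) -> ScreenTable:
    """Derive a table with ``log_base(column)``; non-positive values become missing.

    The number of wells dropped to missing is recorded in the derivation
    log entry so provenance captures the information loss.
    """
    if base <= 0 or base == 1:
        raise ValueError("log base must be positive and != 1")
    if column not in table.data_columns:
        raise KeyError(f"no data column {column!r}")
    x = table.records[column].to_numpy(dtype=float)
    bad = np.isfinite(x) & (x <= 0)
    out = np.full_like(x, np.nan)
    ok = np.isfinite(x) & (x > 0)
    out[ok] = np.log(x[ok]) / np.log(base)
    new_col = f"{column}_log{base:g}"
    child = table.with_column(
        new_col, out, f"log(base={base:g}) of {column}; {int(bad.sum())} non-positive -> missing"
    )
    return child


def zscore(table: ScreenTable, column: str) -> ScreenTable:
    """Derive a per-plate Z-score column: ``(x_i - mean_p) / sd_p``.

    The mean and sample SD are taken over all wells of each plate
    independently. A plate with zero SD (or fewer than two measured wells)
    yields missing values for that plate, with a warning.
    """
    if column not in table.data_columns:
        raise KeyError(f"no data column {column!r}")
    x = table.records[column].astype(float)
    out = np.full(len(x), np.nan)
    for plate, idx in table.records.groupby("plate").groups.items():
        v = x.loc[idx]
        ok = v.notna()
        if ok.sum() < 2 or v[ok].std(ddof=1) == 0:
            warnings.warn(f"plate {plate}: zero variance, Z scores set to missing")
            continue
        out[table.records.index.get_indexer(idx)] = (v - v[ok].mean()) / v[ok].std(ddof=1)
    return table.with_column(f"{column}_z", out, f"zscore({column}) per plate")


def control_normalize(
    table: ScreenTable,
    column: str,
    pos_type: str | None = None,
    neg_type: str | None = None,
    orientation: str = "printed",
) -> ScreenTable:
    """Derive a control-normalized score column, plate by plate.

    With both control types given, the default ("printed") orientation is
    ``(x_i - mean_pos_p) / (mean_pos_p - mean_neg_p)``, which maps the
    positive-control mean to 0 on every plate. ``orientation="percent"``
    instead gives the conventional fraction-of-activation
    ``(x_i - mean_neg_p) / (mean_pos_p - mean_neg_p)`` (0 at the negative,
    1 at the positive control). With only one control type the score is the
    fold change ``(x_i - mean_ctrl_p) / mean_ctrl_p``.
    """
    if column not in table.data_columns:
        raise KeyError(f"no data column {column!r}")
    if pos_type is None and neg_type is None:
        raise ValueError("at least one control type is required")
    if orientation not in ("printed", "percent"):
        raise ValueError("orientation must be 'printed' or 'percent'")
    single = (pos_type is None) or (neg_type is None)
    ctrl = pos_type if pos_type is not None else neg_type

    x = table.records[column].astype(float)
    wt = table.records["well_type"]
    out = np.full(len(x), np.nan)
    flagged: list[int] = []
    for plate, idx in table.records.groupby("plate").groups.items():
        v = x.loc[idx]
        types = wt.loc[idx]

        def ctrl_mean(t: str) -> float:
            cv = v[(types == t) & v.notna()]
            if cv.empty:
                raise DegenerateDataError(
                    f"plate {plate} has no measured {t!r} control wells"
                )
            return float(cv.mean())

        pos = np.nan
        if single:
            m = ctrl_mean(ctrl)
            if m == 0:
                flagged.append(plate)
                continue
            score = (v - m) / m
        else:
            mp, mn = ctrl_mean(pos_type), ctrl_mean(neg_type)
            if mp == mn:
                flagged.append(plate)
                continue
            num = (v - mp) if orientation == "printed" else (v - mn)
            score = num / (mp - mn)
        out[table.records.index.get_indexer(idx)] = score
    if flagged:
        warnings.warn(
            f"plates {flagged}: degenerate control means, scores set to missing"
        )
    what = (
        f"fold change of {column} vs {ctrl}"
        if single
        else f"control score of {column} (pos={pos_type}, neg={neg_type}, {orientation})"
    )
    return table.with_column(f"{column}_ctrl", out, what)


@dataclass
class PolishResult:
    """Decomposition of a plate by two-way median polish.

    ``overall + row_effects[i] + col_effects[j] + residuals[i, j]``
    reconstructs the input on every non-missing cell.
    """

    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    iterations: int
    converged: bool

    def fitted(self) -> np.ndarray:
        return self.overall + self.row_effects[:, None] + self.col_effects[None, :]


def median_polish(
    matrix: np.ndarray, max_iter: int = 10, tol: float = 1e-6
) -> PolishResult:
    """Tukey's two-way median polish of one plate matrix (NaN = missing).

    Each sweep subtracts row medians from the residuals (folding them into
    the row effects), re-centres the column effects, then does the same for
    columns and row effects. Iteration stops when the largest absolute
    change in any effect falls below ``tol`` or after ``max_iter`` sweeps.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-D")
    if np.all(np.isnan(x)):
        raise DegenerateDataError("all cells missing")
    rows_with = np.sum(~np.all(np.isnan(x), axis=1))
    cols_with = np.sum(~np.all(np.isnan(x), axis=0))
    if rows_with < 2 or cols_with < 2:
        raise DegenerateDataError("median polish needs >= 2 rows and >= 2 columns of data")

    n_rows, n_cols = x.shape
    overall = 0.0
    row_eff = np.zeros(n_rows)
    col_eff = np.zeros(n_cols)
    resid = x.copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        delta_max = 0.0
        # rows first, then columns, re-centring the opposite effects each time
        rmed = _nanmedian(resid, axis=1)
        rmed = np.where(np.isnan(rmed), 0.0, rmed)
        resid -= rmed[:, None]
        row_eff += rmed
        delta_max = max(delta_max, float(np.max(np.abs(rmed))))
        cshift = float(_nanmedian(col_eff))
        col_eff -= cshift
        overall += cshift

        cmed = _nanmedian(resid, axis=0)
        cmed = np.where(np.isnan(cmed), 0.0, cmed)
        resid -= cmed[None, :]
        col_eff += cmed
        delta_max = max(delta_max, float(np.max(np.abs(cmed))))
        rshift = float(_nanmedian(row_eff))
        row_eff -= rshift
        overall += rshift

        if delta_max < tol:
            converged = True
            break
    return PolishResult(
        overall=overall,
        row_effects=row_eff,
        col_effects=col_eff,
        residuals=resid,
        iterations=iterations,
        converged=converged,
    )


def bscore(
    table: ScreenTable,
    column: str,
    max_iter: int = 10,
    tol: float = 1e-6,
    scaled_mad: bool = False,
) -> ScreenTable:
    """Derive a B-score column: median-polish residual over the plate MAD.

    For each plate, ``B_ij = R_ij / MAD_p`` where ``R`` are the polish
    residuals and ``MAD_p = median(|R_ij|)`` over measured wells. By
    default the plain median absolute residual is used; ``scaled_mad=True``
    multiplies it by the 1.4826 normal-consistency constant. A plate whose
    MAD is zero (e.g. a purely additive plate) yields missing B scores with
    a warning.
    """
    if column not in table.data_columns:
        raise KeyError(f"no data column {column!r}")
    geom = table.geometry
    out = np.full(len(table.records), np.nan)
    degenerate: list[int] = []
    for plate in table.plates:
        mat = table.plate_matrix(column, plate)
        if np.all(np.isnan(mat)):
            continue
        res = median_polish(mat, max_iter=max_iter, tol=tol)
        mad = float(_nanmedian(np.abs(res.residuals)))
        if scaled_mad:
            mad *= 1.4826
        if mad == 0:
            degenerate.append(plate)
            continue
        b = res.residuals / mad
        mask = table.records["plate"] == plate
        for pos, well in zip(np.flatnonzero(mask.to_numpy()), table.records.loc[mask, "well"]):
            i, j = geom.parse_well(well)
            out[pos] = b[i, j]
    if degenerate:
        warnings.warn(f"plates {degenerate}: zero residual MAD, B scores set to missing")
    return table.with_column(
        f"{column}_b",
        out,
        f"bscore({column}) max_iter={max_iter} tol={tol:g} scaled_mad={scaled_mad}",
    )
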