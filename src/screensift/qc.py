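"""Assay quality control: Z' factor, replicate agreement, well-type summaries.

The Z' factor quantifies the separation of positive and negative control
distributions,

    Z' = 1 - 3 * (sigma_p + sigma_n) / |mu_p - mu_n|,

where (mu, sigma) are the mean and SD of each control group. Z' = 1 is a
perfect assay, Z' <= 0 means the control bands overlap and the assay
cannot discriminate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import SAMPLE, ScreenTable
from .errors import DegenerateDataError

__all__ = ["zprime", "replicate_correlation", "quick_analysis", "QCReport"]


def zprime(pos_values, neg_values) -> float:
    """Z' factor of two control groups (Zhang et al. convention).

    Both groups need at least two values; equal group means leave the
    statistic undefined and raise :class:`DegenerateDataError`.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    pos, neg = pos[~np.isnan(pos)], neg[~np.isnan(neg)]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("zprime needs >= 2 values in each control group")
    mu_p, mu_n = pos.mean(), neg.mean()
    if mu_p == mu_n:
        raise DegenerateDataError("Z' undefined: control means are equal")
    sd_p, sd_n = pos.std(ddof=1), neg.std(ddof=1)
    return float(1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n))


class CorrelationResult(NamedTuple):
    r: float
    t: float
    p: float
    n: int


def replicate_correlation(table: ScreenTable, col_a: str, col_b: str) -> CorrelationResult:
    """Pearson correlation between two replicate columns, with its t test.

    Uses pairwise-complete wells; ``t = r * sqrt(n - 2) / sqrt(1 - r^2)``
    and the two-sided p-value come from the t distribution with n - 2
    degrees of freedom.
    """
    for c in (col_a, col_b):
        if c not in table.data_columns:
            raise KeyError(f"no data column {c!r}")
    a = table.records[col_a].to_numpy(dtype=float)
    b = table.records[col_b].to_numpy(dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    n = len(a)
    if n < 3:
        raise ValueError("replicate correlation needs >= 3 paired values")
    if a.std() == 0 or b.std() == 0:
        raise DegenerateDataError("correlation undefined: a column has zero variance")
    r = float(np.corrcoef(a, b)[0, 1])
    if abs(r) >= 1.0:
        t = np.inf if r > 0 else -np.inf
        p = 0.0
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
        p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, t=float(t), p=p, n=n)


@dataclass
class QCReport:
    """Per-well-type summary statistics plus a pairwise Z' table.

    ``summary`` has one row per well type present in the table (n, mean,
    SD, min, Q1, median, Q3, max; quartiles by linear interpolation).
    ``zprime_table`` has one row per ordered (positive-candidate,
    negative-candidate) pair of declared control types with >= 2 wells
    each; undefined pairs carry NaN and a note.
    """

    column: str
    summary: pd.DataFrame
    zprime_table: pd.DataFrame
    replicate: CorrelationResult | None = None
    notes: list[str] = field(default_factory=list)

    def zprime_of(self, pos: str, neg: str) -> float:
        sel = self.zprime_table[
            (self.zprime_table["positive"] == pos) & (self.zprime_table["negative"] == neg)
        ]
        if sel.empty:
            raise KeyError(f"no Z' entry for ({pos}, {neg})")
        return float(sel["zprime"].iloc[0])

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"Quick Analysis of column {self.column!r}", "", str(self.summary)]
        if not self.zprime_table.empty:
            lines += ["", "Pairwise Z':", str(self.zprime_table)]
        if self.replicate is not None:
            rep = self.replicate
            lines += ["", f"replicates: r={rep.r:.4f} t={rep.t:.2f} p={rep.p:.3g} n={rep.n}"]
        lines += [f"note: {n}" for n in self.notes]
        return "\n".join(lines)


def quick_analysis(table: ScreenTable, column: str) -> QCReport:
    """Summarize one data column by well type and score all control pairs.

    Emulates a first-look QC pass: box-plot statistics per well type
    (samples included) and a Z' factor for every ordered pair of distinct
    declared control types, so the user can judge which control pair
    separates best before picking a normalization.
    """
    if column not in table.data_columns:
        raise KeyError(f"no data column {column!r}")
    notes: list[str] = []
    rows = []
    present = [t for t in [SAMPLE, *table.control_types] if (table.records["well_type"] == t).any()]
    extra = sorted(set(table.records["well_type"]) - set(present))
    for wt in present + extra:
        v = table.values_of_type(wt, column)
        if len(v) == 0:
            rows.append({"well_type": wt, "n": 0})
            continue
        q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
        rows.append(
            {
                "well_type": wt,
                "n": len(v),
                "mean": v.mean(),
                "sd": v.std(ddof=1) if len(v) > 1 else np.nan,
                "min": v.min(),
                "q1": q1,
                "median": med,
                "q3": q3,
                "max": v.max(),
            }
        )
    summary = pd.DataFrame(rows).set_index("well_type")

    for ctrl in table.control_types:
        if (table.records["well_type"] == ctrl).sum() == 0:
            notes.append(f"declared control {ctrl!r} has no wells")

    zp_rows = []
    for pos in table.control_types:
        for neg in table.control_types:
            if pos == neg:
                continue
            pv = table.values_of_type(pos, column)
            nv = table.values_of_type(neg, column)
            if len(pv) < 2 or len(nv) < 2:
                continue
            try:
                z = zprime(pv, nv)
            except DegenerateDataError:
                z = np.nan
                notes.append(f"Z'({pos}, {neg}) undefined: equal control means")
            zp_rows.append({"positive": pos, "negative": neg, "zprime": z})
    zprime_table = pd.DataFrame(zp_rows, columns=["positive", "negative", "zprime"])
    return QCReport(column=column, summary=summary, zprime_table=zprime_table, notes=notes)
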