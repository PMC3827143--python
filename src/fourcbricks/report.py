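"""Expression summary statistics: AREL fold changes and Welch t-tests.

AREL (average relative expression level) values are qPCR summary statistics
per gene and condition.  This module reproduces the ratio arithmetic of the
expression table and, given replicate counts, a two-sample Welch t-test from
the summary statistics alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionRecord",
    "fold_change",
    "welch_t",
    "read_expression_table",
    "load_builtin_expression_table",
]


@dataclass(frozen=True)
class ExpressionRecord:
    gene: str
    ctrl_mean: float
    ctrl_sd: float
    case_mean: float
    case_sd: float
    category: str = "viewpoint"

    def __post_init__(self) -> None:
        for v in (self.ctrl_mean, self.ctrl_sd, self.case_mean, self.case_sd):
            if np.isfinite(v) and v < 0:
                raise ValueError("means and SDs must be non-negative")


def fold_change(record: ExpressionRecord) -> float:
    """case/control AREL ratio, half-up rounded to 3 decimals.

    Genes below the detection limit (missing or zero control mean) have no
    ratio and raise.
    """
    if not np.isfinite(record.ctrl_mean) or record.ctrl_mean <= 0:
        raise ValueError(
            f"{record.gene}: control mean below detection; no ratio defined"
        )
    if not np.isfinite(record.case_mean):
        raise ValueError(f"{record.gene}: case mean below detection")
    ratio = Decimal(repr(record.case_mean)) / Decimal(repr(record.ctrl_mean))
    return float(ratio.quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def welch_t(record: ExpressionRecord, n_ctrl: int, n_case: int) -> tuple[float, float]:
    """Welch two-sample t statistic and two-sided p from summary stats."""
    if n_ctrl < 2 or n_case < 2:
        raise ValueError("need at least 2 replicates per arm")
    if record.ctrl_sd == 0 and record.case_sd == 0:
        if record.ctrl_mean == record.case_mean:
            return 0.0, 1.0
        raise ValueError("zero variance in both arms with unequal means")
    res = stats.ttest_ind_from_stats(
        mean1=record.case_mean,
        std1=record.case_sd,
        nobs1=n_case,
        mean2=record.ctrl_mean,
        std2=record.ctrl_sd,
        nobs2=n_ctrl,
        equal_var=False,
    )
    return float(res.statistic), float(res.pvalue)


def read_expression_table(path) -> list[ExpressionRecord]:
    """Read a TSV of gene, category, ctrl_mean, ctrl_sd, case_mean, case_sd."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "ctrl_mean", "ctrl_sd", "case_mean", "case_sd"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ExpressionRecord(
                gene=row.gene,
                ctrl_mean=float(row.ctrl_mean),
                ctrl_sd=float(row.ctrl_sd),
                case_mean=float(row.case_mean),
                case_sd=float(row.case_sd),
                category=getattr(row, "category", "viewpoint"),
            )
        )
    return records


def load_builtin_expression_table() -> list[ExpressionRecord]:
    """The bundled WBS-vs-control lymphoblastoid AREL table."""
    ref = resources.files("fourcbricks.data").joinpath("wbs_expression.tsv")
    with resources.as_file(ref) as path:
        return read_expression_table(path)
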