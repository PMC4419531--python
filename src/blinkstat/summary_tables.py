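"""Group comparisons from printed summary statistics.

Published demographic/clinical tables report each variable as
"mean (SD)" per group with a two-sample t; this module recomputes those
t statistics from the summaries alone, using the pooled-variance
(Student) formula

    t = (mean2 - mean1) / (sp * sqrt(1/n1 + 1/n2)),
    sp^2 = ((n1-1) sd1^2 + (n2-1) sd2^2) / (n1 + n2 - 2)

with the sign convention second-listed group minus first, which matches
the published tables' sign pattern.  Two reference tables (demographic /
neuropsychological characteristics of the patient study and SPQ
characteristics of the schizotypy study) are shipped as CSV package
data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .analysis import TTestResult
from .errors import DataError

__all__ = [
    "GroupSummary",
    "t_from_summary",
    "reproduce_table",
    "load_packaged_table",
    "SUMMARY_CSV_COLUMNS",
    "format_p",
]

SUMMARY_CSV_COLUMNS = [
    "variable",
    "group1",
    "mean1",
    "sd1",
    "n1",
    "group2",
    "mean2",
    "sd2",
    "n2",
]


@dataclass(frozen=True)
class GroupSummary:
    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise DataError("group summaries need n >= 2")
        if self.sd < 0:
            raise DataError("sd must be non-negative")


def t_from_summary(g1: GroupSummary, g2: GroupSummary) -> TTestResult:
    """Pooled-variance two-sample t from group summaries (mean2 - mean1)."""
    df = g1.n + g2.n - 2
    sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
    if sp2 == 0:
        if g1.mean == g2.mean:
            return TTestResult(t=0.0, df=float(df), p=1.0)
        raise DataError("both SDs zero with unequal means: t is infinite")
    se = math.sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n))
    t = (g2.mean - g1.mean) / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=float(df), p=p)


def _has_second_group(row) -> bool:
    return not (
        pd.isna(row.mean2) or pd.isna(row.sd2) or pd.isna(row.n2)
    )


def reproduce_table(summaries) -> pd.DataFrame:
    """Recompute the t column of a summary table.

    ``summaries`` is a path or a data frame with the documented header.
    Rows that report only one group (e.g. symptom scores rated for
    patients only) are passed through untested; malformed rows get a
    row-level error message and processing continues.
    """
    if not isinstance(summaries, pd.DataFrame):
        summaries = pd.read_csv(summaries)
    for got, want in zip(summaries.columns, SUMMARY_CSV_COLUMNS):
        if got != want:
            raise DataError(
                f"summary CSV header must be {SUMMARY_CSV_COLUMNS}; "
                f"first bad column: {got!r}"
            )
    if len(summaries.columns) != len(SUMMARY_CSV_COLUMNS):
        raise DataError(f"summary CSV header must be exactly {SUMMARY_CSV_COLUMNS}")

    out = []
    for row in summaries.itertuples(index=False):
        rec = {"variable": row.variable, "tested": False,
               "t": np.nan, "df": np.nan, "p": np.nan, "error": ""}
        if _has_second_group(row):
            try:
                res = t_from_summary(
                    GroupSummary(str(row.group1), float(row.mean1),
                                 float(row.sd1), int(row.n1)),
                    GroupSummary(str(row.group2), float(row.mean2),
                                 float(row.sd2), int(row.n2)),
                )
                rec.update(tested=True, t=res.t, df=res.df, p=res.p)
            except (DataError, TypeError, ValueError) as exc:
                rec["error"] = str(exc)
        out.append(rec)
    return pd.DataFrame(out)


def load_packaged_table(name: str) -> pd.DataFrame:
    """Load one of the shipped summary tables.

    ``name`` is ``patients_demographics`` (patient vs control study) or
    ``spd_demographics`` (SPD vs non-SPD study).
    """
    fname = {
        "patients_demographics": "patients_demographics.csv",
        "spd_demographics": "spd_demographics.csv",
    }.get(name)
    if fname is None:
        raise DataError(f"unknown packaged table {name!r}")
    with resources.files("blinkstat.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh)


def format_p(p: float) -> str:
    """Render a p value to 3 significant figures, '<0.001' below that."""
    if p < 0.001:
        return "<0.001"
    return f"{p:.3g}"
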