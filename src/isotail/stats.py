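"""Two-group comparison of per-sample metrics (ratios, cpm, region counts).

The comparison statistic is the classical two-sample pooled-variance
(Student's) t-test with a two-sided p-value; Welch's unequal-variance
variant is available behind a flag.  Missing per-sample values (e.g. an
adenylation ratio undefined because the substrate species was not
observed) are dropped, never imputed as zero.  No multiple-testing
correction is applied by default; Benjamini-Hochberg adjustment across
miRNAs is available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ADJUST_NONE = "none"
ADJUST_BH = "benjamini_hochberg"


@dataclass
class TTestResult:
    t: float
    p: float
    df: float
    degenerate: bool = False
    reason: Optional[str] = None


def student_t(
    values_a: Sequence[float],
    values_b: Sequence[float],
    welch: bool = False,
) -> TTestResult:
    """Two-sample t-test (pooled variance by default; Welch optional).

    Requires >=2 finite values per group.  Zero pooled variance yields a
    degenerate result with undefined (NaN) t and p rather than a
    spuriously extreme statistic.
    """
    a = np.asarray([v for v in values_a if v is not None and math.isfinite(v)], float)
    b = np.asarray([v for v in values_b if v is not None and math.isfinite(v)], float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"need >=2 finite values per group, got {len(a)} and {len(b)}"
        )
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and not welch:
        return TTestResult(
            math.nan, math.nan, len(a) + len(b) - 2,
            degenerate=True, reason="zero pooled variance",
        )
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = float(getattr(res, "df", len(a) + len(b) - 2))
    return TTestResult(float(res.statistic), float(res.pvalue), df)


@dataclass
class GroupComparison:
    """One metric compared between two sample groups."""

    precursor_id: str
    arm_name: str
    metric: str
    group_a: str
    group_b: str
    values_a: tuple[float, ...]
    values_b: tuple[float, ...]
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    p_adjusted: Optional[float] = None
    skipped: bool = False
    skip_reason: Optional[str] = None


def compare_groups(
    metric_table: pd.DataFrame,
    metadata: Mapping[str, str],
    contrast: tuple[str, str],
    metric: Optional[str] = None,
    adjust: str = ADJUST_NONE,
    welch: bool = False,
) -> list[GroupComparison]:
    """Compare a per-sample metric between two groups, per (precursor, arm).

    ``metric_table`` has columns sample_id, precursor_id, arm_name,
    metric, value — one row per sample and measured quantity, with
    missing values absent or NaN.  ``metadata`` maps sample_id → group
    label; both contrast labels must occur in it.  Comparisons with fewer
    than two non-missing values in either group are returned skipped with
    a reason.  BH adjustment, when requested, runs across the
    non-skipped comparisons.
    """
    a_label, b_label = contrast
    groups = set(metadata.values())
    for label in contrast:
        if label not in groups:
            raise ValueError(f"contrast label {label!r} absent from metadata")
    missing = set(metric_table["sample_id"]) - set(metadata)
    if missing:
        raise ValueError(f"samples missing from metadata: {sorted(missing)}")

    table = metric_table
    if metric is not None:
        table = table[table["metric"] == metric]
    out: list[GroupComparison] = []
    for (pid, arm, met), sub in table.groupby(
        ["precursor_id", "arm_name", "metric"], sort=True
    ):
        vals = {"a": [], "b": []}
        for _, row in sub.iterrows():
            g = metadata[row["sample_id"]]
            v = row["value"]
            if v is None or (isinstance(v, float) and not math.isfinite(v)):
                continue
            if g == a_label:
                vals["a"].append(float(v))
            elif g == b_label:
                vals["b"].append(float(v))
        a, b = vals["a"], vals["b"]
        base = dict(
            precursor_id=pid, arm_name=arm, metric=met,
            group_a=a_label, group_b=b_label,
            values_a=tuple(a), values_b=tuple(b),
            n_a=len(a), n_b=len(b),
            mean_a=float(np.mean(a)) if a else math.nan,
            mean_b=float(np.mean(b)) if b else math.nan,
        )
        if len(a) < 2 or len(b) < 2:
            out.append(GroupComparison(
                **base, t_statistic=math.nan, p_value=math.nan,
                skipped=True,
                skip_reason=f"insufficient non-missing values (n_a={len(a)}, n_b={len(b)})",
            ))
            continue
        res = student_t(a, b, welch=welch)
        out.append(GroupComparison(
            **base, t_statistic=res.t, p_value=res.p,
            skipped=res.degenerate,
            skip_reason=res.reason,
        ))

    if adjust == ADJUST_BH:
        idx = [i for i, c in enumerate(out) if not c.skipped and math.isfinite(c.p_value)]
        if idx:
            padj = multipletests([out[i].p_value for i in idx], method="fdr_bh")[1]
            for i, p in zip(idx, padj):
                out[i].p_adjusted = float(p)
    elif adjust != ADJUST_NONE:
        raise ValueError(f"unknown adjust method {adjust!r}")
    return out


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Flatten comparisons into the tabular output written by the pipeline."""
    rows = []
    for c in comparisons:
        rows.append({
            "precursor_id": c.precursor_id,
            "arm_name": c.arm_name,
            "metric": c.metric,
            "group_a": c.group_a,
            "group_b": c.group_b,
            "n_a": c.n_a,
            "n_b": c.n_b,
            "mean_a": c.mean_a,
            "mean_b": c.mean_b,
            "t": c.t_statistic,
            "p": c.p_value,
            "p_adjusted": c.p_adjusted,
            "skipped": c.skipped,
            "skip_reason": c.skip_reason or "",
        })
    return pd.DataFrame(rows)
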