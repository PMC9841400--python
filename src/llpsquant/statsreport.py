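"""Statistical reporting layer: one-way ANOVA, two-tailed unpaired
Student's t-tests, significance-star annotation, and summary tables.

Star bins (half-open, consistent with "ns >= 0.05"):
    p >= 0.05          ns
    0.01 <= p < 0.05   *
    0.001 <= p < 0.01  **
    0.0001 <= p < 0.001 ***
    p < 0.0001         ****

The default t-test is the pooled-variance Student's test; Welch's
unequal-variance variant is available behind a flag.  No multiple-testing
correction is applied by default (a Bonferroni option exists).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class StarAnnotation:
    p_value: float
    label: str


def one_way_anova(groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F-test with (k-1, N-k) degrees of freedom."""
    if isinstance(groups, Mapping):
        samples = [np.asarray(v, dtype=np.float64) for v in groups.values()]
    else:
        samples = [np.asarray(v, dtype=np.float64) for v in groups]
    if len(samples) < 2:
        raise ValueError("need >= 2 groups")
    n_total = sum(len(s) for s in samples)
    if n_total <= len(samples):
        raise ValueError("total observations must exceed the number of groups")
    if all(np.ptp(s) == 0 for s in samples):
        raise ValueError("zero within-group variance in every group; F undefined")
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)


def t_test_two_tailed(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> tuple[float, float]:
    """Unpaired two-sided t-test (pooled-variance Student by default)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means; t undefined")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def star_label(p: float) -> StarAnnotation:
    """Map a p-value onto the ns/*/**/***/**** annotation bins."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p >= 0.05:
        label = "ns"
    elif p >= 0.01:
        label = "*"
    elif p >= 0.001:
        label = "**"
    elif p >= 0.0001:
        label = "***"
    else:
        label = "****"
    return StarAnnotation(p_value=float(p), label=label)


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Optional Bonferroni adjustment (off by default in all reports)."""
    m = len(p_values)
    return [min(1.0, float(p) * m) for p in p_values]


def summarize_groups(
    df: pd.DataFrame,
    group_col: str,
    value_col: str,
    control: str | float | None = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-group mean ± SD with t-tests and stars against a control group."""
    labels = list(pd.unique(df[group_col]))
    groups = {g: df.loc[df[group_col] == g, value_col].to_numpy(dtype=float) for g in labels}
    if control is None:
        control = labels[0]
    rows = []
    for g in labels:
        v = groups[g]
        row = {
            "group": g,
            "n": len(v),
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if len(v) > 1 else np.nan,
        }
        if g != control and len(v) >= 2 and len(groups[control]) >= 2:
            t, p = t_test_two_tailed(v, groups[control], welch=welch)
            row.update(t=t, p=p, stars=star_label(p).label)
        else:
            row.update(t=np.nan, p=np.nan, stars="")
        rows.append(row)
    return pd.DataFrame(rows)


def write_summary(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each named summary table as CSV with a deterministic column order."""
    out_dir = Path(out_dir)
    if not tables:
        print("write_summary: no tables supplied; nothing written")
        return []
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        path = out_dir / f"{name}.csv"
        tables[name].to_csv(path, index=False)
        written.append(path)
    return written
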