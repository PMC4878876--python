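"""Group-comparison arithmetic and summary tables.

The native statistic is the unpaired difference of group means with SEM
propagation in quadrature:

    mu = mean_A - mean_B,   SEM = sqrt(SEM_A^2 + SEM_B^2).

Hypothesis tests (ANOVA families, t-tests) are standard machinery and are
delegated to scipy behind :func:`welch_ttest`; they are not re-derived here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidN, MissingMetric


@dataclass
class GroupDifference:
    """Unpaired difference of two group means with propagated SEM."""

    mean_diff: float
    sem_diff: float
    n_A: int
    n_B: int
    label_A: str = "A"
    label_B: str = "B"


def sem(values: Sequence[float] | np.ndarray) -> float:
    """Standard error of the mean (sample SD / sqrt(n))."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InvalidN("SEM requires n >= 2")
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def unpaired_difference(
    mean_A: float, sem_A: float, n_A: int,
    mean_B: float, sem_B: float, n_B: int,
    label_A: str = "A", label_B: str = "B",
) -> GroupDifference:
    """mu = mean_A - mean_B with SEMs combined in quadrature.

    For independent groups the variance of the difference of means is the
    sum of the variances, hence SEM_diff = sqrt(SEM_A^2 + SEM_B^2).
    """
    if n_A < 2 or n_B < 2:
        raise InvalidN("unpaired difference requires n >= 2 per group")
    if sem_A < 0 or sem_B < 0:
        raise ValueError("SEMs must be non-negative")
    return GroupDifference(
        mean_diff=mean_A - mean_B,
        sem_diff=float(np.sqrt(sem_A ** 2 + sem_B ** 2)),
        n_A=n_A, n_B=n_B, label_A=label_A, label_B=label_B,
    )


def group_summary(
    cohort: pd.DataFrame,
    metric: str,
    by: Sequence[str] = ("sex", "genotype", "condition"),
) -> pd.DataFrame:
    """Per-group mean, SEM and n of one metric column.

    ``cohort`` holds one row per cell (and condition, if present); grouping
    columns missing from the frame are dropped from ``by``.  Rows are sorted
    by the grouping labels for deterministic output.
    """
    if metric not in cohort.columns:
        raise MissingMetric(f"metric {metric!r} not in cohort table")
    keys = [k for k in by if k in cohort.columns]
    if not keys:
        raise MissingMetric("no grouping columns present")
    rows = []
    for labels, sub in cohort.groupby(keys, sort=True, dropna=False):
        vals = sub[metric].dropna().to_numpy(dtype=float)
        if vals.size < 2:
            raise InvalidN(
                f"group {labels!r} has {vals.size} values for {metric!r} (need >= 2)")
        rows.append(dict(zip(keys, labels if isinstance(labels, tuple) else (labels,)),
                         metric=metric, mean=float(np.mean(vals)),
                         sem=sem(vals), n=int(vals.size)))
    return pd.DataFrame(rows)


def welch_ttest(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Welch two-sample t-test (delegated to scipy); returns (t, p)."""
    from scipy import stats as sps

    res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)
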