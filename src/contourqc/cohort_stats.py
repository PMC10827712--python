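"""Cohort-level analyses of segmentation style and quality.

Covers the statistics used to compare annotators and to filter training
cohorts by segmentation quality:

* quantile partitioning of a cohort by edge roughness (or length) into the
  lowest quartile Q1, highest quartile Q4, and the middle 50% — the
  quality-filtering design that selects the cleanest quartile of cases;
* Dunn's test, the rank-based pairwise multiple comparison performed after
  a Kruskal–Wallis rejection, with tie correction;
* Fisher's exact test on 2x2 outlier-proportion tables;
* two-sample t comparisons (Welch by default).

The significance convention throughout is two-sided with alpha = 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortRecord",
    "PairwiseTestResult",
    "quantile_split",
    "dunn_test",
    "fisher_exact",
    "two_sample_t",
    "read_cohort_csv",
    "write_cohort_csv",
    "annotator_summary",
    "SIGNIFICANCE_LEVEL",
]

SIGNIFICANCE_LEVEL = 0.01


@dataclass
class CohortRecord:
    """One case: annotator, measured length, roughness, optional Dice."""

    case_id: str
    annotator: str
    length_cm: float
    roughness: float
    dice: float | None = None

    def __post_init__(self) -> None:
        if self.length_cm <= 0:
            raise ValueError(f"length_cm must be > 0, got {self.length_cm}")
        if self.roughness < 0:
            raise ValueError(f"roughness must be >= 0, got {self.roughness}")
        if self.dice is not None and not (0.0 <= self.dice <= 1.0):
            raise ValueError(f"dice must be in [0, 1], got {self.dice}")


@dataclass
class PairwiseTestResult:
    """Dunn pairwise z/p matrices with the global Kruskal–Wallis gate."""

    labels: list[str]
    z_matrix: np.ndarray
    p_matrix: np.ndarray
    kruskal_h: float
    kruskal_p: float
    adjusted: bool = False

    def p_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.p_matrix, index=self.labels, columns=self.labels)
        np.fill_diagonal(df.values, np.nan)
        return df


# ---------------------------------------------------------------------------
# Quantile filtering


def quantile_split(
    records: Sequence[CohortRecord], key: str = "roughness", mode: str = "Q1"
) -> list[CohortRecord]:
    """Select the Q1 / Q4 / middle50 branch of a cohort by a quality key.

    Percentiles use linear interpolation between order statistics.  Q1
    returns records with key <= the 25th percentile, Q4 those with key >=
    the 75th, and middle50 the strict interior; assignment is evaluated in
    the fixed order Q1 -> Q4 -> middle50 so tied records fall on one side
    and the three branches always partition the input.
    """
    if not records:
        raise ValueError("records must be non-empty")
    if key not in ("roughness", "length_cm"):
        raise ValueError(f"key must be 'roughness' or 'length_cm', got {key!r}")
    if mode not in ("Q1", "Q4", "middle50"):
        raise ValueError(f"mode must be Q1, Q4 or middle50, got {mode!r}")
    values = np.array([getattr(r, key) for r in records], dtype=float)
    p25, p75 = np.percentile(values, [25, 75])  # linear interpolation
    if mode == "Q1":
        sel = values <= p25
    elif mode == "Q4":
        sel = (values >= p75) & ~(values <= p25)
    else:
        sel = ~(values <= p25) & ~((values >= p75) & ~(values <= p25))
    return [r for r, keep in zip(records, sel) if keep]


# ---------------------------------------------------------------------------
# Dunn's test


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def dunn_test(
    groups: Sequence[tuple[str, Sequence[float]]], holm: bool = False
) -> PairwiseTestResult:
    """Dunn's pairwise multiple comparison after Kruskal–Wallis.

    Pooled observations are ranked with mid-ranks for ties; for each pair
    (i, j) the z statistic is

        z_ij = (Rbar_i - Rbar_j) / sqrt( (N(N+1)/12 - T/(12(N-1)))
                                         * (1/n_i + 1/n_j) )

    with T = sum(t^3 - t) over tie groups, and the two-sided p comes from
    the standard normal.  P-values are unadjusted by default; ``holm=True``
    applies a Holm step-down correction across the pairs.
    """
    if len(groups) < 2:
        raise ValueError("dunn_test requires at least 2 groups")
    labels = [str(lbl) for lbl, _ in groups]
    data = [np.asarray(vals, dtype=float) for _, vals in groups]
    if any(len(d) < 2 for d in data):
        raise ValueError("every group needs at least 2 observations")
    pooled = np.concatenate(data)
    if np.ptp(pooled) == 0:
        raise ValueError("all observations are identical across all groups")

    kw_h, kw_p = stats.kruskal(*data)

    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    n = np.array([len(d) for d in data])
    edges = np.concatenate([[0], np.cumsum(n)])
    mean_ranks = np.array([ranks[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])

    N = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))

    k = len(groups)
    z = np.zeros((k, k))
    p = np.ones((k, k))
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    raw = np.empty(len(pairs))
    for idx, (i, j) in enumerate(pairs):
        se = np.sqrt(var * (1.0 / n[i] + 1.0 / n[j]))
        zij = (mean_ranks[i] - mean_ranks[j]) / se
        z[i, j], z[j, i] = zij, -zij
        raw[idx] = 2.0 * stats.norm.sf(abs(zij))
    if holm:
        raw = _holm(raw)
    for idx, (i, j) in enumerate(pairs):
        p[i, j] = p[j, i] = min(1.0, raw[idx])
    return PairwiseTestResult(
        labels=labels,
        z_matrix=z,
        p_matrix=p,
        kruskal_h=float(kw_h),
        kruskal_p=float(kw_p),
        adjusted=holm,
    )


# ---------------------------------------------------------------------------
# Fisher exact and t tests


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    The two-sided p sums the hypergeometric probabilities of every table
    with the same margins whose probability does not exceed the observed
    table's.  Both margins must be positive.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("both margins must be positive")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def two_sample_t(
    a: Sequence[float], b: Sequence[float], equal_var: bool = False
) -> tuple[float, float]:
    """Two-sample t test: Welch by default, pooled when ``equal_var``.

    Returns (t statistic, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
        raise ValueError("zero variance in both samples")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Cohort table I/O and summaries

_COLUMNS = ["case_id", "annotator", "length_cm", "roughness", "dice"]


def read_cohort_csv(path: str | Path) -> list[CohortRecord]:
    """Read a cohort manifest CSV (case_id, annotator, length_cm, roughness[, dice])."""
    df = pd.read_csv(path)
    missing = set(_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        dice = getattr(row, "dice", None)
        if dice is not None and pd.isna(dice):
            dice = None
        records.append(
            CohortRecord(
                case_id=str(row.case_id),
                annotator=str(row.annotator),
                length_cm=float(row.length_cm),
                roughness=float(row.roughness),
                dice=None if dice is None else float(dice),
            )
        )
    return records


def write_cohort_csv(records: Sequence[CohortRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "case_id": r.case_id,
                "annotator": r.annotator,
                "length_cm": r.length_cm,
                "roughness": r.roughness,
                "dice": r.dice,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def annotator_summary(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Per-annotator mean ± SD of roughness and length, with case counts."""
    if not records:
        raise ValueError("records must be non-empty")
    df = pd.DataFrame(
        [
            {"annotator": r.annotator, "length_cm": r.length_cm, "roughness": r.roughness}
            for r in records
        ]
    )
    out = df.groupby("annotator").agg(
        n=("roughness", "size"),
        roughness_mean=("roughness", "mean"),
        roughness_sd=("roughness", "std"),
        length_mean_cm=("length_cm", "mean"),
        length_sd_cm=("length_cm", "std"),
    )
    return out.reset_index()
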