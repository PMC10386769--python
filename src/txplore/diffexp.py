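"""Group-vs-group differential expression.

Per-gene tests are the two classical location tests used throughout bulk
RNA-seq exploration: Welch's unequal-variance t-test and the Wilcoxon
rank-sum (Mann-Whitney) test. Effect size is the log2 ratio of group
means with a shared pseudocount. Multiple testing is controlled by the
Benjamini-Hochberg step-up procedure.

The Wilcoxon exact null distribution (used whenever both groups have at
most ``EXACT_WILCOXON_MAX`` samples and the pooled data are untied) is
computed by dynamic programming over rank-sum counts — identical to full
enumeration of label assignments, at polynomial cost. Ties always route
to the tie-corrected normal approximation with continuity correction.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    COUNT_UNIT,
    DataError,
    ExpressionMatrix,
    SampleGroups,
)

__all__ = [
    "log2_fold_change",
    "welch_t_test",
    "wilcoxon_rank_sum",
    "benjamini_hochberg",
    "run_differential_expression",
    "DEResult",
    "EXACT_WILCOXON_MAX",
]

#: Largest per-group size for which the exact Wilcoxon null is used.
EXACT_WILCOXON_MAX = 25


def log2_fold_change(values_a, values_b, pseudocount: float = 1.0) -> float:
    """log2((mean_A + pseudocount) / (mean_B + pseudocount))."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("fold change requires non-empty groups")
    if pseudocount <= 0:
        raise DataError("pseudocount must be positive")
    return float(np.log2((a.mean() + pseudocount) / (b.mean() + pseudocount)))


def welch_t_test(values_a, values_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test.

    Returns ``(t, satterthwaite_df, two_sided_p)``. Degenerate inputs
    with both sample variances zero use documented conventions: equal
    means give ``(0, df, 1)``; unequal means give p = 0 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    n_a, n_b = a.size, b.size
    if n_a < 2 or n_b < 2:
        raise DataError("Welch's t-test requires at least 2 samples per group")
    var_a = a.var(ddof=1)
    var_b = b.var(ddof=1)
    diff = a.mean() - b.mean()
    if var_a == 0.0 and var_b == 0.0:
        df = float(n_a + n_b - 2)
        if diff == 0.0:
            return 0.0, df, 1.0
        warnings.warn(
            "both group variances are zero with unequal means; p set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.copysign(math.inf, diff), df, 0.0
    se2_a = var_a / n_a
    se2_b = var_b / n_b
    t = diff / math.sqrt(se2_a + se2_b)
    df = (se2_a + se2_b) ** 2 / (
        se2_a**2 / (n_a - 1) + se2_b**2 / (n_b - 1)
    )
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), min(p, 1.0)


@lru_cache(maxsize=64)
def _rank_sum_counts(n: int, total: int) -> np.ndarray:
    """Number of size-``n`` subsets of ranks 1..``total`` per rank sum.

    Index ``w`` of the returned array counts subsets summing to ``w``.
    Counts fit exactly in int64 for total <= 50 (max C(50,25) ~ 1.3e14).
    """
    max_sum = total * (total + 1) // 2
    counts = np.zeros((n + 1, max_sum + 1), dtype=np.int64)
    counts[0, 0] = 1
    for rank in range(1, total + 1):
        # iterate subset sizes downward so each rank is used at most once
        upper = min(rank * (2 * total - rank + 1) // 2, max_sum)
        for k in range(min(n, rank), 0, -1):
            counts[k, rank:upper + 1] += counts[k - 1, : upper + 1 - rank]
    return counts[n]


def _exact_rank_sum_p(w: float, n_a: int, total: int) -> float:
    """Exact two-sided p for rank-sum ``w`` of group A (no ties)."""
    counts = _rank_sum_counts(n_a, total)
    total_subsets = counts.sum()
    w_int = int(round(w))
    lower = counts[: w_int + 1].sum() / total_subsets
    upper = counts[w_int:].sum() / total_subsets
    # null is symmetric without ties: double the smaller tail
    return min(1.0, 2.0 * min(lower, upper))


def wilcoxon_rank_sum(values_a, values_b) -> tuple[float, float]:
    """Wilcoxon rank-sum test; returns ``(W_A, two_sided_p)``.

    ``W_A`` is the sum of mid-ranks of group A in the pooled sample.
    Exact enumeration-equivalent p when both groups have at most
    ``EXACT_WILCOXON_MAX`` samples and there are no ties; otherwise the
    normal approximation with tie and continuity corrections. A pooled
    sample with zero rank variance (all values tied) returns p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    n_a, n_b = a.size, b.size
    if n_a == 0 or n_b == 0:
        raise DataError("rank-sum test requires non-empty groups")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n_a].sum())
    total = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    if not has_ties and n_a <= EXACT_WILCOXON_MAX and n_b <= EXACT_WILCOXON_MAX:
        return w, _exact_rank_sum_p(w, n_a, total)
    mean_w = n_a * (total + 1) / 2.0
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var_w = n_a * n_b / 12.0 * ((total + 1) - tie_term / (total * (total - 1)))
    if var_w <= 0.0:
        return w, 1.0
    # continuity correction: shrink the deviation by 0.5 toward the mean
    deviation = abs(w - mean_w) - 0.5
    z = max(deviation, 0.0) / math.sqrt(var_w)
    p = 2.0 * float(stats.norm.sf(z))
    return w, min(1.0, p)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise DataError("p-values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class DEResult:
    """Per-gene differential expression table plus comparison metadata.

    ``table`` columns: gene, mean_a, mean_b, log2_fold_change, statistic,
    p_value, q_value — one row per retained gene, in matrix order.
    Volcano thresholds are advisory metadata, never applied as filters.
    """

    table: pd.DataFrame
    group_a: str
    group_b: str
    test: str
    pseudocount: float
    n_a: int
    n_b: int
    n_dropped_all_zero: int
    unit: str
    volcano_log2fc_threshold: float = 1.0
    volcano_q_threshold: float = 0.05
    extra: dict = field(default_factory=dict)


def run_differential_expression(
    matrix: ExpressionMatrix,
    groups: SampleGroups,
    group_a: str,
    group_b: str,
    test: str = "wilcoxon",
    pseudocount: float = 1.0,
) -> DEResult:
    """Per-gene two-group comparison on a normalized matrix.

    Counts are refused (normalize first). Genes with zero expression in
    every sample of both groups are dropped and counted. q-values are BH
    over all genes actually tested.
    """
    if matrix.unit == COUNT_UNIT:
        raise DataError(
            "differential expression requires normalized values; run cpm/rpkm/tpm"
        )
    if test not in ("welch", "wilcoxon"):
        raise DataError(f"unknown test {test!r}; expected 'welch' or 'wilcoxon'")
    if group_a == group_b:
        raise DataError("group_a and group_b must differ")
    samples_a = groups[group_a]
    samples_b = groups[group_b]
    missing = [
        s for s in samples_a + samples_b if s not in set(matrix.sample_ids)
    ]
    if missing:
        raise DataError(f"samples absent from matrix: {missing[:20]}")
    if test == "welch" and (len(samples_a) < 2 or len(samples_b) < 2):
        raise DataError("Welch's t-test needs >= 2 samples in each group")
    sub_a = matrix.data[samples_a].to_numpy(dtype=float)
    sub_b = matrix.data[samples_b].to_numpy(dtype=float)
    nonzero = (sub_a != 0).any(axis=1) | (sub_b != 0).any(axis=1)
    n_dropped = int((~nonzero).sum())
    genes = [g for g, keep in zip(matrix.gene_ids, nonzero) if keep]
    sub_a, sub_b = sub_a[nonzero], sub_b[nonzero]
    if sub_a.shape[0] == 0:
        raise DataError("no genes with nonzero expression in either group")
    records = []
    for gene, row_a, row_b in zip(genes, sub_a, sub_b):
        fc = log2_fold_change(row_a, row_b, pseudocount)
        if test == "welch":
            stat, _df, p = welch_t_test(row_a, row_b)
        else:
            stat, p = wilcoxon_rank_sum(row_a, row_b)
        records.append((gene, row_a.mean(), row_b.mean(), fc, stat, p))
    table = pd.DataFrame.from_records(
        records,
        columns=["gene", "mean_a", "mean_b", "log2_fold_change", "statistic", "p_value"],
    )
    table["q_value"] = benjamini_hochberg(table["p_value"].to_numpy())
    return DEResult(
        table=table,
        group_a=group_a,
        group_b=group_b,
        test=test,
        pseudocount=pseudocount,
        n_a=len(samples_a),
        n_b=len(samples_b),
        n_dropped_all_zero=n_dropped,
        unit=matrix.unit,
    )
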