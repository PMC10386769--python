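"""One-vs-rest marker-gene discovery.

A good marker for a sample group is a gene with high expression in that
group and low, *stable* expression everywhere: maximal fold change
toward the target group and minimal within-group coefficient of
variation (CV) in every group. The default ranking is an additive rank
combination — rank of descending log2 fold change (target vs the union
of all other groups) plus rank of ascending maximal within-group CV —
with lexicographic gene-id tie-breaking so output is fully
deterministic. Welch / Wilcoxon p-value orderings and a three-way rank
combination are available as alternatives.

CV is computed on the normalized (non-log) scale with the n-1 standard
deviation; an all-zero gene has CV 0 by convention (nonnegative values
with mean zero force sd zero).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import COUNT_UNIT, DataError, ExpressionMatrix, SampleGroups
from .diffexp import log2_fold_change, welch_t_test, wilcoxon_rank_sum, benjamini_hochberg

__all__ = [
    "coefficient_of_variation",
    "discover_biomarkers",
    "one_vs_rest_panel",
    "BiomarkerResult",
    "BiomarkerPanel",
]

METHODS = ("cv_fc", "welch", "wilcoxon", "combined")


def coefficient_of_variation(values) -> float:
    """Sample standard deviation (n-1) over mean; 0 for all-zero input."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DataError("coefficient of variation requires >= 2 values")
    mean = v.mean()
    if mean == 0.0:
        return 0.0
    return float(v.std(ddof=1) / mean)


def _ordinal_ranks(keys: list[tuple]) -> np.ndarray:
    """1-based ranks for sort keys; ties already broken inside the keys."""
    order = sorted(range(len(keys)), key=keys.__getitem__)
    ranks = np.empty(len(keys), dtype=np.int64)
    for rank, idx in enumerate(order, start=1):
        ranks[idx] = rank
    return ranks


@dataclass
class BiomarkerResult:
    """Ranked marker table for one target group.

    ``table`` columns: gene, log2_fold_change, cv_target, cv_rest_max,
    cv_max, rank_fc, rank_cv, (p_value, q_value, rank_p for test-based
    methods), combined_rank, eligible — sorted by the method's final
    ordering. ``top_genes`` lists the top-k *eligible* (up in target)
    genes in that order.
    """

    target: str
    method: str
    table: pd.DataFrame
    top_genes: list[str]
    pseudocount: float
    low_separation: bool
    extra: dict = field(default_factory=dict)


def discover_biomarkers(
    matrix: ExpressionMatrix,
    groups: SampleGroups,
    target: str,
    method: str = "cv_fc",
    pseudocount: float = 1.0,
    top_k: int | None = None,
) -> BiomarkerResult:
    """Rank genes as candidate markers of ``target`` versus all other groups."""
    if matrix.unit == COUNT_UNIT:
        raise DataError("biomarker discovery requires normalized values")
    if method not in METHODS:
        raise DataError(f"unknown method {method!r}; expected one of {METHODS}")
    target_samples = groups[target]
    rest_by_group = groups.rest_of(target)
    if not rest_by_group:
        raise DataError("biomarker discovery needs at least one non-target group")
    rest_samples = [s for ss in rest_by_group.values() for s in ss]
    missing = [
        s
        for s in target_samples + rest_samples
        if s not in set(matrix.sample_ids)
    ]
    if missing:
        raise DataError(f"samples absent from matrix: {missing[:20]}")
    needs_cv = method in ("cv_fc", "combined")
    if needs_cv:
        small = [
            lb
            for lb, ss in [(target, target_samples), *rest_by_group.items()]
            if len(ss) < 2
        ]
        if small:
            raise DataError(
                f"CV-based ranking needs >= 2 samples per group; too small: {small}"
            )
    if method in ("welch", "combined") and (
        len(target_samples) < 2 or len(rest_samples) < 2
    ):
        raise DataError("Welch-based ranking needs >= 2 samples per side")

    data_t = matrix.data[target_samples].to_numpy(dtype=float)
    data_r = matrix.data[rest_samples].to_numpy(dtype=float)
    genes = matrix.gene_ids
    n = len(genes)

    fc = np.array(
        [log2_fold_change(a, b, pseudocount) for a, b in zip(data_t, data_r)]
    )
    cv_target = np.array([coefficient_of_variation(row) for row in data_t]) \
        if len(target_samples) >= 2 else np.full(n, np.nan)
    group_cvs = []
    for lb, ss in rest_by_group.items():
        if len(ss) >= 2:
            block = matrix.data[ss].to_numpy(dtype=float)
            group_cvs.append([coefficient_of_variation(row) for row in block])
    cv_rest_max = (
        np.max(np.array(group_cvs), axis=0) if group_cvs else np.full(n, np.nan)
    )
    cv_max = np.fmax(cv_target, cv_rest_max)

    columns: dict[str, np.ndarray | list] = {
        "gene": genes,
        "log2_fold_change": fc,
        "cv_target": cv_target,
        "cv_rest_max": cv_rest_max,
        "cv_max": cv_max,
    }
    rank_fc = _ordinal_ranks([(-f, g) for f, g in zip(fc, genes)])
    columns["rank_fc"] = rank_fc
    rank_cv = None
    if needs_cv:
        rank_cv = _ordinal_ranks([(c, g) for c, g in zip(cv_max, genes)])
        columns["rank_cv"] = rank_cv
    rank_p = None
    if method in ("welch", "wilcoxon", "combined"):
        p_values = np.empty(n)
        for i, (a, b) in enumerate(zip(data_t, data_r)):
            if method == "wilcoxon":
                _, p = wilcoxon_rank_sum(a, b)
            else:
                _, _, p = welch_t_test(a, b)
            p_values[i] = p
        columns["p_value"] = p_values
        columns["q_value"] = benjamini_hochberg(p_values)
        rank_p = _ordinal_ranks([(p, g) for p, g in zip(p_values, genes)])
        columns["rank_p"] = rank_p

    if method == "cv_fc":
        combined = rank_fc + rank_cv
    elif method == "combined":
        combined = rank_fc + rank_cv + rank_p
    else:
        combined = None
    if combined is not None:
        columns["combined_rank"] = combined
        sort_keys = [(int(c), g) for c, g in zip(combined, genes)]
    else:
        sort_keys = [
            (p, -abs(f), g)
            for p, f, g in zip(columns["p_value"], fc, genes)
        ]
    columns["eligible"] = fc > 0

    table = pd.DataFrame(columns)
    final_order = sorted(range(n), key=sort_keys.__getitem__)
    table = table.iloc[final_order].reset_index(drop=True)

    eligible_sorted = table.loc[table["eligible"], "gene"].tolist()
    top_genes = eligible_sorted if top_k is None else eligible_sorted[:top_k]
    low_separation = not bool((np.abs(fc) >= 1.0).any())
    return BiomarkerResult(
        target=target,
        method=method,
        table=table,
        top_genes=top_genes,
        pseudocount=pseudocount,
        low_separation=low_separation,
    )


@dataclass
class BiomarkerPanel:
    """One-vs-rest marker results for every group plus their union panel.

    ``panel`` maps each union-panel gene to its best (lowest) position
    and the group where it achieved it — the gene list used for
    marker-based heatmaps and embeddings.
    """

    results: dict[str, BiomarkerResult]
    panel: pd.DataFrame  # columns: gene, best_group, best_position

    @property
    def panel_genes(self) -> list[str]:
        return self.panel["gene"].tolist()


def one_vs_rest_panel(
    matrix: ExpressionMatrix,
    groups: SampleGroups,
    method: str = "cv_fc",
    pseudocount: float = 1.0,
    top_k: int | None = 20,
) -> BiomarkerPanel:
    """Run ``discover_biomarkers`` for every group and merge the winners."""
    if len(groups.labels) < 2:
        raise DataError("a one-vs-rest panel needs at least 2 groups")
    results = {
        label: discover_biomarkers(
            matrix, groups, label, method=method, pseudocount=pseudocount, top_k=top_k
        )
        for label in groups.labels
    }
    best: dict[str, tuple[int, str]] = {}
    for label in groups.labels:  # stable group order decides equal positions
        for pos, gene in enumerate(results[label].top_genes, start=1):
            if gene not in best or pos < best[gene][0]:
                best[gene] = (pos, label)
    rows = sorted(
        ((gene, grp, pos) for gene, (pos, grp) in best.items()),
        key=lambda r: (r[2], r[1], r[0]),
    )
    panel = pd.DataFrame(rows, columns=["gene", "best_group", "best_position"])
    return BiomarkerPanel(results=results, panel=panel)
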