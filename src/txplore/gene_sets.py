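"""Gene-set statistics: pre-ranked GSEA, over-representation, and
set-level expression comparison.

Pre-ranked GSEA follows the standard weighted Kolmogorov-Smirnov
running-sum construction: walking the ranked list, member genes push the
sum up by |r|^w normalized over members, non-members pull it down by
1/(N - n_set); the enrichment score (ES) is the signed extreme of the
walk. The permutation null samples, independently per set, random
member positions of the observed set size from the ranked statistics;
each set's random substream is keyed by its name, so p-values are
invariant to set-member and collection ordering. The p-value resolution
floor is 1/(n_permutations + 1).

Over-representation uses the hypergeometric upper tail; the set-level
comparison reduces each member gene to its within-group mean and applies
the Wilcoxon rank-sum test across the two per-gene mean vectors.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    COUNT_UNIT,
    DataError,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    SampleGroups,
)
from .diffexp import DEResult, benjamini_hochberg, wilcoxon_rank_sum

__all__ = [
    "RankedList",
    "make_ranked_list",
    "enrichment_score",
    "EnrichmentProfile",
    "preranked_gsea",
    "GSEAResult",
    "overrepresentation_test",
    "ORAResult",
    "compare_set_expression",
    "SetComparisonResult",
]


@dataclass
class RankedList:
    """Genes sorted by a real-valued statistic, descending; ties broken
    by ascending gene identifier."""

    genes: list[str]
    stats: np.ndarray
    n_dropped_nonfinite: int = 0

    def __post_init__(self) -> None:
        self.stats = np.asarray(self.stats, dtype=float)
        if len(self.genes) != self.stats.size:
            raise DataError("ranked list genes and statistics differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise DataError("ranked list contains duplicate gene identifiers")
        if not np.isfinite(self.stats).all():
            raise DataError("ranked list statistics must be finite")
        if (np.diff(self.stats) > 0).any():
            raise DataError("ranked list statistics must be nonincreasing")

    def __len__(self) -> int:
        return len(self.genes)


def make_ranked_list(de: DEResult, statistic: str = "log2_fold_change") -> RankedList:
    """Build a pre-ranked gene list from a differential expression table."""
    if statistic not in de.table.columns:
        raise DataError(f"statistic {statistic!r} not in DE table")
    if len(de.table) == 0:
        raise DataError("DE result is empty")
    genes = de.table["gene"].tolist()
    values = de.table[statistic].to_numpy(dtype=float)
    finite = np.isfinite(values)
    n_dropped = int((~finite).sum())
    pairs = sorted(
        zip(np.asarray(genes, dtype=object)[finite], values[finite]),
        key=lambda gv: (-gv[1], gv[0]),
    )
    return RankedList(
        genes=[g for g, _ in pairs],
        stats=np.array([v for _, v in pairs]),
        n_dropped_nonfinite=n_dropped,
    )


@dataclass
class EnrichmentProfile:
    es: float
    running_sum: np.ndarray
    leading_edge: list[str]
    hit_positions: np.ndarray  # 0-based positions of members in the list


def _signed_extreme(running: np.ndarray) -> float:
    """Signed maximal deviation of a running sum from zero.

    When the largest positive and negative deviations tie in magnitude,
    the sign of the mean running-sum value decides (positive mean picks
    the positive extreme). This tie rule is itself antisymmetric, so ES
    negates exactly under statistic negation plus list reversal.
    """
    hi = float(running.max())
    lo = float(running.min())
    # tolerance absorbs summation-order float noise so ties are detected
    # identically on a list and its negated reversal
    if hi + lo > 1e-9:
        return hi
    if hi + lo < -1e-9:
        return lo
    total = float(running.sum())
    if total > 1e-9:
        return hi
    if total < -1e-9:
        return lo
    return hi  # fully symmetric walk: positive extreme by convention


def _es_from_mask(stats: np.ndarray, mask: np.ndarray, weight: float):
    """ES and running sum for a boolean membership mask over ranked stats."""
    n = stats.size
    n_hit = int(mask.sum())
    weighted = np.abs(stats[mask]) ** weight
    norm = weighted.sum()
    inc = np.full(n, -1.0 / (n - n_hit))
    if norm > 0:
        inc[mask] = weighted / norm
    else:  # all member stats zero: fall back to equal hit increments
        inc[mask] = 1.0 / n_hit
    running = np.cumsum(inc)
    es = _signed_extreme(running)
    peak = int(np.argmax(running)) if es > 0 else int(np.argmin(running))
    return es, running, peak


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet | frozenset | set, weight: float = 1.0
) -> EnrichmentProfile:
    """Weighted running-sum enrichment score of one set in a ranked list."""
    if weight < 0:
        raise DataError("weight exponent must be nonnegative")
    members = gene_set.members if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    mask = np.fromiter((g in members for g in ranked.genes), bool, len(ranked))
    n_hit = int(mask.sum())
    if n_hit == 0:
        raise DataError("gene set has no overlap with the ranked list")
    if n_hit == len(ranked):
        raise DataError("gene set covers the entire ranked list")
    es, running, peak = _es_from_mask(ranked.stats, mask, weight)
    positions = np.flatnonzero(mask)
    if es > 0:
        lead_pos = positions[positions <= peak]
    elif es < 0:
        lead_pos = positions[positions >= peak]
    else:
        lead_pos = positions[:0]
    return EnrichmentProfile(
        es=es,
        running_sum=running,
        leading_edge=[ranked.genes[i] for i in lead_pos],
        hit_positions=positions,
    )


@dataclass
class GSEAResult:
    """Per-set enrichment table with permutation p-values.

    ``table`` columns: name, size, es, nes, p_value, q_value,
    leading_edge (';'-joined). Sets filtered by the size bounds or with
    empty overlap are absent but counted in ``n_skipped_size`` /
    ``n_skipped_empty``.
    """

    table: pd.DataFrame
    n_permutations: int
    weight: float
    min_size: int
    max_size: int
    seed: int
    n_skipped_size: int
    n_skipped_empty: int
    extra: dict = field(default_factory=dict)


def _null_es_pool(
    stats: np.ndarray,
    size: int,
    n_permutations: int,
    weight: float,
    rng,
    chunk: int = 256,
) -> np.ndarray:
    """Null ES distribution for random size-``size`` member positions.

    Uses the same running-sum definition (including the extreme tie
    rule) as :func:`enrichment_score`, vectorized over permutations in
    chunks to bound memory.
    """
    n = stats.size
    abs_w = np.abs(stats) ** weight
    miss_step = -1.0 / (n - size)
    null_es = np.empty(n_permutations)
    done = 0
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        draws = rng.random((b, n)).argpartition(size - 1, axis=1)[:, :size]
        inc = np.full((b, n), miss_step)
        hit_w = abs_w[draws]
        norms = hit_w.sum(axis=1, keepdims=True)
        hit_inc = np.where(norms > 0, hit_w / np.where(norms > 0, norms, 1.0), 1.0 / size)
        np.put_along_axis(inc, draws, hit_inc, axis=1)
        running = np.cumsum(inc, axis=1)
        hi = running.max(axis=1)
        lo = running.min(axis=1)
        es = np.where(hi + lo > 0, hi, lo)
        tied = np.abs(hi + lo) <= 1e-9
        if tied.any():
            totals = running[tied].sum(axis=1)
            es[tied] = np.where(totals >= -1e-9, hi[tied], lo[tied])
        null_es[done : done + b] = es
        done += b
    return null_es


def preranked_gsea(
    ranked: RankedList,
    collection: GeneSetCollection,
    n_permutations: int = 1000,
    weight: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
    seed: int = 0,
) -> GSEAResult:
    """Pre-ranked GSEA over a collection with a gene-sampling null.

    p = (1 + #{same-sign null with |ES_null| >= |ES|}) / (1 + #{same-sign
    null}); NES = ES / mean(|same-sign null ES|); q by BH across all
    tested sets. Fully reproducible given the seed.
    """
    if len(collection) == 0:
        raise DataError("empty gene set collection")
    if n_permutations < 100:
        raise DataError("need at least 100 permutations")
    gene_index = set(ranked.genes)
    observed: list[tuple[str, int, EnrichmentProfile]] = []
    n_skipped_size = 0
    n_skipped_empty = 0
    for gs in collection:
        overlap = gs.members & gene_index
        if not overlap:
            n_skipped_empty += 1
            continue
        size = len(overlap)
        if size < min_size or size > max_size or size == len(ranked):
            n_skipped_size += 1
            continue
        observed.append((gs.name, size, enrichment_score(ranked, overlap, weight)))
    if not observed:
        raise DataError(
            f"no gene sets within size bounds [{min_size}, {max_size}] "
            "overlap the ranked list"
        )
    rows = []
    for name, size, profile in observed:
        # per-set substream keyed by the set name, so p-values do not
        # depend on collection or member ordering
        rng = np.random.default_rng([seed, zlib.crc32(name.encode())])
        null = _null_es_pool(ranked.stats, size, n_permutations, weight, rng)
        es = profile.es
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if same_sign.size == 0:
            p, nes = 1.0, float("nan")
        else:
            extreme = int((np.abs(same_sign) >= abs(es)).sum())
            p = (1 + extreme) / (1 + same_sign.size)
            denom = np.abs(same_sign).mean()
            nes = es / denom if denom > 0 else float("nan")
        rows.append(
            (name, size, es, nes, p, ";".join(profile.leading_edge))
        )
    table = pd.DataFrame(
        rows, columns=["name", "size", "es", "nes", "p_value", "leading_edge"]
    )
    table["q_value"] = benjamini_hochberg(table["p_value"].to_numpy())
    table = table[
        ["name", "size", "es", "nes", "p_value", "q_value", "leading_edge"]
    ]
    return GSEAResult(
        table=table,
        n_permutations=n_permutations,
        weight=weight,
        min_size=min_size,
        max_size=max_size,
        seed=seed,
        n_skipped_size=n_skipped_size,
        n_skipped_empty=n_skipped_empty,
    )


@dataclass
class ORAResult:
    overlap: int
    expected: float
    p_value: float
    set_size_in_universe: int
    query_size: int
    universe_size: int


def overrepresentation_test(query, universe, gene_set) -> ORAResult:
    """Hypergeometric upper-tail over-representation of ``gene_set``
    within ``query`` drawn from ``universe``."""
    query = frozenset(query)
    universe = frozenset(universe)
    members = (
        gene_set.members if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    )
    if not query or not universe:
        raise DataError("query and universe must be non-empty")
    stray = query - universe
    if stray:
        raise DataError(
            f"{len(stray)} query gene(s) outside the universe, "
            f"e.g. {sorted(stray)[:5]}"
        )
    in_universe = members & universe
    k = len(query & in_universe)
    m, big_k, n = len(universe), len(in_universe), len(query)
    expected = n * big_k / m
    p = float(stats.hypergeom.sf(k - 1, m, big_k, n)) if big_k else 1.0
    return ORAResult(
        overlap=k,
        expected=expected,
        p_value=min(1.0, p),
        set_size_in_universe=big_k,
        query_size=n,
        universe_size=m,
    )


@dataclass
class SetComparisonResult:
    """Set-level expression comparison between two groups.

    One value per member gene per group — the within-group mean
    expression — compared with the rank-sum test. ``values`` is
    plot-ready: one row per member gene with its mean in each group.
    """

    set_name: str
    values: pd.DataFrame  # columns: gene, mean_<A>, mean_<B>
    statistic: float
    p_value: float
    direction: str  # group label with the higher median, or "equal"
    group_a: str
    group_b: str


def compare_set_expression(
    matrix: ExpressionMatrix,
    gene_set: GeneSet,
    groups: SampleGroups,
    group_a: str,
    group_b: str,
) -> SetComparisonResult:
    """Rank-sum comparison of a gene set's expression between two groups."""
    if matrix.unit == COUNT_UNIT:
        raise DataError("set comparison requires normalized values")
    samples_a = groups[group_a]
    samples_b = groups[group_b]
    member_genes = sorted(gene_set.members & set(matrix.gene_ids))
    if len(member_genes) < 3:
        raise DataError(
            f"set {gene_set.name!r} overlaps only {len(member_genes)} matrix "
            "gene(s); need >= 3 for a meaningful comparison"
        )
    sub = matrix.data.loc[member_genes]
    means_a = sub[samples_a].mean(axis=1).to_numpy()
    means_b = sub[samples_b].mean(axis=1).to_numpy()
    w, p = wilcoxon_rank_sum(means_a, means_b)
    med_a, med_b = float(np.median(means_a)), float(np.median(means_b))
    if med_a > med_b:
        direction = group_a
    elif med_b > med_a:
        direction = group_b
    else:
        direction = "equal"
    values = pd.DataFrame(
        {
            "gene": member_genes,
            f"mean_{group_a}": means_a,
            f"mean_{group_b}": means_b,
        }
    )
    return SetComparisonResult(
        set_name=gene_set.name,
        values=values,
        statistic=w,
        p_value=p,
        direction=direction,
        group_a=group_a,
        group_b=group_b,
    )
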