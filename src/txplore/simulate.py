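"""Deterministic synthetic RNA-seq fixture generator.

Emulates small grouped bulk RNA-seq studies (a handful of libraries per
condition, as in public immune-cell datasets): per-gene baseline means
are log-normal, counts are negative-binomial with a shared dispersion
(variance mu + alpha * mu^2), and gene lengths are uniform integers.
Structure is planted on top of the baseline:

* **markers** — per group, genes multiplied by a fold factor in the
  target group, drawn at reduced dispersion and rejection-resampled in
  *every* group until the empirical within-group CV is at or below the
  cap (bounded retries, then a warning). Marker baseline means are
  floored so the cap is attainable — a mean-5 count gene cannot have
  CV <= 0.2 under any count model.
* **differentially expressed genes** — between one named pair of
  groups, multiplied by 2^effect in the second group, with alternating
  signs (half up, half down) recorded in the truth table.
* **gene sets** — planted "enriched" sets drawing a fraction of their
  members from the up-regulated DE genes (so they concentrate at the
  top of a fold-change ranking), plus optional null sets of random
  background genes.

Every draw flows from a single seed; identical specs give byte-identical
bundles.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (
    DataError,
    ExpressionMatrix,
    GeneLengthTable,
    GeneSet,
    GeneSetCollection,
    SampleGroups,
)

__all__ = ["SyntheticSpec", "DatasetBundle", "generate_dataset"]

_MARKER_BASELINE_FLOOR = 50.0
_CV_RETRIES = 200


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study.

    Defaults mirror a small multi-group immune-cell comparison: 500
    genes, three groups of four libraries, overdispersed counts
    (dispersion 0.25, background within-group CV ~ 0.5), and planted
    structure of 10 markers per group at 8-fold with CV capped at 0.2,
    50 DE genes at |log2 effect| 2 between groups A and B, and five
    enriched 30-gene sets drawing 80% of members from up-regulated DE
    genes.
    """

    n_genes: int = 500
    groups: dict[str, int] = field(default_factory=lambda: {"A": 4, "B": 4, "C": 4})
    baseline_log_mean: float = math.log(100.0)
    baseline_log_sd: float = 1.0
    dispersion: float = 0.25
    length_range: tuple[int, int] = (500, 5000)
    markers_per_group: int = 10
    marker_fold: float = 8.0
    marker_cv_cap: float = 0.2
    n_de_genes: int = 50
    de_pair: tuple[str, str] = ("A", "B")
    de_log2_effect: float = 2.0
    n_gene_sets: int = 5
    gene_set_size: int = 30
    de_fraction_in_sets: float = 0.8
    n_null_sets: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise DataError("n_genes must be positive")
        if not self.groups or any(n < 1 for n in self.groups.values()):
            raise DataError("every group needs at least one sample")
        n_planted = (
            self.markers_per_group * len(self.groups) + self.n_de_genes
        )
        if n_planted > self.n_genes:
            raise DataError(
                f"planted genes ({n_planted}) exceed n_genes ({self.n_genes})"
            )
        if self.markers_per_group and self.marker_fold <= 1:
            raise DataError("marker fold must exceed 1")
        if self.n_de_genes:
            a, b = self.de_pair
            if a not in self.groups or b not in self.groups:
                raise DataError(f"de_pair {self.de_pair} not in groups")
        if self.n_gene_sets and self.gene_set_size > self.n_genes:
            raise DataError("gene_set_size exceeds n_genes")

    def null(self) -> "SyntheticSpec":
        """Copy of this spec with all planted structure removed."""
        return replace(
            self, markers_per_group=0, n_de_genes=0, n_gene_sets=0, n_null_sets=0
        )


@dataclass
class DatasetBundle:
    """A synthetic study plus the ground truth planted into it."""

    matrix: ExpressionMatrix
    groups: SampleGroups
    lengths: GeneLengthTable
    sets: GeneSetCollection | None
    marker_truth: dict[str, list[str]]  # group -> planted marker genes
    de_truth: pd.DataFrame  # columns: gene, log2_effect (signed)
    enriched_sets: list[str]
    spec: SyntheticSpec

    def __post_init__(self) -> None:
        genes = set(self.matrix.gene_ids)
        for label, ids in self.marker_truth.items():
            stray = set(ids) - genes
            if stray:
                raise DataError(f"marker truth for {label!r} not in matrix: {stray}")
        stray = set(self.de_truth["gene"]) - genes
        if stray:
            raise DataError(f"DE truth genes not in matrix: {stray}")


def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with variance mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-8:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _draw_capped_cv(rng, mean: float, n: int, cap: float) -> np.ndarray:
    """Counts for one gene in one group with empirical CV <= cap.

    Uses a reduced dispersion targeting a true CV of cap/2, then
    rejection-resamples; after bounded retries the best draw so far is
    kept with a warning.
    """
    target_cv = cap / 2.0
    disp = max(target_cv**2 - 1.0 / max(mean, 1.0), 0.0)
    best = None
    best_cv = math.inf
    for _ in range(_CV_RETRIES):
        draw = _nb_draw(rng, np.full(n, mean), disp)
        m = draw.mean()
        cv = draw.std(ddof=1) / m if m > 0 else math.inf
        if cv < best_cv:
            best, best_cv = draw, cv
        if cv <= cap:
            return draw
    warnings.warn(
        f"CV cap {cap} not met after {_CV_RETRIES} retries (best {best_cv:.3f})",
        RuntimeWarning,
        stacklevel=2,
    )
    return best


def generate_dataset(spec: SyntheticSpec) -> DatasetBundle:
    """Generate a grouped count matrix with planted structure and truth."""
    rng = np.random.default_rng(spec.seed)
    n_genes = spec.n_genes
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    labels = list(spec.groups)
    sample_ids: list[str] = []
    group_map: dict[str, list[str]] = {}
    for label in labels:
        ids = [f"{label}_{j + 1}" for j in range(spec.groups[label])]
        group_map[label] = ids
        sample_ids.extend(ids)
    groups = SampleGroups(group_map)

    baseline = rng.lognormal(
        spec.baseline_log_mean, spec.baseline_log_sd, size=n_genes
    )

    # allocate planted gene slots: markers per group first, then DE genes
    cursor = 0
    marker_truth: dict[str, list[str]] = {}
    marker_index: dict[str, list[int]] = {}
    for label in labels:
        idx = list(range(cursor, cursor + spec.markers_per_group))
        cursor += spec.markers_per_group
        marker_index[label] = idx
        marker_truth[label] = [gene_ids[i] for i in idx]
        baseline[idx] = np.maximum(baseline[idx], _MARKER_BASELINE_FLOOR)
    de_index = list(range(cursor, cursor + spec.n_de_genes))
    de_signs = np.where(np.arange(spec.n_de_genes) % 2 == 0, 1.0, -1.0)
    de_truth = pd.DataFrame(
        {
            "gene": [gene_ids[i] for i in de_index],
            "log2_effect": de_signs * spec.de_log2_effect,
        }
    )

    # per-group mean matrix
    means = {label: baseline.copy() for label in labels}
    for label in labels:
        means[label][marker_index[label]] *= spec.marker_fold
    if spec.n_de_genes:
        second = spec.de_pair[1]
        means[second][de_index] *= 2.0 ** (de_signs * spec.de_log2_effect)

    all_marker_idx = sorted(i for idx in marker_index.values() for i in idx)
    counts = np.empty((n_genes, len(sample_ids)), dtype=np.int64)
    col = 0
    for label in labels:
        n_s = spec.groups[label]
        block = _nb_draw(
            rng,
            np.repeat(means[label][:, None], n_s, axis=1),
            spec.dispersion,
        )
        # markers must be CV-stable in every group, not just their target
        for gi in all_marker_idx:
            block[gi] = _draw_capped_cv(
                rng, float(means[label][gi]), n_s, spec.marker_cv_cap
            )
        counts[:, col : col + n_s] = block
        col += n_s

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids), "counts"
    )
    lengths = GeneLengthTable(
        pd.Series(
            rng.integers(spec.length_range[0], spec.length_range[1] + 1, n_genes),
            index=gene_ids,
        )
    )

    sets = None
    enriched_names: list[str] = []
    if spec.n_gene_sets or spec.n_null_sets:
        collection: dict[str, GeneSet] = {}
        up_de = [gene_ids[i] for i, s in zip(de_index, de_signs) if s > 0]
        background = [
            g
            for i, g in enumerate(gene_ids)
            if i not in set(de_index) and i not in set(all_marker_idx)
        ]
        for k in range(spec.n_gene_sets):
            n_from_de = min(
                int(round(spec.de_fraction_in_sets * spec.gene_set_size)),
                len(up_de),
            )
            chosen = list(rng.choice(up_de, n_from_de, replace=False)) if n_from_de else []
            filler = list(
                rng.choice(background, spec.gene_set_size - n_from_de, replace=False)
            )
            name = f"SET_ENR_{k + 1:02d}"
            collection[name] = GeneSet(name, "planted enriched set", tuple(chosen + filler))
            if n_from_de:
                enriched_names.append(name)
        for k in range(spec.n_null_sets):
            name = f"SET_NULL_{k + 1:02d}"
            members = tuple(
                rng.choice(background, spec.gene_set_size, replace=False)
            )
            collection[name] = GeneSet(name, "random background set", members)
        sets = GeneSetCollection(collection)

    return DatasetBundle(
        matrix=matrix,
        groups=groups,
        lengths=lengths,
        sets=sets,
        marker_truth=marker_truth,
        de_truth=de_truth,
        enriched_sets=enriched_names,
        spec=spec,
    )
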