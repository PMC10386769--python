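"""Core data containers shared across the toolkit.

The toolkit operates on four kinds of tabular input: a gene × sample
expression matrix with a declared unit, a gene → length map, a labeled
partition of samples into comparison groups, and named gene-set
collections (GMT-derived). Each container validates its invariants on
construction so downstream code can assume well-formed data.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COUNT_UNIT = "counts"
NORMALIZED_UNITS = ("CPM", "RPKM", "FPKM", "TPM")
LOG_UNIT = "log2"
VALID_UNITS = (COUNT_UNIT, *NORMALIZED_UNITS, LOG_UNIT)


class DataError(ValueError):
    """Raised when input data violate a documented contract."""


def _first_duplicate(values) -> str | None:
    seen = set()
    for v in values:
        if v in seen:
            return str(v)
        seen.add(v)
    return None


@dataclass
class ExpressionMatrix:
    """Gene × sample expression grid with a declared unit.

    ``data`` is a pandas DataFrame indexed by gene identifier with one
    column per sample identifier. All values must be finite; values must
    be nonnegative unless the unit is ``log2``.
    """

    data: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise DataError(
                f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}"
            )
        if self.data.shape[0] == 0:
            raise DataError("expression matrix has no genes")
        if self.data.shape[1] == 0:
            raise DataError("expression matrix has no samples")
        dup = _first_duplicate(self.data.index)
        if dup is not None:
            raise DataError(f"duplicate gene identifier {dup!r}")
        dup = _first_duplicate(self.data.columns)
        if dup is not None:
            raise DataError(f"duplicate sample identifier {dup!r}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DataError("expression matrix contains non-numeric values")
        if not np.isfinite(values).all():
            g, s = np.argwhere(~np.isfinite(values))[0]
            raise DataError(
                f"non-finite value at gene {self.data.index[g]!r}, "
                f"sample {self.data.columns[s]!r}"
            )
        if self.unit != LOG_UNIT and (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise DataError(
                f"negative value {values[g, s]} at gene "
                f"{self.data.index[g]!r}, sample {self.data.columns[s]!r} "
                f"(unit {self.unit!r} requires nonnegative values)"
            )

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_values(self, values: np.ndarray, unit: str) -> "ExpressionMatrix":
        """Return a new matrix with the same axes but new values/unit."""
        return ExpressionMatrix(
            pd.DataFrame(values, index=self.data.index, columns=self.data.columns),
            unit,
        )


@dataclass
class GeneLengthTable:
    """Gene identifier → transcript/gene length in base pairs."""

    lengths: pd.Series

    def __post_init__(self) -> None:
        dup = _first_duplicate(self.lengths.index)
        if dup is not None:
            raise DataError(f"duplicate gene identifier {dup!r} in length table")
        vals = self.lengths.to_numpy()
        if not np.issubdtype(vals.dtype, np.number) or (vals < 1).any():
            raise DataError("gene lengths must be integers >= 1")
        self.lengths = self.lengths.astype(np.int64)

    def __contains__(self, gene: str) -> bool:
        return gene in self.lengths.index

    def __getitem__(self, gene: str) -> int:
        return int(self.lengths[gene])

    def __len__(self) -> int:
        return len(self.lengths)

    def for_genes(self, genes) -> np.ndarray:
        """Lengths aligned to ``genes``; missing genes are a hard error."""
        missing = [g for g in genes if g not in self.lengths.index]
        if missing:
            shown = ", ".join(map(repr, missing[:20]))
            raise DataError(f"no length for {len(missing)} gene(s): {shown}")
        return self.lengths.loc[list(genes)].to_numpy(dtype=float)


@dataclass
class SampleGroups:
    """Disjoint, labeled partition of sample identifiers."""

    groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.groups:
            raise DataError("no sample groups defined")
        seen: dict[str, str] = {}
        for label, samples in self.groups.items():
            if not samples:
                raise DataError(f"group {label!r} is empty")
            for s in samples:
                if s in seen:
                    raise DataError(
                        f"sample {s!r} assigned to both {seen[s]!r} and {label!r}"
                    )
                seen[s] = label

    @property
    def labels(self) -> list[str]:
        return list(self.groups)

    def __contains__(self, label: str) -> bool:
        return label in self.groups

    def __getitem__(self, label: str) -> list[str]:
        if label not in self.groups:
            raise DataError(
                f"unknown group {label!r}; available: {sorted(self.groups)}"
            )
        return list(self.groups[label])

    def all_samples(self) -> list[str]:
        return [s for samples in self.groups.values() for s in samples]

    def rest_of(self, target: str) -> dict[str, list[str]]:
        """Non-target groups (label → samples)."""
        self[target]  # raise on unknown label
        return {lb: list(ss) for lb, ss in self.groups.items() if lb != target}


@dataclass
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise DataError(f"gene set {self.name!r} is empty")

    @property
    def members(self) -> frozenset[str]:
        return frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets (one GMT line each)."""

    sets: dict[str, GeneSet]
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if name != gs.name:
                raise DataError(f"set name mismatch: key {name!r} vs {gs.name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> GeneSet:
        if name not in self.sets:
            raise DataError(f"unknown gene set {name!r}")
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for gs in self:
            out |= gs.members
        return frozenset(out)


@dataclass
class ValidationReport:
    """Cross-reference report of annotations against a matrix."""

    n_genes_matched: int
    n_genes_unmatched: int
    unmatched_examples: list[str]
    warnings: list[str]

    def __post_init__(self) -> None:
        if len(self.unmatched_examples) > 20:
            self.unmatched_examples = self.unmatched_examples[:20]
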