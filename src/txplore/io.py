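"""Readers and writers for the delimited-text formats the toolkit consumes.

Expression tables are delimited text with a header row of sample ids and
gene ids in the first column. Gene sets use the MSigDB GMT dialect. Group
assignments are two-column delimited text. Lines starting with ``#`` are
treated as comments everywhere (the CLI writes provenance headers).

Delimiters are explicit (default tab); no auto-detection is attempted.
Identifier matching is exact and case-sensitive throughout.
"""
from __future__ import annotations

import csv
import os

import numpy as np
import pandas as pd

from .containers import (
    COUNT_UNIT,
    DataError,
    ExpressionMatrix,
    GeneLengthTable,
    GeneSet,
    GeneSetCollection,
    SampleGroups,
    ValidationReport,
)

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_gene_lengths",
    "write_gene_lengths",
    "read_gene_sets_gmt",
    "write_gene_sets_gmt",
    "read_sample_groups",
    "write_sample_groups",
    "validate_against",
]


def _data_rows(path: str | os.PathLike, delimiter: str) -> list[list[str]]:
    try:
        handle = open(path, newline="")
    except OSError as exc:
        raise DataError(f"cannot read {path}: {exc}") from exc
    with handle:
        reader = csv.reader(handle, delimiter=delimiter)
        rows = [row for row in reader if row and not row[0].startswith("#")]
    return rows


def read_expression_table(
    path: str | os.PathLike,
    delimiter: str = "\t",
    unit: str = COUNT_UNIT,
    strict_integer: bool = False,
) -> ExpressionMatrix:
    """Read a gene × sample expression table.

    The first row holds sample identifiers (an optional leading corner
    label is accepted); the first column holds gene identifiers; the body
    is numeric. Values are parsed as decimal reals even for counts (RSEM
    and kin emit non-integer expected counts); pass ``strict_integer=True``
    to enforce integrality.
    """
    rows = _data_rows(path, delimiter)
    if len(rows) < 2:
        raise DataError(f"{path}: need a header row and at least one gene row")
    header, body = rows[0], rows[1:]
    width = len(body[0])
    if len(header) == width:
        sample_ids = header[1:]
    elif len(header) == width - 1:
        sample_ids = header
    else:
        raise DataError(
            f"{path}: header has {len(header)} fields but first data row has "
            f"{width} (ragged rows)"
        )
    gene_ids: list[str] = []
    values = np.empty((len(body), len(sample_ids)), dtype=float)
    for i, row in enumerate(body):
        if len(row) != width:
            raise DataError(
                f"{path}: row {i + 2} has {len(row)} fields, expected {width} "
                "(ragged rows)"
            )
        gene = row[0]
        gene_ids.append(gene)
        for j, cell in enumerate(row[1:]):
            try:
                v = float(cell)
            except ValueError:
                raise DataError(
                    f"{path}: non-numeric cell {cell!r} at gene {gene!r}, "
                    f"sample {sample_ids[j]!r}"
                ) from None
            if strict_integer and v != int(v):
                raise DataError(
                    f"{path}: non-integer count {cell!r} at gene {gene!r}, "
                    f"sample {sample_ids[j]!r} (strict integer mode)"
                )
            values[i, j] = v
    frame = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    return ExpressionMatrix(frame, unit)


def write_expression_table(
    matrix: ExpressionMatrix,
    path: str | os.PathLike,
    delimiter: str = "\t",
    header_comment: str | None = None,
) -> None:
    """Write an expression table; values serialized at full precision."""
    try:
        handle = open(path, "w", newline="")
    except OSError as exc:
        raise DataError(f"cannot write {path}: {exc}") from exc
    with handle:
        if header_comment:
            for line in header_comment.splitlines():
                handle.write(f"# {line}\n")
        handle.write(delimiter.join(["gene_id", *matrix.sample_ids]) + "\n")
        values = matrix.data.to_numpy()
        for gene, row in zip(matrix.gene_ids, values):
            cells = [repr(float(v)) for v in row]
            handle.write(delimiter.join([gene, *cells]) + "\n")


def read_gene_lengths(
    path: str | os.PathLike, delimiter: str = "\t", header: bool = False
) -> GeneLengthTable:
    """Read a two-column gene → length (bp) table."""
    rows = _data_rows(path, delimiter)
    if header:
        rows = rows[1:]
    if not rows:
        raise DataError(f"{path}: no gene lengths found")
    genes, lengths = [], []
    for i, row in enumerate(rows):
        if len(row) < 2:
            raise DataError(f"{path}: row {i + 1} needs gene and length columns")
        try:
            length = int(row[1])
        except ValueError:
            raise DataError(
                f"{path}: non-integer length {row[1]!r} for gene {row[0]!r}"
            ) from None
        genes.append(row[0])
        lengths.append(length)
    return GeneLengthTable(pd.Series(lengths, index=genes))


def write_gene_lengths(
    table: GeneLengthTable, path: str | os.PathLike, delimiter: str = "\t"
) -> None:
    with open(path, "w", newline="") as handle:
        for gene, length in table.lengths.items():
            handle.write(f"{gene}{delimiter}{int(length)}\n")


def read_gene_sets_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Read an MSigDB-dialect GMT file (name, description, members...).

    Duplicate member genes within one line are deduplicated (first
    occurrence kept); lines without members are skipped with a warning.
    Duplicate set names are a hard error.
    """
    try:
        handle = open(path)
    except OSError as exc:
        raise DataError(f"cannot read {path}: {exc}") from exc
    sets: dict[str, GeneSet] = {}
    warnings: list[str] = []
    with handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise DataError(
                    f"{path}: line {lineno} needs at least name and description"
                )
            name, description = fields[0], fields[1]
            if name in sets:
                raise DataError(f"{path}: duplicate gene set name {name!r}")
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            if not members:
                warnings.append(f"line {lineno}: set {name!r} has no members, skipped")
                continue
            sets[name] = GeneSet(name, description, tuple(members))
    if not sets:
        raise DataError(f"{path}: no usable gene sets")
    return GeneSetCollection(sets, warnings)


def write_gene_sets_gmt(
    collection: GeneSetCollection, path: str | os.PathLike
) -> None:
    with open(path, "w") as handle:
        for gs in collection:
            handle.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def read_sample_groups(
    path: str | os.PathLike, delimiter: str = "\t", header: bool = False
) -> SampleGroups:
    """Read two-column sample → group assignments, preserving file order."""
    rows = _data_rows(path, delimiter)
    if header:
        rows = rows[1:]
    if not rows:
        raise DataError(f"{path}: no sample assignments found")
    groups: dict[str, list[str]] = {}
    for i, row in enumerate(rows):
        if len(row) < 2:
            raise DataError(
                f"{path}: row {i + 1} needs sample and group columns"
            )
        sample, label = row[0], row[1]
        groups.setdefault(label, []).append(sample)
    return SampleGroups(groups)


def write_sample_groups(
    groups: SampleGroups, path: str | os.PathLike, delimiter: str = "\t"
) -> None:
    with open(path, "w", newline="") as handle:
        for label in groups.labels:
            for sample in groups[label]:
                handle.write(f"{sample}{delimiter}{label}\n")


def validate_against(
    matrix: ExpressionMatrix,
    groups: SampleGroups | None = None,
    sets: GeneSetCollection | None = None,
    lengths: GeneLengthTable | None = None,
) -> ValidationReport:
    """Cross-reference annotations against a matrix.

    Group samples missing from the matrix are a hard error (comparisons
    must be fully resolvable); genes referenced by sets or the length
    table but absent from the matrix are reported, not fatal.
    """
    matrix_genes = set(matrix.gene_ids)
    matrix_samples = set(matrix.sample_ids)
    warnings: list[str] = []
    if groups is not None:
        missing = [s for s in groups.all_samples() if s not in matrix_samples]
        if missing:
            shown = ", ".join(map(repr, missing[:20]))
            raise DataError(
                f"{len(missing)} group sample(s) absent from matrix: {shown}"
            )
    queried: set[str] = set()
    if sets is not None:
        queried |= sets.all_genes()
    if lengths is not None:
        length_genes = set(map(str, lengths.lengths.index))
        queried |= length_genes
        missing_lengths = sorted(matrix_genes - length_genes)
        if missing_lengths:
            shown = ", ".join(map(repr, missing_lengths[:20]))
            warnings.append(
                f"{len(missing_lengths)} matrix gene(s) lack lengths: {shown}"
            )
    matched = sorted(queried & matrix_genes)
    unmatched = sorted(queried - matrix_genes)
    if unmatched:
        warnings.append(f"{len(unmatched)} annotation gene(s) not in matrix")
    return ValidationReport(
        n_genes_matched=len(matched),
        n_genes_unmatched=len(unmatched),
        unmatched_examples=unmatched[:20],
        warnings=warnings,
    )
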