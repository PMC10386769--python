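"""Count normalization: CPM, RPKM/FPKM, TPM, and the log2 transform.

Library size is always the column sum of the supplied count matrix; the
toolkit never consults aligner-reported totals. FPKM is treated as a
synonym of RPKM. All three normalizations refuse non-count input rather
than silently renormalizing an already-normalized unit.
"""
from __future__ import annotations

import numpy as np

from .containers import (
    COUNT_UNIT,
    LOG_UNIT,
    DataError,
    ExpressionMatrix,
    GeneLengthTable,
)

__all__ = ["cpm", "rpkm", "tpm", "log_transform"]


def _require_counts(matrix: ExpressionMatrix, op: str) -> np.ndarray:
    if matrix.unit != COUNT_UNIT:
        raise DataError(
            f"{op} requires raw counts, got unit {matrix.unit!r} "
            "(refusing to renormalize an already-normalized matrix)"
        )
    return matrix.data.to_numpy(dtype=float)


def _library_sizes(matrix: ExpressionMatrix, counts: np.ndarray) -> np.ndarray:
    sizes = counts.sum(axis=0)
    if (sizes <= 0).any():
        bad = matrix.sample_ids[int(np.argmax(sizes <= 0))]
        raise DataError(f"sample {bad!r} has zero library size (all-zero column)")
    return sizes


def cpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Counts per million: depth-only normalization by column sum."""
    counts = _require_counts(matrix, "cpm")
    sizes = _library_sizes(matrix, counts)
    return matrix.with_values(counts * 1e6 / sizes, "CPM")


def rpkm(matrix: ExpressionMatrix, lengths: GeneLengthTable) -> ExpressionMatrix:
    """Reads per kilobase per million mapped reads.

    value(g, s) = counts(g, s) * 1e9 / (library_size(s) * length(g))
    """
    counts = _require_counts(matrix, "rpkm")
    sizes = _library_sizes(matrix, counts)
    length_bp = lengths.for_genes(matrix.gene_ids)
    values = counts * 1e9 / (sizes[None, :] * length_bp[:, None])
    return matrix.with_values(values, "RPKM")


def tpm(matrix: ExpressionMatrix, lengths: GeneLengthTable) -> ExpressionMatrix:
    """Transcripts per million: per-length read rates rescaled so every
    column sums to 1e6."""
    counts = _require_counts(matrix, "tpm")
    _library_sizes(matrix, counts)  # zero-library columns are an error here too
    length_bp = lengths.for_genes(matrix.gene_ids)
    rates = counts / length_bp[:, None]
    totals = rates.sum(axis=0)
    values = rates * 1e6 / totals
    return matrix.with_values(values, "TPM")


def log_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(value + pseudocount); requires a non-log input unit."""
    if matrix.unit == LOG_UNIT:
        raise DataError("matrix is already log2-transformed")
    if pseudocount <= 0:
        if (matrix.data.to_numpy() == 0).any():
            raise DataError(
                "pseudocount must be > 0 when the matrix contains zeros"
            )
        if pseudocount < 0:
            raise DataError("pseudocount must be nonnegative")
    values = np.log2(matrix.data.to_numpy(dtype=float) + pseudocount)
    return matrix.with_values(values, LOG_UNIT)
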