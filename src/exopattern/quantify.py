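"""RPKM quantification, reliable-quantification filtering, low-count replacement.

RPKM = count * 1e9 / (length_bp * library_size). A feature is *retained*
when its RPKM reaches the RPKM-equivalent of ``rqt_reads`` mapped reads in
at least one sample — algebraically identical to "count >= rqt_reads in >= 1
sample", since RPKM is monotone in count at fixed length and library size.
RPKMs arising from ``replace_max_reads`` or fewer reads are replaced by a
single experiment-wide value: the cross-sample mean of the RPKM-equivalent
of ``replace_max_reads`` reads at the median feature length. The floor
prevents spuriously large fold changes from near-zero denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Optional

import numpy as np
import pandas as pd

from .config import QuantifyParams
from .errors import DataError, DomainError
from .features import FeatureTable


@dataclass
class ExpressionMatrix:
    """RPKM values with per-entry provenance and per-feature retention.

    ``replaced`` flags entries set to the experiment-wide replacement value;
    ``retained`` is None until the retention filter has run. Dropped
    features stay in the matrix (flagged False), never silently removed.
    """

    values: pd.DataFrame
    replaced: pd.DataFrame
    length_bp: pd.Series
    library_size: pd.Series
    retained: Optional[pd.Series] = None
    replacement_value: Optional[float] = None

    def retained_values(self) -> pd.DataFrame:
        if self.retained is None:
            return self.values
        return self.values[self.retained]


def rpkm(count: float, length_bp: float, library_size: float) -> float:
    """Reads per kilobase of feature per million mapped reads for one entry."""
    if length_bp <= 0:
        raise DomainError(f"length_bp must be positive, got {length_bp}")
    if library_size <= 0:
        raise DomainError(f"library_size must be positive, got {library_size}")
    if count < 0:
        raise DomainError(f"count must be nonnegative, got {count}")
    return count * 1e9 / (length_bp * library_size)


def _denominator(length_bp: np.ndarray, library_size: np.ndarray) -> np.ndarray:
    # shared by rpkm_matrix and the RQT threshold so the boundary case
    # (count == rqt_reads) compares bit-identically
    return np.multiply.outer(length_bp.astype(float), library_size.astype(float))


def rpkm_matrix(counts, features: FeatureTable) -> ExpressionMatrix:
    """Entrywise RPKM for a CountMatrix; provenance all-raw, retention unset."""
    lens = features.lengths().reindex(counts.counts.index)
    if lens.isna().any():
        missing = lens.index[lens.isna()][0]
        raise DataError(f"feature {missing!r} has no length in the feature table")
    lib = counts.library_sizes()
    denom = _denominator(lens.to_numpy(), lib.to_numpy())
    vals = counts.counts.to_numpy(dtype=float) * 1e9 / denom
    values = pd.DataFrame(vals, index=counts.counts.index, columns=counts.counts.columns)
    replaced = pd.DataFrame(False, index=values.index, columns=values.columns)
    return ExpressionMatrix(values, replaced, lens.astype(int), lib.astype(int))


def _check_aligned(expr: ExpressionMatrix, counts) -> None:
    if not expr.values.index.equals(counts.counts.index) or not expr.values.columns.equals(
        counts.counts.columns
    ):
        raise DataError("expression and count matrices are misaligned")


def rqt_filter(expr: ExpressionMatrix, counts, params: QuantifyParams) -> ExpressionMatrix:
    """Apply the reliable-quantification retention rule in RPKM space.

    A feature is retained when its RPKM is >= (or > in strict mode) the
    per-entry RPKM-equivalent of ``params.rqt_reads`` reads in at least one
    sample. The threshold is computed with the same expression as the RPKM
    itself so the decision coincides exactly with the count-space rule.
    The decision uses the raw (count-derived) RPKM, so the filter commutes
    with the low-count replacement.
    """
    _check_aligned(expr, counts)
    denom = _denominator(expr.length_bp.to_numpy(), expr.library_size.to_numpy())
    threshold = params.rqt_reads * 1e9 / denom
    vals = counts.counts.to_numpy(dtype=float) * 1e9 / denom
    hits = vals > threshold if params.strict_rqt else vals >= threshold
    retained = pd.Series(hits.any(axis=1), index=expr.values.index)
    return dc_replace(expr, retained=retained)


def low_count_replacement(
    expr: ExpressionMatrix, counts, params: QuantifyParams
) -> ExpressionMatrix:
    """Replace RPKMs arising from <= ``replace_max_reads`` reads by a floor value.

    The floor V is the mean over samples s of
    replace_max_reads * 1e9 / (median_length_kb * 1000 * library_size_s);
    every entry whose *count* is <= replace_max_reads becomes V and is
    flagged replaced. Keyed on counts, hence idempotent.
    """
    _check_aligned(expr, counts)
    lib = expr.library_size.to_numpy(dtype=float)
    value = float(
        np.mean(params.replace_max_reads * 1e9 / (params.median_length_kb * 1000.0 * lib))
    )
    mask = counts.counts.to_numpy() <= params.replace_max_reads
    vals = expr.values.to_numpy().copy()
    vals[mask] = value
    values = pd.DataFrame(vals, index=expr.values.index, columns=expr.values.columns)
    replaced = pd.DataFrame(
        expr.replaced.to_numpy() | mask, index=values.index, columns=values.columns
    )
    return dc_replace(expr, values=values, replaced=replaced, replacement_value=value)


def quantify_counts(counts, features: FeatureTable, params: QuantifyParams) -> ExpressionMatrix:
    """Convenience composition: RPKM -> retention filter -> replacement floor."""
    expr = rpkm_matrix(counts, features)
    expr = rqt_filter(expr, counts, params)
    return low_count_replacement(expr, counts, params)
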