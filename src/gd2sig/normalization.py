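"""Median-of-ratios count normalization and the decimal-log transform.

Raw gene-level read counts are scaled by per-sample size factors estimated
with the median-of-ratios method: every gene with strictly positive counts
in all samples contributes the ratio of its count to its across-sample
geometric mean, and a sample's size factor is the median of those ratios.
Dividing counts by the size factors yields normalized expression values;
all downstream signature scoring operates on ``log10(normalized + pseudocount)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InputError

__all__ = [
    "validate_count_matrix",
    "estimate_size_factors",
    "normalize_counts",
    "log10_transform",
]


def validate_count_matrix(counts: pd.DataFrame, *, require_integer: bool = True) -> None:
    """Check the count-matrix contract: unique axes, nonnegative values.

    Raises
    ------
    InputError
        If gene or sample identifiers are duplicated, or any value is
        negative, non-finite, or (with ``require_integer``) non-integral.
    """
    if counts.index.has_duplicates:
        dupes = counts.index[counts.index.duplicated()].unique().tolist()
        raise InputError(f"duplicate gene identifiers: {dupes[:5]}")
    if counts.columns.has_duplicates:
        dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise InputError(f"duplicate sample identifiers: {dupes[:5]}")
    values = counts.to_numpy()
    if not np.isfinite(values).all():
        raise InputError("count matrix contains non-finite values")
    if (values < 0).any():
        raise InputError("count matrix contains negative values")
    if require_integer and not np.array_equal(values, np.floor(values)):
        raise InputError("count matrix contains non-integral values")


def estimate_size_factors(
    counts: pd.DataFrame, *, positive_only: bool = False
) -> pd.Series:
    """Estimate per-sample size factors by the median-of-ratios method.

    Parameters
    ----------
    counts
        Genes x samples matrix of nonnegative integer read counts.
    positive_only
        Fallback for sparse matrices: compute each gene's geometric mean
        over its strictly positive entries only, and take each sample's
        median ratio over the genes with a positive count in that sample.
        The default (``False``) uses the standard convention in which any
        gene containing a zero is excluded from the reference set.

    Returns
    -------
    pandas.Series
        Positive size factor per sample, indexed like ``counts.columns``.

    Raises
    ------
    DegenerateDataError
        If no reference genes are available (default mode: no gene is
        positive in every sample; fallback mode: some sample has no
        positive counts at all).

    Notes
    -----
    Real-valued matrices are accepted so that an already-normalized matrix
    can be re-estimated (its size factors are 1 when the reference gene set
    is unchanged); integrality of raw inputs is enforced at the pipeline
    boundary.
    """
    validate_count_matrix(counts, require_integer=False)
    values = counts.to_numpy(dtype=float)
    if positive_only:
        return _size_factors_positive_only(values, counts.columns)

    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise DegenerateDataError(
            "no gene has strictly positive counts in every sample; "
            "filter samples/genes or pass positive_only=True to use the "
            "positive-counts-only geometric-mean fallback"
        )
    ref = values[all_positive]
    log_geo_mean = np.log(ref).mean(axis=1)
    ratios = ref / np.exp(log_geo_mean)[:, None]
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _size_factors_positive_only(values: np.ndarray, samples: pd.Index) -> pd.Series:
    positive = values > 0
    has_any = positive.any(axis=1)
    if not has_any.any():
        raise DegenerateDataError("count matrix is entirely zero")
    values = values[has_any]
    positive = positive[has_any]
    logs = np.zeros_like(values)
    np.log(values, out=logs, where=positive)
    log_geo_mean = logs.sum(axis=1) / positive.sum(axis=1)
    factors = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        mask = positive[:, j]
        if not mask.any():
            raise DegenerateDataError(
                f"sample {samples[j]!r} has no positive counts; cannot "
                "estimate its size factor"
            )
        factors[j] = np.median(values[mask, j] / np.exp(log_geo_mean[mask]))
    return pd.Series(factors, index=samples, name="size_factor")


def normalize_counts(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its size factor.

    Raises
    ------
    InputError
        If the sample sets of the matrix and the size-factor vector differ,
        or any size factor is nonpositive.
    """
    if set(size_factors.index) != set(counts.columns):
        raise InputError("size-factor samples do not match count-matrix samples")
    factors = size_factors.reindex(counts.columns)
    if (factors <= 0).any() or not np.isfinite(factors.to_numpy()).all():
        raise InputError("size factors must be positive and finite")
    return counts / factors


def log10_transform(expr: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise ``log10(expr + pseudocount)``.

    A pseudocount of 1 maps zero expression to a score contribution of 0
    while preserving the ordering of values.
    """
    if not pseudocount > 0:
        raise InputError(f"pseudocount must be positive, got {pseudocount}")
    return np.log10(expr + pseudocount)
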