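"""Reading, writing and basic preparation of RNA-seq count matrices.

A count matrix is a :class:`pandas.DataFrame` of non-negative integers with
gene identifiers as the index (rows) and sample identifiers as the columns.
This orientation — genes x samples — is used in every on-disk file and in
every public function of the package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "read_counts",
    "write_counts",
    "validate_counts",
    "read_covariates",
    "filter_low_expression",
    "estimate_size_factors",
]


class CountMatrixError(ValueError):
    """Raised when a table does not satisfy the count-matrix contract."""


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check the count-matrix invariants and return the validated frame.

    Requires non-negative integral entries and unique gene / sample
    identifiers. Float dtypes holding whole numbers are accepted and cast
    to int64.
    """
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()][0]
        raise CountMatrixError(f"duplicate gene id: {dup!r}")
    if counts.columns.has_duplicates:
        dup = counts.columns[counts.columns.duplicated()][0]
        raise CountMatrixError(f"duplicate sample id: {dup!r}")
    values = counts.to_numpy()
    if values.size:
        if not np.issubdtype(values.dtype, np.number):
            raise CountMatrixError("counts must be numeric")
        if not np.isfinite(values).all():
            raise CountMatrixError("counts contain non-finite values")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise CountMatrixError(
                f"negative count at gene {counts.index[i]!r}, "
                f"sample {counts.columns[j]!r}"
            )
        if not np.issubdtype(values.dtype, np.integer):
            if np.any(values != np.round(values)):
                i, j = np.argwhere(values != np.round(values))[0]
                raise CountMatrixError(
                    f"non-integer count at gene {counts.index[i]!r}, "
                    f"sample {counts.columns[j]!r}"
                )
    return counts.astype(np.int64)


def read_counts(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a genes x samples count matrix from a delimited text file.

    The first column holds gene ids, the header row holds sample ids.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise CountMatrixError(f"cannot parse count matrix {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None  # header label is file furniture, not data
    return validate_counts(df)


def write_counts(counts: pd.DataFrame, path, delimiter: str = "\t") -> None:
    """Write a count matrix so that :func:`read_counts` recovers it exactly."""
    validate_counts(counts).to_csv(path, sep=delimiter, index_label="gene_id")


def read_covariates(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a sample-covariate table (sample id index, categorical columns)."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise CountMatrixError(f"duplicate sample id in covariates: {dup!r}")
    return df


def filter_low_expression(counts: pd.DataFrame, min_mean: float = 1.0) -> pd.DataFrame:
    """Drop genes whose mean raw count across samples is below ``min_mean``.

    Returns the retained sub-matrix (same samples). Raises if nothing
    survives, which almost always means the threshold is too high.
    """
    if min_mean < 0:
        raise ValueError("min_mean must be >= 0")
    keep = counts.mean(axis=1) >= min_mean
    out = counts.loc[keep]
    if len(out) == 0:
        raise CountMatrixError(
            f"no gene has mean count >= {min_mean}; lower the filter threshold"
        )
    return out


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    Each sample's counts are compared to a pseudo-reference sample (the
    per-gene geometric mean); the per-sample factor is the median ratio over
    genes with strictly positive counts in every sample. The vector is then
    rescaled so its geometric mean is exactly 1.
    """
    values = counts.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise CountMatrixError(
            "no gene has positive counts in all samples; "
            "filter low-expression genes or check the input"
        )
    log_values = np.log(values[positive])
    log_ref = log_values.mean(axis=1, keepdims=True)  # per-gene geometric mean
    log_factors = np.median(log_values - log_ref, axis=0)
    log_factors -= log_factors.mean()  # geometric mean 1
    return pd.Series(np.exp(log_factors), index=counts.columns, name="size_factor")
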