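"""Reconstruction-fidelity scores: divergence score and delta count.

For original counts ``k`` and reconstructions ``k_hat``:

* ratio        ``L = (k + 1) / (k_hat + 1)``
* divergence   ``D = (L - mean(L)) / sd(L)``, standardized along an axis —
  by default within each gene across samples (population sd; an axis with
  zero spread yields D = 0);
* delta count  ``Delta = log2((k_hat + 1) / (mu_k + 1))`` with ``mu_k`` the
  gene's mean original count (the pseudocount keeps zeros well-defined).

A faithfully reconstructed observation has L near 1, D near 0 and Delta
near the gene's own log-ratio of mean reconstruction to mean count; an
aberrant observation that the autoencoder refuses to reproduce stands out
in both coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ScorePair", "divergence_score", "delta_count", "score_pair"]


@dataclass
class ScorePair:
    """Paired score matrices (genes x samples) plus their building blocks."""

    divergence: pd.DataFrame
    delta: pd.DataFrame
    ratio: pd.DataFrame
    gene_count_means: pd.Series
    axis: str  # standardization axis of the divergence score

    @property
    def gene_ids(self):
        return self.divergence.index

    @property
    def sample_ids(self):
        return self.divergence.columns


def _check_shapes(original: pd.DataFrame, recon: pd.DataFrame):
    if original.shape != recon.shape:
        raise ValueError(
            f"shape mismatch: original {original.shape} vs reconstruction {recon.shape}"
        )
    if not original.index.equals(recon.index) or not original.columns.equals(recon.columns):
        raise ValueError("gene/sample identifiers of original and reconstruction differ")


def divergence_score(
    original: pd.DataFrame, recon: pd.DataFrame, axis: str = "per_gene"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardized reconstruction ratio; returns ``(divergence, ratio)``.

    ``axis='per_gene'`` standardizes each gene's L values across samples
    (the default: every downstream per-gene plot and regression works in
    this frame); ``'per_sample'`` standardizes within each sample instead.
    """
    _check_shapes(original, recon)
    if axis not in ("per_gene", "per_sample"):
        raise ValueError("axis must be 'per_gene' or 'per_sample'")
    k = original.to_numpy(dtype=float)
    k_hat = recon.to_numpy(dtype=float)
    L = (k + 1.0) / (k_hat + 1.0)
    ax = 1 if axis == "per_gene" else 0
    mean = L.mean(axis=ax, keepdims=True)
    sd = L.std(axis=ax, keepdims=True)  # population sd (divisor n)
    n_flat = int((sd == 0.0).sum())
    if n_flat:
        logger.info("%d axes with zero ratio spread; divergence set to 0 there", n_flat)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(sd > 0.0, (L - mean) / np.where(sd > 0.0, sd, 1.0), 0.0)
    idx, cols = original.index, original.columns
    return (
        pd.DataFrame(D, index=idx, columns=cols),
        pd.DataFrame(L, index=idx, columns=cols),
    )


def delta_count(original: pd.DataFrame, recon: pd.DataFrame) -> pd.DataFrame:
    """log2 of reconstruction over the gene's mean original count (pseudocount 1)."""
    _check_shapes(original, recon)
    k_hat = recon.to_numpy(dtype=float)
    mu = original.to_numpy(dtype=float).mean(axis=1)
    delta = np.log2((k_hat + 1.0) / (mu[:, None] + 1.0))
    return pd.DataFrame(delta, index=original.index, columns=original.columns)


def score_pair(
    original: pd.DataFrame, recon: pd.DataFrame, axis: str = "per_gene"
) -> ScorePair:
    """Bundle divergence score and delta count for a matrix pair."""
    D, L = divergence_score(original, recon, axis=axis)
    delta = delta_count(original, recon)
    mu = pd.Series(original.to_numpy(dtype=float).mean(axis=1), index=original.index)
    return ScorePair(divergence=D, delta=delta, ratio=L, gene_count_means=mu, axis=axis)
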