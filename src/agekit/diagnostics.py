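"""Per-gene regression influence diagnostics on the score plane.

For each gene, the delta counts of all samples are regressed (OLS, with
intercept) on their divergence scores. An aberrant sample sits far from the
gene's point cloud, so classical influence and leverage measures of that
single fit flag it:

* ``typeerror`` — internally studentized residual e_i / (s * sqrt(1 - h_i));
* ``hat``       — leverage, the diagonal of the projection (hat) matrix;
* ``dfbetas``   — max over {intercept, slope} of the standardized change in
  the coefficient when observation i is deleted (classical DFBETAS);
* ``cooksD``    — Cook's distance, (t_i^2 / 2) * h_i / (1 - h_i).

All four are computed from closed forms of the simple-regression fit,
vectorized over genes; a leave-one-out refit reproduces them exactly.
DFBETAS scales by the deleted-observation residual sd (the (n-3)-divisor
estimate), so a gene needs at least 4 finite points; genes with fewer
points or a degenerate predictor (no spread in divergence) are excluded
and reported, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scores import ScorePair

__all__ = [
    "GeneRegressionFit",
    "DiagnosticsResult",
    "FEATURES",
    "fit_gene_regression",
    "gene_diagnostics",
    "diagnostics_table",
]

FEATURES = ("typeerror", "dfbetas", "hat", "cooksD")

_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class GeneRegressionFit:
    gene_id: str
    slope: float
    intercept: float
    residual_sd: float
    n_points: int
    degenerate: bool = False


@dataclass
class DiagnosticsResult:
    """Long-format feature table plus per-gene fits and exclusions."""

    table: pd.DataFrame  # columns: gene_id, sample_id, typeerror, dfbetas, hat, cooksD
    fits: pd.DataFrame  # index gene_id: slope, intercept, residual_sd, n_points
    excluded: pd.DataFrame  # index gene_id: reason


def fit_gene_regression(scores: ScorePair, gene_id: str) -> GeneRegressionFit:
    """OLS of a single gene's delta counts on its divergence scores."""
    x = scores.divergence.loc[gene_id].to_numpy(dtype=float)
    y = scores.delta.loc[gene_id].to_numpy(dtype=float)
    finite = np.isfinite(x) & np.isfinite(y)
    x, y = x[finite], y[finite]
    n = len(x)
    if n < 3:
        return GeneRegressionFit(gene_id, np.nan, np.nan, np.nan, n, degenerate=True)
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx <= _DEGENERATE_TOL:
        return GeneRegressionFit(gene_id, np.nan, np.nan, np.nan, n, degenerate=True)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    intercept = y.mean() - slope * x.mean()
    rss = np.sum((y - intercept - slope * x) ** 2)
    return GeneRegressionFit(
        gene_id, float(slope), float(intercept), float(np.sqrt(rss / (n - 2))), n
    )


def _diagnostics_arrays(x: np.ndarray, y: np.ndarray):
    """Closed-form diagnostics for G simultaneous simple regressions.

    x, y: (G, n) arrays. Returns dict of (G, n) arrays plus per-gene slope,
    intercept, residual sd and a validity mask.
    """
    G, n = x.shape
    xbar = x.mean(axis=1, keepdims=True)
    ybar = y.mean(axis=1, keepdims=True)
    dx = x - xbar
    sxx = (dx**2).sum(axis=1, keepdims=True)
    valid = (sxx[:, 0] > _DEGENERATE_TOL) & (n >= 4)

    safe_sxx = np.where(sxx > _DEGENERATE_TOL, sxx, 1.0)
    slope = (dx * (y - ybar)).sum(axis=1, keepdims=True) / safe_sxx
    intercept = ybar - slope * xbar
    e = y - intercept - slope * x
    rss = (e**2).sum(axis=1, keepdims=True)
    s2 = rss / max(n - 2, 1)

    h = 1.0 / n + dx**2 / safe_sxx
    one_minus_h = 1.0 - h
    leverage_point = one_minus_h <= _DEGENERATE_TOL
    safe_omh = np.where(leverage_point, 1.0, one_minus_h)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = e / np.sqrt(s2 * safe_omh)
    t = np.where(s2 > 0.0, t, 0.0)
    t = np.where(leverage_point, np.inf, t)

    cooks = (t**2 / 2.0) * (h / safe_omh)
    cooks = np.where(leverage_point, np.inf, cooks)

    # coefficient change on deleting i: (X'X)^-1 x_i e_i / (1 - h_i)
    sum_x2 = (x**2).sum(axis=1, keepdims=True)
    sum_x = x.sum(axis=1, keepdims=True)
    d0 = (sum_x2 - x * sum_x) * e / (n * safe_sxx * safe_omh)
    d1 = (n * x - sum_x) * e / (n * safe_sxx * safe_omh)
    # deleted-observation residual variance, (n-3) divisor
    s2_del = ((n - 2) * s2 - e**2 / safe_omh) / max(n - 3, 1)
    s2_del = np.clip(s2_del, 0.0, None)
    se0 = np.sqrt(s2_del * (sum_x2 / (n * safe_sxx)))
    se1 = np.sqrt(s2_del / safe_sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        dfb0 = np.where(se0 > 0.0, d0 / se0, np.where(d0 == 0.0, 0.0, np.inf))
        dfb1 = np.where(se1 > 0.0, d1 / se1, np.where(d1 == 0.0, 0.0, np.inf))
    dfbetas = np.maximum(np.abs(dfb0), np.abs(dfb1))
    dfbetas = np.where(leverage_point, np.inf, dfbetas)

    return {
        "typeerror": t,
        "dfbetas": dfbetas,
        "hat": h,
        "cooksD": cooks,
        "slope": slope[:, 0],
        "intercept": intercept[:, 0],
        "residual_sd": np.sqrt(s2[:, 0]) if n > 2 else np.full(G, np.nan),
        "valid": valid,
    }


def gene_diagnostics(scores: ScorePair, gene_id: str) -> pd.DataFrame:
    """Diagnostics rows for a single gene (one row per sample)."""
    x = scores.divergence.loc[[gene_id]].to_numpy(dtype=float)
    y = scores.delta.loc[[gene_id]].to_numpy(dtype=float)
    arrs = _diagnostics_arrays(x, y)
    if not arrs["valid"][0]:
        raise ValueError(f"gene {gene_id!r} is unscorable (degenerate or < 4 points)")
    return pd.DataFrame(
        {
            "gene_id": gene_id,
            "sample_id": scores.sample_ids,
            **{f: arrs[f][0] for f in FEATURES},
        }
    )


def diagnostics_table(scores: ScorePair) -> DiagnosticsResult:
    """Fit every gene and assemble the long-format diagnostics table.

    Genes with a degenerate divergence axis or fewer than 4 samples are
    listed in ``excluded`` with a reason and contribute no rows.
    """
    x = scores.divergence.to_numpy(dtype=float)
    y = scores.delta.to_numpy(dtype=float)
    G, n = x.shape
    if n < 4:
        raise ValueError("diagnostics require at least 4 samples")
    arrs = _diagnostics_arrays(x, y)
    valid = arrs["valid"]

    genes = np.asarray(scores.gene_ids)
    samples = np.asarray(scores.sample_ids)
    vidx = np.nonzero(valid)[0]
    table = pd.DataFrame(
        {
            "gene_id": np.repeat(genes[vidx], n),
            "sample_id": np.tile(samples, len(vidx)),
            **{f: arrs[f][vidx].ravel() for f in FEATURES},
        }
    )
    fits = pd.DataFrame(
        {
            "slope": arrs["slope"][vidx],
            "intercept": arrs["intercept"][vidx],
            "residual_sd": arrs["residual_sd"][vidx],
            "n_points": n,
        },
        index=pd.Index(genes[vidx], name="gene_id"),
    )
    excl_idx = np.nonzero(~valid)[0]
    excluded = pd.DataFrame(
        {"reason": ["degenerate divergence axis"] * len(excl_idx)},
        index=pd.Index(genes[excl_idx], name="gene_id"),
    )
    return DiagnosticsResult(table=table, fits=fits, excluded=excluded)
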