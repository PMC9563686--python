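"""Isolation-forest anomaly scores for (divergence, delta) point clouds.

Each gene's samples form a 2-D cloud on the score plane. An isolation
forest is grown per gene and every observation receives the classic
anomaly score

    s(x) = 2 ** ( -E[h(x)] / c(m) )

where ``E[h(x)]`` is the mean isolation depth over trees and ``c(m)`` the
expected path length of an unsuccessful search in a binary search tree of
``m`` points. Scores live in (0, 1); the closer to 1, the more isolated —
and hence the more severe the aberration. The score replaces a p-value as
the ranking of calls: the method deliberately involves no distributional
test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.ensemble import IsolationForest

from .scores import ScorePair

logger = logging.getLogger(__name__)

__all__ = ["expected_path_length", "isolation_scores", "score_calls"]


def expected_path_length(m: int) -> float:
    """c(m) = 2 H(m-1) - 2 (m-1)/m, with exact harmonic numbers; c(1) = 0."""
    if m <= 1:
        return 0.0
    harmonic = float(np.sum(1.0 / np.arange(1, m)))
    return 2.0 * harmonic - 2.0 * (m - 1) / m


def isolation_scores(
    points: np.ndarray, n_trees: int = 100, subsample: int = 64, seed: int = 0
) -> np.ndarray:
    """Anomaly scores in (0, 1) for an (n, d) point cloud."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = points.shape[0]
    if n < 2:
        raise ValueError("isolation scores require at least 2 points")
    forest = IsolationForest(
        n_estimators=n_trees,
        max_samples=min(subsample, n),
        random_state=seed,
    ).fit(points)
    # sklearn's score_samples returns the negated original-paper score
    return -forest.score_samples(points)


def score_calls(
    scores: ScorePair,
    labeled: pd.DataFrame,
    n_trees: int = 100,
    subsample: int = 64,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach per-gene anomaly scores to classified (gene, sample) points.

    ``labeled`` is a long-format table with columns ``gene_id, sample_id,
    label`` (from :func:`agekit.classify.classify`). Every observation of
    every scorable gene is scored — labels only affect reporting order.
    Returns a call set sorted AGE-first, score-descending, with columns
    ``gene_id, sample_id, label, anomaly_score, divergence, delta``.

    Genes with fewer than 2 samples are excluded (and logged). Per-gene
    forests get distinct seeds derived deterministically from ``seed``.
    """
    D = scores.divergence
    delta = scores.delta
    n_samples = D.shape[1]
    if n_samples < 2:
        raise ValueError("anomaly scoring requires at least 2 samples")

    gene_ids = list(labeled["gene_id"].unique())
    rows = []
    for i, gene in enumerate(gene_ids):
        pts = np.column_stack([D.loc[gene].to_numpy(), delta.loc[gene].to_numpy()])
        gene_seed = (seed * 1000003 + i) % (2**31 - 1)
        rows.append(
            isolation_scores(pts, n_trees=n_trees, subsample=subsample, seed=gene_seed)
        )
    per_obs = pd.DataFrame(
        {
            "gene_id": np.repeat(gene_ids, n_samples),
            "sample_id": np.tile(D.columns.to_numpy(), len(gene_ids)),
            "anomaly_score": np.concatenate(rows),
            "divergence": D.loc[gene_ids].to_numpy().ravel(),
            "delta": delta.loc[gene_ids].to_numpy().ravel(),
        }
    )
    out = labeled.loc[:, ["gene_id", "sample_id", "label"]].merge(
        per_obs, on=["gene_id", "sample_id"], how="left", validate="one_to_one"
    )
    out["_age"] = (out["label"] == "AGE").astype(int)
    out = (
        out.sort_values(["_age", "anomaly_score"], ascending=[False, False], kind="stable")
        .drop(columns="_age")
        .reset_index(drop=True)
    )
    return out
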