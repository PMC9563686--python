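"""Benchmark scoring of predicted aberrations against injection truth.

A prediction counts as a true positive only on an exact (gene, sample)
match with an injected entry. Injections whose corrupted count rounded
back to the original value are undetectable in principle and are removed
from the truth set before scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["BenchmarkResult", "confusion", "pr_curve", "pr_auc", "run_benchmark"]


@dataclass
class BenchmarkResult:
    provenance: dict
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    pr_curves: dict = field(default_factory=dict)  # ranking -> (recall, precision) array
    error: str | None = None


def _truth_pairs(mask: pd.DataFrame, corrupted=None, original=None) -> set:
    """Injected (gene, sample) pairs, dropping collapsed (invisible) ones."""
    m = mask.to_numpy(dtype=bool)
    if corrupted is not None and original is not None:
        m = m & (corrupted.to_numpy() != original.to_numpy())
    rows, cols = np.nonzero(m)
    return {(mask.index[r], mask.columns[c]) for r, c in zip(rows, cols)}


def confusion(pred_pairs, truth_pairs):
    """(tp, fp, fn) between predicted-AGE pairs and injected pairs."""
    pred = set(pred_pairs)
    truth = set(truth_pairs)
    tp = len(pred & truth)
    fp = len(pred - truth)
    fn = len(truth - pred)
    return tp, fp, fn


def _prf(tp, fp, fn):
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return precision, recall, f1


def pr_curve(scores: np.ndarray, is_true: np.ndarray) -> np.ndarray:
    """Precision-recall points sweeping |score| descending, ties as a block.

    Returns an array of (recall, precision) rows, one per distinct absolute
    score; recalls are non-decreasing.
    """
    scores = np.abs(np.asarray(scores, dtype=float))
    is_true = np.asarray(is_true, dtype=bool)
    n_true = int(is_true.sum())
    if n_true == 0:
        raise ValueError("no true positives in the universe; recall undefined")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = is_true[order]
    cum_tp = np.cumsum(t)
    k = np.arange(1, len(s) + 1)
    # last index of each tie block
    block_end = np.nonzero(np.r_[s[1:] != s[:-1], True])[0]
    recall = cum_tp[block_end] / n_true
    precision = cum_tp[block_end] / k[block_end]
    return np.column_stack([recall, precision])


def pr_auc(curve: np.ndarray) -> float:
    """Step-wise area under a (recall, precision) curve (right-continuous)."""
    r = np.r_[0.0, curve[:, 0]]
    p = curve[:, 1]
    return float(np.sum((r[1:] - r[:-1]) * p))


def run_benchmark(grid, detector_factory, rankings=("divergence", "delta", "anomaly")):
    """Run the detection pipeline over labeled datasets and score each one.

    ``detector_factory(dataset)`` must return a fitted detector exposing
    ``predict(counts) -> call set`` (see
    :class:`agekit.detector.AberrationDetector`). Failures are isolated per
    dataset: the result carries an ``error`` and the run continues.
    """
    results = []
    for ds in grid:
        try:
            det = detector_factory(ds)
            calls = det.predict(ds.corrupted)
            truth = _truth_pairs(ds.mask, ds.corrupted, ds.original)
            age = calls[calls["label"] == "AGE"]
            pred = set(zip(age["gene_id"], age["sample_id"]))
            tp, fp, fn = confusion(pred, truth)
            precision, recall, f1 = _prf(tp, fp, fn)
            truth_pairs = set(truth)
            is_true = np.array(
                [
                    (g, s) in truth_pairs
                    for g, s in zip(calls["gene_id"], calls["sample_id"])
                ]
            )
            curves = {}
            if is_true.any():
                for ranking in rankings:
                    col = {"anomaly": "anomaly_score"}.get(ranking, ranking)
                    curves[ranking] = pr_curve(calls[col].to_numpy(), is_true)
            results.append(
                BenchmarkResult(
                    provenance=dict(ds.provenance),
                    tp=tp, fp=fp, fn=fn,
                    precision=precision, recall=recall, f1=f1,
                    pr_curves=curves,
                )
            )
        except Exception as exc:  # noqa: BLE001 - isolate per-dataset failures
            logger.warning("benchmark dataset failed: %s", exc)
            results.append(
                BenchmarkResult(
                    provenance=dict(getattr(ds, "provenance", {})),
                    tp=0, fp=0, fn=0,
                    precision=0.0, recall=0.0, f1=0.0,
                    error=str(exc),
                )
            )
    return results
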