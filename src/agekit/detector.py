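"""End-to-end aberrant-expression detection.

:class:`AberrationDetector` chains the whole method:

supervised phase (``fit``, needs injection labels)
    filter genes -> size factors -> train VAE -> reconstruct -> divergence /
    delta scores -> per-gene regression diagnostics -> CART -> interval rules;

unsupervised phase (``predict``, label-free)
    the same chain up to the diagnostics, then classification by the stored
    (or shipped) interval rules and per-gene isolation-forest anomaly
    scoring of every (gene, sample) observation.

A single ``random_state`` fans out to fixed per-stage offsets (VAE +1,
tree +2, forest +3) so each stage is individually reproducible.
"""

from __future__ import annotations

import importlib.resources
import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .anomaly import score_calls
from .classify import AberrationIntervals, AberrationTreeClassifier, classify
from .diagnostics import diagnostics_table
from .io import estimate_size_factors, filter_low_expression
from .scores import score_pair
from .vae import CountVAE

logger = logging.getLogger(__name__)

__all__ = ["AberrationDetector", "default_intervals"]


def default_intervals() -> AberrationIntervals:
    """The interval rules shipped with the package.

    Trained on a fully synthetic labeled cohort (see the packaged file's
    metadata); a stand-in that lets the unsupervised phase run without a
    labeled dataset of one's own.
    """
    ref = importlib.resources.files("agekit.data") / "default_intervals_synthetic.json"
    return AberrationIntervals.from_json(ref.read_text())


class AberrationDetector(BaseEstimator):
    """Detect aberrant (gene, sample) expression in a count matrix.

    Parameters mirror the stages: ``min_mean`` (low-expression filter),
    the VAE schedule, the CART settings, and the isolation-forest size.
    ``intervals`` may carry pre-trained rules (an
    :class:`~agekit.classify.AberrationIntervals`, a JSON path, or
    ``"default"`` for the shipped synthetic-trained set), in which case
    ``predict`` works without ``fit``.
    """

    def __init__(
        self,
        min_mean: float = 1.0,
        axis: str = "per_gene",
        latent_dim: int = 128,
        hidden_sizes=None,
        epochs: int = 300,
        batch_size=None,
        learning_rate: float = 1e-3,
        kl_weight: float = 50.0,
        early_stopping_patience: int = 30,
        max_depth: int = 6,
        min_samples_leaf: int = 20,
        class_weight="aberration_cost",
        n_trees: int = 100,
        subsample: int = 64,
        relaxed_tau=None,
        intervals=None,
        random_state: int = 0,
    ):
        self.min_mean = min_mean
        self.axis = axis
        self.latent_dim = latent_dim
        self.hidden_sizes = hidden_sizes
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.kl_weight = kl_weight
        self.early_stopping_patience = early_stopping_patience
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.class_weight = class_weight
        self.n_trees = n_trees
        self.subsample = subsample
        self.relaxed_tau = relaxed_tau
        self.intervals = intervals
        self.random_state = random_state

    # -- shared chain ------------------------------------------------------

    def _make_vae(self) -> CountVAE:
        return CountVAE(
            latent_dim=self.latent_dim,
            hidden_sizes=self.hidden_sizes,
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            kl_weight=self.kl_weight,
            early_stopping_patience=self.early_stopping_patience,
            random_state=self.random_state + 1,
        )

    def _reconstruction_chain(self, counts: pd.DataFrame):
        filtered = filter_low_expression(counts, self.min_mean)
        logger.info("filter: %d genes in, %d retained", len(counts), len(filtered))
        sf = estimate_size_factors(filtered)
        vae = self._make_vae().fit(filtered, sf)
        recon = vae.reconstruct()
        scores = score_pair(filtered, recon, axis=self.axis)
        diag = diagnostics_table(scores)
        logger.info(
            "diagnostics: %d observations from %d genes (%d excluded)",
            len(diag.table), len(diag.fits), len(diag.excluded),
        )
        return filtered, sf, vae, scores, diag

    # -- supervised phase --------------------------------------------------

    def fit(self, counts: pd.DataFrame, mask: pd.DataFrame):
        """Train on a labeled (corrupted counts, injection mask) dataset."""
        filtered, sf, vae, scores, diag = self._reconstruction_chain(counts)
        mask = mask.loc[filtered.index, filtered.columns]
        mvals = mask.to_numpy(dtype=bool)
        gidx = filtered.index.get_indexer(diag.table["gene_id"])
        sidx = filtered.columns.get_indexer(diag.table["sample_id"])
        y = mvals[gidx, sidx]

        clf = AberrationTreeClassifier(
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            class_weight=self.class_weight,
            random_state=self.random_state + 2,
        ).fit(diag.table, y)

        self.vae_ = vae
        self._fit_input_ = counts.copy()
        self._fit_filtered_ = filtered
        self.size_factors_ = sf
        self.scores_ = scores
        self.diagnostics_ = diag
        self.classifier_ = clf
        self.intervals_ = clf.intervals_
        leaf_purities = [r.age_fraction for r in clf.intervals_.rules]
        self.training_report_ = {
            "n_observations": int(len(y)),
            "n_age_labels": int(y.sum()),
            "class_balance": float(y.mean()),
            "n_rules": len(clf.intervals_.rules),
            "tree_depth": clf.intervals_.metadata["tree_depth"],
            "leaf_age_fractions": leaf_purities,
            "vae_final_loss": vae.history_[-1] if vae.history_ else None,
        }
        return self

    # -- unsupervised phase ------------------------------------------------

    def _resolve_intervals(self) -> AberrationIntervals:
        if hasattr(self, "intervals_") and self.intervals_ is not None:
            return self.intervals_
        if self.intervals is None:
            raise RuntimeError(
                "no interval rules: call fit() on a labeled dataset, or pass "
                "intervals=... (an AberrationIntervals, a JSON path, or 'default')"
            )
        if isinstance(self.intervals, AberrationIntervals):
            return self.intervals
        if self.intervals == "default":
            return default_intervals()
        return AberrationIntervals.from_json(self.intervals)

    def predict(self, counts: pd.DataFrame) -> pd.DataFrame:
        """Classify every (gene, sample) point of an unlabeled cohort.

        Trains a fresh VAE on ``counts`` (the reconstruction must model
        *this* cohort), applies the stored interval rules, and attaches
        per-gene anomaly scores. Returns the call set sorted AGE-first by
        descending anomaly score; a per-sample AGE-count summary lands in
        ``summary_``.
        """
        intervals = self._resolve_intervals()
        if hasattr(self, "_fit_input_") and self._fit_input_.equals(counts):
            # predicting on the very matrix fit() saw: reuse the fitted chain
            filtered = self._fit_filtered_
            vae, scores, diag = self.vae_, self.scores_, self.diagnostics_
        else:
            filtered, sf, vae, scores, diag = self._reconstruction_chain(counts)
        labeled = classify(diag.table, intervals, relaxed_tau=self.relaxed_tau)
        calls = score_calls(
            scores,
            labeled,
            n_trees=self.n_trees,
            subsample=self.subsample,
            seed=self.random_state + 3,
        )
        self.predict_vae_ = vae
        self.predict_scores_ = scores
        self.predict_diagnostics_ = diag
        age = calls[calls["label"] == "AGE"]
        self.summary_ = (
            age.groupby("sample_id").size().reindex(filtered.columns, fill_value=0)
        )
        logger.info("calls: %d AGE of %d observations", len(age), len(calls))
        return calls

    def encode_latent(self, counts: pd.DataFrame | None = None) -> pd.DataFrame:
        """Latent posterior means of the most recently trained VAE."""
        vae = getattr(self, "predict_vae_", None) or getattr(self, "vae_", None)
        if vae is None:
            raise RuntimeError("no trained VAE; call fit() or predict() first")
        return vae.encode(counts)
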