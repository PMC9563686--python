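"""Variational autoencoder over expression profiles.

Samples (patients) are the observations; genes are the features. Counts are
transformed to per-gene standardized ``log2(k / s + 1)`` values, encoded to
a Gaussian posterior in a low-dimensional latent space (width 128 by
default), and decoded back. Each hidden block is dense -> batch norm -> ELU,
four blocks per side. Training maximizes the usual evidence lower bound:
a Gaussian reconstruction term (squared error on the feature scale, summed
over genes) plus the analytic KL divergence of the posterior from the
standard normal prior, with reparameterized sampling.

Reconstruction and latent encoding use the posterior mean — no sampling —
so every downstream score is deterministic for a trained model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._nn import ELU, Adam, BatchNorm, Dense, Sequential
from .io import estimate_size_factors

__all__ = ["FeatureMatrix", "preprocess", "inverse_preprocess", "CountVAE"]

_LOGVAR_CLIP = 10.0


@dataclass
class FeatureMatrix:
    """Preprocessed expression: samples x genes values plus the inverse map."""

    values: pd.DataFrame  # samples x genes
    gene_mean: pd.Series  # mean of log2(k/s + 1) per gene
    gene_scale: pd.Series  # population sd per gene (1 where sd == 0)
    size_factors: pd.Series
    zero_variance: pd.Series | None = None  # genes constant across samples


def preprocess(counts: pd.DataFrame, size_factors: pd.Series | None = None) -> FeatureMatrix:
    """Per-gene standardized log2(k/s + 1) features (samples x genes)."""
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    sf = size_factors.reindex(counts.columns).to_numpy(dtype=float)
    if np.isnan(sf).any():
        raise ValueError("size factors do not cover all samples")
    u = np.log2(counts.to_numpy(dtype=float) / sf[None, :] + 1.0)  # genes x samples
    mean = u.mean(axis=1)
    raw_scale = u.std(axis=1)
    scale = np.where(raw_scale == 0.0, 1.0, raw_scale)  # constant genes map to 0
    z = (u - mean[:, None]) / scale[:, None]
    return FeatureMatrix(
        values=pd.DataFrame(z.T, index=counts.columns, columns=counts.index),
        gene_mean=pd.Series(mean, index=counts.index),
        gene_scale=pd.Series(scale, index=counts.index),
        size_factors=pd.Series(sf, index=counts.columns, name="size_factor"),
        zero_variance=pd.Series(raw_scale == 0.0, index=counts.index),
    )


def inverse_preprocess(values: np.ndarray, fm: FeatureMatrix) -> np.ndarray:
    """Map samples x genes features back to the log2(k/s + 1) scale (genes x samples).

    Genes that were constant across samples are restored to their constant:
    their standardized feature carries no information, and a constant gene
    is by definition perfectly predictable.
    """
    mean = fm.gene_mean.to_numpy()
    scale = fm.gene_scale.to_numpy()
    u = (values * scale[None, :] + mean[None, :]).T
    if fm.zero_variance is not None:
        zv = fm.zero_variance.to_numpy()
        u[zv, :] = mean[zv, None]
    return u


def _features_to_counts(values: np.ndarray, fm: FeatureMatrix) -> np.ndarray:
    """Features -> non-negative reconstructed counts (genes x samples)."""
    u = inverse_preprocess(values, fm)
    sf = fm.size_factors.to_numpy()
    return np.clip(sf[None, :] * (2.0 ** u - 1.0), 0.0, None)


def _default_hidden(n_genes: int, latent_dim: int) -> list:
    top = max(min(1024, n_genes), latent_dim)
    bottom = max(int(round(1.5 * latent_dim)), latent_dim)
    top = max(top, bottom)
    ratio = (bottom / top) ** (1.0 / 3.0)
    return [max(int(round(top * ratio**k)), 1) for k in range(4)]


class CountVAE(BaseEstimator):
    """Variational autoencoder for RNA-seq count matrices.

    Parameters
    ----------
    latent_dim : width of the latent space (default 128).
    hidden_sizes : encoder hidden widths, input side first; mirrored in the
        decoder. ``None`` -> geometric taper from min(1024, n_genes) down to
        1.5 * latent_dim over four layers.
    batch_norm : insert batch normalization in every hidden block.
    epochs, batch_size, learning_rate : Adam training schedule; batch_size
        ``None`` -> min(32, n_samples).
    kl_weight : multiplier on the KL term of the ELBO.
    early_stopping_patience : stop after this many epochs without improving
        the best epoch loss by ``min_delta``; ``None`` disables.
    random_state : seeds initialization, shuffling and the sampling noise.

    Attributes (after :meth:`fit`)
    ------------------------------
    feature_info_ : the :class:`FeatureMatrix` transform of the training data.
    history_ : per-epoch mean training loss.
    gene_ids_, sample_ids_ : training universe.
    """

    def __init__(
        self,
        latent_dim: int = 128,
        hidden_sizes=None,
        batch_norm: bool = True,
        epochs: int = 300,
        batch_size=None,
        learning_rate: float = 1e-3,
        kl_weight: float = 50.0,
        early_stopping_patience: int = 30,
        min_delta: float = 1e-3,
        random_state: int = 0,
    ):
        self.latent_dim = latent_dim
        self.hidden_sizes = hidden_sizes
        self.batch_norm = batch_norm
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.kl_weight = kl_weight
        self.early_stopping_patience = early_stopping_patience
        self.min_delta = min_delta
        self.random_state = random_state

    # -- architecture ------------------------------------------------------

    def _block(self, n_in, n_out, rng):
        layers = [Dense(n_in, n_out, rng)]
        if self.batch_norm:
            layers.append(BatchNorm(n_out))
        layers.append(ELU())
        return layers

    def _build(self, n_genes: int, rng: np.random.Generator):
        if self.hidden_sizes is None:
            hidden = _default_hidden(n_genes, self.latent_dim)
        else:
            hidden = list(self.hidden_sizes)
        if not hidden:
            raise ValueError("hidden_sizes must be nonempty")
        enc_layers = []
        prev = n_genes
        for h in hidden:
            enc_layers.extend(self._block(prev, h, rng))
            prev = h
        self._encoder = Sequential(enc_layers)
        self._mu_head = Dense(prev, self.latent_dim, rng)
        self._lv_head = Dense(prev, self.latent_dim, rng)
        dec_layers = []
        prev = self.latent_dim
        for h in reversed(hidden):
            dec_layers.extend(self._block(prev, h, rng))
            prev = h
        self._decoder = Sequential(dec_layers)
        self._out_head = Dense(prev, n_genes, rng)
        self.hidden_sizes_ = hidden

    def _all_params(self):
        params = []
        for part in (self._encoder, self._mu_head, self._lv_head, self._decoder, self._out_head):
            params.extend(part.params())
        return params

    def n_parameters(self) -> int:
        """Total number of trainable scalars in the network."""
        return int(sum(p.size for p, _ in self._all_params()))

    # -- training ----------------------------------------------------------

    def fit(self, counts: pd.DataFrame, size_factors: pd.Series | None = None):
        """Train on a genes x samples count matrix."""
        fm = preprocess(counts, size_factors)
        X = fm.values.to_numpy(dtype=float)  # samples x genes
        n_samples, n_genes = X.shape
        if n_samples == 0 or n_genes == 0:
            raise ValueError("empty training matrix")
        rng = np.random.default_rng(self.random_state)
        self._build(n_genes, rng)
        self.feature_info_ = fm
        self.gene_ids_ = list(counts.index)
        self.sample_ids_ = list(counts.columns)

        batch = self.batch_size or min(32, n_samples)
        opt = Adam(self._all_params(), lr=self.learning_rate)
        history = []
        best = np.inf
        stall = 0
        for _ in range(self.epochs):
            order = rng.permutation(n_samples)
            total, seen = 0.0, 0
            for start in range(0, n_samples, batch):
                idx = order[start : start + batch]
                loss = self._train_step(X[idx], opt, rng)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        "non-finite training loss; try a lower learning_rate"
                    )
                total += loss * len(idx)
                seen += len(idx)
            epoch_loss = total / seen
            history.append(epoch_loss)
            if epoch_loss < best - self.min_delta:
                best = epoch_loss
                stall = 0
            else:
                stall += 1
                if (
                    self.early_stopping_patience is not None
                    and stall >= self.early_stopping_patience
                ):
                    break
        self.history_ = history
        return self

    def _train_step(self, x, opt, rng):
        B = x.shape[0]
        h = self._encoder.forward(x, train=True)
        mu = self._mu_head.forward(h, train=True)
        lv_raw = self._lv_head.forward(h, train=True)
        lv = np.clip(lv_raw, -_LOGVAR_CLIP, _LOGVAR_CLIP)
        in_range = (lv_raw > -_LOGVAR_CLIP) & (lv_raw < _LOGVAR_CLIP)
        eps = rng.standard_normal(mu.shape)
        std = np.exp(0.5 * lv)
        z = mu + std * eps
        d = self._decoder.forward(z, train=True)
        xhat = self._out_head.forward(d, train=True)

        diff = xhat - x
        recon = (diff**2).sum() / B  # per-sample sum over genes, batch mean
        kl = -0.5 * (1.0 + lv - mu**2 - np.exp(lv)).sum() / B
        loss = recon + self.kl_weight * kl

        dxhat = 2.0 * diff / B
        dz = self._decoder.backward(self._out_head.backward(dxhat))
        dmu = dz + self.kl_weight * mu / B
        dlv = dz * eps * 0.5 * std + self.kl_weight * 0.5 * (np.exp(lv) - 1.0) / B
        dlv = np.where(in_range, dlv, 0.0)
        dh = self._mu_head.backward(dmu) + self._lv_head.backward(dlv)
        self._encoder.backward(dh)
        opt.step()
        return float(loss)

    # -- inference ---------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "feature_info_"):
            raise RuntimeError("CountVAE is not fitted")

    def _features_for(self, counts, size_factors):
        """Features for new samples using the *training* per-gene transform."""
        if counts is None:
            return self.feature_info_, self.feature_info_.values.to_numpy(dtype=float)
        missing = [g for g in self.gene_ids_ if g not in counts.index]
        if missing:
            raise ValueError(f"gene set mismatch; missing {missing[:5]} ...")
        counts = counts.loc[self.gene_ids_]
        if size_factors is None:
            size_factors = estimate_size_factors(counts)
        sf = size_factors.reindex(counts.columns).to_numpy(dtype=float)
        u = np.log2(counts.to_numpy(dtype=float) / sf[None, :] + 1.0)
        mean = self.feature_info_.gene_mean.to_numpy()
        scale = self.feature_info_.gene_scale.to_numpy()
        z = ((u - mean[:, None]) / scale[:, None]).T
        fm = FeatureMatrix(
            values=pd.DataFrame(z, index=counts.columns, columns=self.gene_ids_),
            gene_mean=self.feature_info_.gene_mean,
            gene_scale=self.feature_info_.gene_scale,
            size_factors=pd.Series(sf, index=counts.columns, name="size_factor"),
            zero_variance=self.feature_info_.zero_variance,
        )
        return fm, z

    def _decode_mean(self, x):
        h = self._encoder.forward(x, train=False)
        mu = self._mu_head.forward(h, train=False)
        d = self._decoder.forward(mu, train=False)
        return mu, self._out_head.forward(d, train=False)

    def reconstruct(
        self, counts: pd.DataFrame | None = None, size_factors: pd.Series | None = None
    ) -> pd.DataFrame:
        """Reconstructed counts k-hat (genes x samples, non-negative reals).

        With no arguments, reconstructs the training matrix. The decoder is
        driven by the posterior mean, and the output is mapped back to the
        count scale through the stored per-gene transform:
        ``k_hat = s * (2**u_hat - 1)`` clipped at 0.
        """
        self._check_fitted()
        fm, X = self._features_for(counts, size_factors)
        _, xhat = self._decode_mean(X)
        k_hat = _features_to_counts(xhat, fm)
        return pd.DataFrame(k_hat, index=self.gene_ids_, columns=fm.values.index)

    def encode(
        self, counts: pd.DataFrame | None = None, size_factors: pd.Series | None = None
    ) -> pd.DataFrame:
        """Posterior latent means, samples x latent_dim."""
        self._check_fitted()
        fm, X = self._features_for(counts, size_factors)
        h = self._encoder.forward(X, train=False)
        mu = self._mu_head.forward(h, train=False)
        cols = [f"latent_{k}" for k in range(self.latent_dim)]
        return pd.DataFrame(mu, index=fm.values.index, columns=cols)
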