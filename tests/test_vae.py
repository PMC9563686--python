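import numpy as np
import pandas as pd
import pytest
from scipy import stats

import agekit as ak
from agekit.vae import FeatureMatrix, inverse_preprocess, preprocess

from conftest import random_counts


class TestPreprocess:
    def test_constant_gene_maps_to_zeros(self):
        counts = pd.DataFrame({"a": [5, 1], "b": [5, 9], "c": [5, 3]},
                              index=["flat", "var"])
        fm = preprocess(counts, pd.Series(1.0, index=counts.columns))
        np.testing.assert_allclose(fm.values["flat"].to_numpy(), 0.0)

    def test_round_trip_on_log_scale(self, rng):
        counts = random_counts(rng, 30, 12)
        fm = preprocess(counts)
        u_back = inverse_preprocess(fm.values.to_numpy(), fm)
        sf = fm.size_factors.to_numpy()
        u_true = np.log2(counts.to_numpy() / sf[None, :] + 1.0)
        assert np.abs(u_back - u_true).max() < 1e-9

    def test_direct_formula_single_entry(self):
        counts = pd.DataFrame({"a": [3, 8], "b": [1, 8], "c": [0, 8]},
                              index=["g", "flat"])
        fm = preprocess(counts, pd.Series(1.0, index=counts.columns))
        u = np.log2(np.array([3, 1, 0]) + 1.0)
        expected = (np.log2(4) - u.mean()) / u.std()
        assert fm.values.loc["a", "g"] == pytest.approx(expected, rel=1e-12)


class TestArchitecture:
    def test_parameter_count_matches_formula(self):
        vae = ak.CountVAE(latent_dim=4, hidden_sizes=[16, 8], batch_norm=True,
                          epochs=0, random_state=0)
        vae.fit(random_counts(np.random.default_rng(0), 20, 6))
        n_genes, hidden, latent = 20, [16, 8], 4

        def dense(i, o):
            return i * o + o

        def bn(o):
            return 2 * o

        expected = 0
        prev = n_genes
        for h in hidden:  # encoder
            expected += dense(prev, h) + bn(h)
            prev = h
        expected += 2 * dense(prev, latent)  # mu and logvar heads
        prev = latent
        for h in reversed(hidden):  # decoder
            expected += dense(prev, h) + bn(h)
            prev = h
        expected += dense(prev, n_genes)
        assert vae.n_parameters() == expected

    def test_latent_output_width_matches_config(self, trained_vae):
        z = trained_vae.encode()
        assert z.shape[1] == trained_vae.latent_dim

    def test_empty_hidden_sizes_rejected(self, rng):
        with pytest.raises(ValueError):
            ak.CountVAE(hidden_sizes=[], epochs=1).fit(random_counts(rng, 10, 4))


class TestTraining:
    def test_zero_epochs_empty_history(self, rng):
        vae = ak.CountVAE(epochs=0, latent_dim=2, hidden_sizes=[8])
        vae.fit(random_counts(rng, 15, 5))
        assert vae.history_ == []

    def test_same_seed_identical_loss_history(self, rng):
        counts = random_counts(rng, 40, 10)
        h = [
            ak.CountVAE(latent_dim=4, hidden_sizes=[16], epochs=10,
                        random_state=5).fit(counts).history_
            for _ in range(2)
        ]
        assert h[0] == h[1]

    def test_loss_decreases_on_smoke_run(self, trained_vae):
        assert trained_vae.history_[-1] < 0.9 * trained_vae.history_[0]

    def test_unconstrained_model_approaches_autoencoding_limit(self, rng):
        # kl_weight 0 and latent >= genes: tiny data is nearly memorized
        counts = random_counts(rng, 6, 12)
        vae = ak.CountVAE(latent_dim=8, hidden_sizes=[32, 16], kl_weight=0.0,
                          epochs=400, early_stopping_patience=None,
                          random_state=2).fit(counts)
        feats = vae.feature_info_.values.to_numpy()
        _, xhat = vae._decode_mean(feats)
        assert np.mean((xhat - feats) ** 2) < 0.1


class TestReconstruct:
    def test_untrained_reconstruction_finite_nonnegative(self, rng):
        counts = random_counts(rng, 25, 8)
        vae = ak.CountVAE(epochs=0, latent_dim=4, hidden_sizes=[8]).fit(counts)
        r = vae.reconstruct()
        assert np.isfinite(r.to_numpy()).all()
        assert (r.to_numpy() >= 0).all()
        assert r.shape == counts.shape

    def test_constant_data_reconstructed_exactly(self):
        # constant genes have zero-variance features; the inverse transform
        # restores the constants regardless of the decoder output
        counts = pd.DataFrame(
            np.tile([[4], [9]], (1, 5)), index=["g1", "g2"],
            columns=[f"s{i}" for i in range(5)],
        )
        vae = ak.CountVAE(latent_dim=2, hidden_sizes=[4], epochs=50,
                          random_state=3).fit(counts, pd.Series(1.0, index=counts.columns))
        r = vae.reconstruct()
        np.testing.assert_allclose(r.to_numpy(), counts.to_numpy(), atol=1e-6)

    def test_median_gene_correlation_positive(self, labeled_small, trained_vae):
        k = labeled_small.corrupted.to_numpy(dtype=float)
        kh = trained_vae.reconstruct().to_numpy()
        cors = [
            stats.pearsonr(k[g], kh[g])[0]
            for g in range(k.shape[0])
            if k[g].std() > 0 and kh[g].std() > 0
        ]
        assert np.median(cors) > 0

    def test_gene_set_mismatch_raises(self, trained_vae, rng):
        other = random_counts(rng, 5, 4)
        with pytest.raises(ValueError, match="gene set"):
            trained_vae.reconstruct(other)


class TestEncode:
    def test_repeated_encode_bitwise_identical(self, trained_vae):
        a = trained_vae.encode()
        b = trained_vae.encode()
        pd.testing.assert_frame_equal(a, b)

    def test_duplicate_samples_identical_latents(self, labeled_small, trained_vae):
        counts = labeled_small.corrupted
        dup = pd.concat(
            [counts.iloc[:, :2], counts.iloc[:, :2].set_axis(["d1", "d2"], axis=1)],
            axis=1,
        )
        sf = pd.Series(1.0, index=dup.columns)
        z = trained_vae.encode(dup, sf)
        np.testing.assert_allclose(
            z.iloc[0].to_numpy(), z.iloc[2].to_numpy(), rtol=1e-12
        )

    def test_latent_separates_two_group_covariate(self):
        spec = ak.CohortSpec(
            n_samples=50, n_genes=500, seed=21,
            covariate_effects=(ak.CovariateEffect("group", ("A", "B"), 0.2, 1.0),),
        )
        counts, cov, sf = ak.generate_cohort(spec)
        vae = ak.CountVAE(latent_dim=8, epochs=120, random_state=22).fit(counts, sf)
        z = vae.encode()
        g = (cov["group"] == "B").astype(float).to_numpy()
        best = max(abs(stats.pointbiserialr(g, z[c])[0]) for c in z.columns)
        assert best > 0.5
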