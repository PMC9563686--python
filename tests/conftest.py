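"""Shared fixtures: small synthetic cohorts and a trained VAE.

Everything is generated programmatically with fixed seeds; the expensive
objects (trained VAE, injected cohort) are session-scoped and reused.
"""

import numpy as np
import pandas as pd
import pytest

import agekit as ak


@pytest.fixture(scope="session")
def small_cohort():
    """40 samples x 300 genes NB cohort with true size factors."""
    spec = ak.CohortSpec(n_samples=40, n_genes=300, seed=101)
    counts, covariates, sf = ak.generate_cohort(spec)
    return counts, covariates, sf


@pytest.fixture(scope="session")
def labeled_small(small_cohort):
    """The small cohort corrupted at probability 2e-3 (~24 injections)."""
    counts, _, sf = small_cohort
    return ak.inject_aberrations(
        counts, ak.InjectionParams(probability=2e-3, seed=102), sf
    )


@pytest.fixture(scope="session")
def trained_vae(labeled_small):
    """A VAE trained on the corrupted small cohort (modest schedule)."""
    vae = ak.CountVAE(latent_dim=8, epochs=120, random_state=103)
    vae.fit(labeled_small.corrupted)
    return vae


@pytest.fixture(scope="session")
def small_scores(labeled_small, trained_vae):
    recon = trained_vae.reconstruct()
    return ak.score_pair(labeled_small.corrupted, recon)


def random_counts(rng, n_genes, n_samples, lam=50):
    """Helper: small random Poisson count matrix as a DataFrame."""
    vals = rng.poisson(lam, size=(n_genes, n_samples))
    return pd.DataFrame(
        vals,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(7)
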