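import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import agekit as ak


class TestGenerateCohort:
    def test_determinism(self):
        spec = ak.CohortSpec(n_samples=10, n_genes=50, seed=3)
        a, _, _ = ak.generate_cohort(spec)
        b, _, _ = ak.generate_cohort(spec)
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_spec_concentrates_on_shared_mean(self):
        spec = ak.CohortSpec(
            n_samples=400, n_genes=30, mean_log_mu=math.log(100), sd_log_mu=0.0,
            dispersion=1e-4, size_factor_sd=0.0, seed=4,
        )
        counts, _, sf = ak.generate_cohort(spec)
        np.testing.assert_allclose(sf.to_numpy(), 1.0)
        means = counts.mean(axis=1).to_numpy()
        # CLT: per-gene sample means within a few sd/sqrt(n) of mu = 100
        assert np.all(np.abs(means - 100) < 5)

    def test_nb_moment_relationship(self):
        spec = ak.CohortSpec(
            n_samples=100, n_genes=2000, dispersion=0.1, size_factor_sd=0.0, seed=6
        )
        counts, _, _ = ak.generate_cohort(spec)
        k = counts.to_numpy(dtype=float)
        mu = k.mean(axis=1)
        var = k.var(axis=1, ddof=1)
        expected = mu + 0.1 * mu**2
        ok = mu > 5  # skip near-zero genes where the ratio is unstable
        ratio = var[ok] / expected[ok]
        assert abs(np.median(ratio) - 1.0) < 0.2

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            ak.CohortSpec(n_samples=0)

    def test_covariates_returned_with_assignments(self):
        spec = ak.CohortSpec(
            n_samples=30, n_genes=40, seed=8,
            covariate_effects=(ak.CovariateEffect("sex", ("F", "M")),),
        )
        _, cov, _ = ak.generate_cohort(spec)
        assert set(cov["sex"]) <= {"F", "M"}
        assert len(cov) == 30


class TestInjectAberrations:
    def test_probability_zero_is_noop(self, small_cohort):
        counts, _, sf = small_cohort
        ds = ak.inject_aberrations(counts, ak.InjectionParams(probability=0.0), sf)
        pd.testing.assert_frame_equal(ds.corrupted, counts)
        assert not ds.mask.to_numpy().any()

    def test_untouched_entries_bit_identical(self, labeled_small):
        m = labeled_small.mask.to_numpy()
        orig = labeled_small.original.to_numpy()
        corr = labeled_small.corrupted.to_numpy()
        assert np.array_equal(orig[~m], corr[~m])

    def test_direction_consistency(self, labeled_small):
        m = labeled_small.mask.to_numpy()
        orig = labeled_small.original.to_numpy()
        corr = labeled_small.corrupted.to_numpy()
        d = labeled_small.direction.to_numpy()
        up = (d == 1) & m
        down = (d == -1) & m
        collapsed = (corr == orig) & m
        assert np.all(corr[up & ~collapsed] > orig[up & ~collapsed])
        assert np.all(corr[down & ~collapsed] < orig[down & ~collapsed])
        assert collapsed.sum() == labeled_small.n_collapsed

    def test_determinism(self, small_cohort):
        counts, _, sf = small_cohort
        p = ak.InjectionParams(probability=5e-3, seed=9)
        a = ak.inject_aberrations(counts, p, sf)
        b = ak.inject_aberrations(counts, p, sf)
        pd.testing.assert_frame_equal(a.corrupted, b.corrupted)
        pd.testing.assert_frame_equal(a.mask, b.mask)

    def test_realized_fraction_within_binomial_interval(self):
        spec = ak.CohortSpec(n_samples=100, n_genes=5000, seed=10)
        counts, _, sf = ak.generate_cohort(spec)
        p = 1e-3
        ds = ak.inject_aberrations(
            counts, ak.InjectionParams(probability=p, seed=11), sf
        )
        n = counts.size
        hits = int(ds.mask.to_numpy().sum()) + ds.n_skipped_zero_sd
        lo, hi = stats.binom.interval(0.999, n, p)
        assert lo <= hits <= hi

    def test_amplitude_law(self):
        params = ak.InjectionParams(seed=12)
        amps = ak.simulate.sample_amplitudes(100_000, params)
        logs = np.log(amps)
        se = math.log(1.6) / math.sqrt(len(logs))
        assert abs(logs.mean() - math.log(3)) < 3 * se
        assert abs(logs.std(ddof=1) - math.log(1.6)) < 3 * se

    def test_zero_variance_gene_never_injected(self):
        counts = pd.DataFrame(
            {"a": [5, 10], "b": [5, 20], "c": [5, 30]}, index=["flat", "varying"]
        )
        sf = pd.Series(1.0, index=counts.columns)
        ds = ak.inject_aberrations(
            counts, ak.InjectionParams(probability=1.0, seed=13), sf
        )
        assert not ds.mask.loc["flat"].any()
        assert (ds.corrupted.loc["flat"] == 5).all()
        assert ds.n_skipped_zero_sd == 3


class TestBenchmarkGrid:
    def test_full_grid_cardinality(self):
        grid = ak.build_benchmark_grid(
            ak.CohortSpec(n_genes=100, seed=14),
            sizes=(50, 75, 125, 250, 500, 1000),
            probabilities=(1e-6, 1e-5, 1e-4),
            seed=15,
        )
        assert len(grid) == 18
        sizes = sorted({d.provenance["size"] for d in grid})
        assert sizes == [50, 75, 125, 250, 500, 1000]

    def test_single_cell_grid(self):
        grid = ak.build_benchmark_grid(
            ak.CohortSpec(n_genes=50, seed=16), sizes=(20,), probabilities=(1e-3,)
        )
        assert len(grid) == 1
        assert grid[0].corrupted.shape == (50, 20)

    def test_mask_density_within_binomial_tolerance(self):
        grid = ak.build_benchmark_grid(
            ak.CohortSpec(n_genes=2000, seed=17), sizes=(200,), probabilities=(2e-3,)
        )
        ds = grid[0]
        n = ds.mask.size
        hits = int(ds.mask.to_numpy().sum()) + ds.n_skipped_zero_sd
        lo, hi = stats.binom.interval(0.999, n, 2e-3)
        assert lo <= hits <= hi

    def test_fixed_cohort_source_and_oversize_rejection(self, small_cohort):
        counts, _, _ = small_cohort
        grid = ak.build_benchmark_grid(counts, sizes=(10,), probabilities=(1e-2,))
        assert grid[0].corrupted.shape == (counts.shape[0], 10)
        with pytest.raises(ValueError, match="exceeds"):
            ak.build_benchmark_grid(counts, sizes=(500,), probabilities=(1e-3,))


class TestSubsampleSmallDatasets:
    def test_protocol_cardinality(self, small_cohort):
        counts, _, _ = small_cohort
        keep = list(counts.columns[:6])
        out = ak.subsample_small_datasets(
            counts, keep, sizes=(30, 25, 20, 15, 10, 6), replicates=10, seed=19
        )
        assert len(out) == 60

    def test_keep_samples_always_present_and_unique(self, small_cohort):
        counts, _, _ = small_cohort
        keep = list(counts.columns[:6])
        out = ak.subsample_small_datasets(
            counts, keep, sizes=(20, 10), replicates=5, seed=20
        )
        for ds in out:
            assert set(keep) <= set(ds.columns)
            assert len(set(ds.columns)) == len(ds.columns)

    def test_size_equal_to_keep_is_constant(self, small_cohort):
        counts, _, _ = small_cohort
        keep = list(counts.columns[:6])
        out = ak.subsample_small_datasets(counts, keep, sizes=(6,), replicates=3)
        for ds in out:
            assert list(ds.columns) == keep

    def test_too_small_size_rejected(self, small_cohort):
        counts, _, _ = small_cohort
        with pytest.raises(ValueError):
            ak.subsample_small_datasets(
                counts, list(counts.columns[:6]), sizes=(5,), replicates=1
            )
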