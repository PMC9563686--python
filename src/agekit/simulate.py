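"""Synthetic RNA-seq cohorts and artificial aberrant-expression injection.

The injection model replaces a randomly selected count ``k_ij`` (gene *j*,
sample *i*) by::

    k_ij' = round( s_i * 2 ** (mu_j_u  +/-  exp(N) * sigma_j_u) )

where ``u = log2(k / s + 1)`` is the size-factor-normalized log profile,
``mu_j_u`` / ``sigma_j_u`` are its per-gene mean and standard deviation
across samples, and the z-score amplitude ``exp(N)`` is log-normal with
``N ~ Normal(log 3, log 1.6)`` — so the median injected aberration sits
three standard deviations away from the gene's mean profile. Entries are
selected i.i.d. with a small per-entry probability (1e-6 .. 1e-4 in the
benchmark grids), the direction (up/down) is a fair coin, and replacements
are clipped at zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import estimate_size_factors

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSpec",
    "CovariateEffect",
    "InjectionParams",
    "LabeledDataset",
    "generate_cohort",
    "inject_aberrations",
    "sample_amplitudes",
    "build_benchmark_grid",
    "subsample_small_datasets",
]


@dataclass(frozen=True)
class CovariateEffect:
    """A categorical sample covariate that shifts part of the transcriptome.

    Samples are assigned uniformly at random to ``levels``; genes in a
    random ``affected_fraction`` of the transcriptome are multiplied by
    ``2 ** log2_fc`` in every non-reference level (reference = first level).
    """

    name: str
    levels: tuple = ("A", "B")
    affected_fraction: float = 0.2
    log2_fc: float = 1.0


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a negative-binomial RNA-seq cohort.

    Gene means are log-normal (``mean_log_mu``, ``sd_log_mu`` on the natural
    log scale); counts are NB with variance ``mu + dispersion * mu**2``;
    per-sample size factors are log-normal with sd ``size_factor_sd``,
    normalized to geometric mean 1.
    """

    n_samples: int = 100
    n_genes: int = 2000
    mean_log_mu: float = math.log(200.0)
    sd_log_mu: float = 1.5
    dispersion: float = 0.1
    size_factor_sd: float = 0.2
    covariate_effects: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_samples <= 0 or self.n_genes <= 0:
            raise ValueError("n_samples and n_genes must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.size_factor_sd < 0:
            raise ValueError("size_factor_sd must be >= 0")


@dataclass(frozen=True)
class InjectionParams:
    """Corruption parameters: per-entry probability and amplitude law."""

    probability: float = 1e-4
    amplitude_meanlog: float = math.log(3.0)
    amplitude_sdlog: float = math.log(1.6)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")
        if self.amplitude_sdlog <= 0:
            raise ValueError("amplitude_sdlog must be > 0")


@dataclass
class LabeledDataset:
    """A corrupted count matrix with its injection ground truth.

    ``mask`` is True exactly where a count was replaced; ``direction`` holds
    +1 (up), -1 (down) or 0 (untouched). ``n_collapsed`` counts selected
    entries whose replacement rounded back to the original value (they stay
    in the mask — the corruption was applied, it just had no visible
    effect); ``n_skipped_zero_sd`` counts selections dropped because the
    gene had zero profile variance (excluded from the mask).
    """

    corrupted: pd.DataFrame
    mask: pd.DataFrame
    original: pd.DataFrame
    direction: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    n_collapsed: int = 0
    n_skipped_zero_sd: int = 0


def generate_cohort(spec: CohortSpec):
    """Draw a synthetic cohort.

    Returns ``(counts, covariates, size_factors)``: a genes x samples
    integer DataFrame, a sample-indexed covariate DataFrame (empty if the
    spec has no covariate effects) and the true size factors used.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"g{j:05d}" for j in range(spec.n_genes)]
    sample_ids = [f"s{i:04d}" for i in range(spec.n_samples)]

    mu = rng.lognormal(spec.mean_log_mu, spec.sd_log_mu, size=spec.n_genes)
    if spec.size_factor_sd > 0:
        log_sf = rng.normal(0.0, spec.size_factor_sd, size=spec.n_samples)
        log_sf -= log_sf.mean()
    else:
        log_sf = np.zeros(spec.n_samples)
    sf = np.exp(log_sf)

    log2_shift = np.zeros((spec.n_genes, spec.n_samples))
    cov_data = {}
    for eff in spec.covariate_effects:
        assign = rng.integers(0, len(eff.levels), size=spec.n_samples)
        cov_data[eff.name] = [eff.levels[a] for a in assign]
        affected = rng.random(spec.n_genes) < eff.affected_fraction
        log2_shift += np.outer(affected * eff.log2_fc, (assign > 0).astype(float))

    mean = sf[None, :] * mu[:, None] * 2.0 ** log2_shift
    # NB with var = m + dispersion * m^2:  n = 1/dispersion, p = n/(n+m)
    n_param = 1.0 / spec.dispersion
    p_param = n_param / (n_param + mean)
    counts = rng.negative_binomial(n_param, p_param)

    counts_df = pd.DataFrame(counts.astype(np.int64), index=gene_ids, columns=sample_ids)
    cov_df = pd.DataFrame(cov_data, index=sample_ids)
    sf_series = pd.Series(sf, index=sample_ids, name="size_factor")
    return counts_df, cov_df, sf_series


def sample_amplitudes(n: int, params: InjectionParams, rng=None) -> np.ndarray:
    """Draw ``n`` aberration amplitudes ``exp(N)``, N ~ Normal(meanlog, sdlog)."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    return np.exp(rng.normal(params.amplitude_meanlog, params.amplitude_sdlog, size=n))


def inject_aberrations(
    counts: pd.DataFrame,
    params: InjectionParams,
    size_factors: pd.Series | None = None,
) -> LabeledDataset:
    """Corrupt a count matrix with artificial aberrant-expression events.

    If ``size_factors`` is omitted they are estimated from ``counts`` by
    median-of-ratios. Deterministic given ``params.seed``.
    """
    if counts.size == 0:
        raise ValueError("cannot inject into an empty matrix")
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    sf = size_factors.reindex(counts.columns).to_numpy(dtype=float)
    if np.isnan(sf).any():
        raise ValueError("size factors do not cover all samples")

    rng = np.random.default_rng(params.seed)
    k = counts.to_numpy(dtype=float)
    u = np.log2(k / sf[None, :] + 1.0)
    mu_u = u.mean(axis=1)
    sd_u = u.std(axis=1)  # population sd, consistent with the score module

    selected = rng.random(k.shape) < params.probability
    n_sel = int(selected.sum())
    corrupted = k.copy()
    direction = np.zeros(k.shape, dtype=np.int8)
    mask = np.zeros(k.shape, dtype=bool)
    n_collapsed = 0
    n_skipped = 0

    if n_sel:
        rows, cols = np.nonzero(selected)
        amplitude = sample_amplitudes(n_sel, params, rng)
        sign = rng.choice([-1.0, 1.0], size=n_sel)
        zero_sd = sd_u[rows] == 0.0
        n_skipped = int(zero_sd.sum())
        if n_skipped:
            logger.info("skipping %d injections into zero-variance genes", n_skipped)
        ok = ~zero_sd
        rows, cols = rows[ok], cols[ok]
        amplitude, sign = amplitude[ok], sign[ok]
        new_u = mu_u[rows] + sign * amplitude * sd_u[rows]
        new_k = np.round(np.clip(sf[cols] * 2.0 ** new_u, 0.0, None))
        n_collapsed = int((new_k == k[rows, cols]).sum())
        corrupted[rows, cols] = new_k
        mask[rows, cols] = True
        direction[rows, cols] = np.where(sign > 0, 1, -1)

    out = LabeledDataset(
        corrupted=pd.DataFrame(
            corrupted.astype(np.int64), index=counts.index, columns=counts.columns
        ),
        mask=pd.DataFrame(mask, index=counts.index, columns=counts.columns),
        original=counts.copy(),
        direction=pd.DataFrame(direction, index=counts.index, columns=counts.columns),
        provenance={
            "probability": params.probability,
            "amplitude_meanlog": params.amplitude_meanlog,
            "amplitude_sdlog": params.amplitude_sdlog,
            "seed": params.seed,
        },
        n_collapsed=n_collapsed,
        n_skipped_zero_sd=n_skipped,
    )
    return out


def build_benchmark_grid(
    base: CohortSpec,
    sizes=(50, 75, 125, 250, 500, 1000),
    probabilities=(1e-6, 1e-5, 1e-4),
    seed: int = 0,
) -> list:
    """Build the full benchmark grid: one corrupted dataset per (size, probability).

    ``base`` is either a :class:`CohortSpec` — a cohort of at least
    ``max(sizes)`` samples is generated from it — or a fixed count matrix
    to subsample directly. Each dataset subsamples the cohort to ``size``
    samples and injects with the given probability. With the default six
    sizes and three probabilities this yields 18 datasets.
    """
    sizes = list(sizes)
    probabilities = list(probabilities)
    if not sizes or not probabilities:
        raise ValueError("sizes and probabilities must be nonempty")
    if isinstance(base, pd.DataFrame):
        counts = base
        sf = estimate_size_factors(counts)
    else:
        import dataclasses

        spec = dataclasses.replace(base, n_samples=max(max(sizes), base.n_samples))
        counts, _, sf = generate_cohort(spec)
    if max(sizes) > counts.shape[1]:
        raise ValueError(
            f"requested size {max(sizes)} exceeds the {counts.shape[1]} "
            "available samples of the fixed cohort"
        )

    rng = np.random.default_rng(seed)
    datasets = []
    for size in sizes:
        for prob in probabilities:
            cols = rng.choice(counts.shape[1], size=size, replace=False)
            cols.sort()
            sub = counts.iloc[:, cols]
            sub_sf = sf.iloc[cols]
            sub_sf = sub_sf / np.exp(np.log(sub_sf).mean())
            inj_seed = int(rng.integers(0, 2**31 - 1))
            ds = inject_aberrations(
                sub, InjectionParams(probability=prob, seed=inj_seed), sub_sf
            )
            ds.provenance.update({"size": size, "grid_seed": seed})
            datasets.append(ds)
    return datasets


def subsample_small_datasets(
    counts: pd.DataFrame,
    keep_samples,
    sizes=(110, 90, 60, 30, 20, 10),
    replicates: int = 10,
    seed: int = 0,
) -> list:
    """Random sub-cohorts that always retain a fixed set of samples.

    For each target size, draw ``replicates`` datasets containing every id
    in ``keep_samples`` plus a random complement (without replacement) from
    the remaining samples. Mirrors the small-cohort ablation protocol: six
    sizes x 10 replicates = 60 datasets.
    """
    keep_samples = list(keep_samples)
    missing = [s for s in keep_samples if s not in counts.columns]
    if missing:
        raise ValueError(f"keep_samples not in matrix: {missing}")
    if min(sizes) < len(keep_samples):
        raise ValueError("smallest size is below the number of kept samples")
    others = [s for s in counts.columns if s not in keep_samples]
    rng = np.random.default_rng(seed)
    out = []
    for size in sizes:
        extra = size - len(keep_samples)
        if extra > len(others):
            raise ValueError(f"size {size} exceeds available samples")
        for _ in range(replicates):
            chosen = list(rng.choice(others, size=extra, replace=False))
            cols = keep_samples + chosen
            out.append(counts.loc[:, cols])
    return out
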