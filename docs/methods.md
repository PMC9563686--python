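# Methods

This note documents the models, defaults and numerical conventions behind
`agekit`, the design choices that were genuinely open, and what the
synthetic benchmarks do and do not demonstrate.

## The detection model

The method treats aberrant gene expression (AGE) as a *reconstruction
failure*. A variational autoencoder (VAE) is trained on the cohort's
expression profiles; because its latent bottleneck forces the model to
encode only structure shared across samples, a single aberrant
(gene, sample) entry is not worth the capacity it would cost, and its
reconstruction reverts toward the cohort's expectation. The gap between
original and reconstructed counts, summarized by two scores and four
regression-influence features, is then classified by a decision tree whose
root-to-leaf paths act as explicit, portable threshold intervals. No
distributional test is involved anywhere; severity is ranked by an
isolation-forest anomaly score instead of a p-value.

## Preprocessing

- Low-expression filter: genes with mean raw count < `min_mean` (default
  1.0) are removed. Lowly expressed genes carry almost no signal but
  produce unstable count ratios.
- Size factors: DESeq-style median-of-ratios against the per-gene
  geometric-mean pseudo-reference, over genes positive in all samples,
  rescaled to geometric mean 1. The per-sample factor `s_i` (dimensionless)
  captures sequencing depth.
- VAE input: per-gene standardized `u = log2(k/s + 1)`. The transform is
  stored and exactly invertible; zero-variance genes map to a zero feature
  and are restored to their constant on inversion (a constant gene is
  perfectly predictable by definition). The standard deviation convention
  is the population sd (divisor *n*) throughout the package.

## The variational autoencoder

Architecture: encoder `n_genes → h1 → h2 → h3 → h4 → (μ, log σ²)` with
latent width 128; decoder mirrors the encoder; every hidden block is
dense → batch normalization → ELU. Default hidden widths taper
geometrically from `min(1024, n_genes)` down to `1.5 × latent_dim`
(e.g. 1024, 587, 336, 192 for a few thousand genes). Training uses the
reparameterized ELBO — squared reconstruction error on the feature scale
(summed over genes, averaged over the batch) plus `kl_weight ×` the
analytic KL of the posterior from N(0, I) — with Adam (lr 1e-3), batch
size `min(32, n)`, up to 300 epochs, early stopping after 30 epochs
without improvement. Log-variances are clipped to ±10 for numerical
safety. The implementation is plain numpy with hand-written
backpropagation; training is single-threaded and bitwise reproducible
given the seed, and inference (reconstruction, latent encoding) uses
the posterior mean and batch-norm running statistics, so repeated calls
agree exactly.

**KL weight (default 50).** This is the load-bearing regularizer. With the
plain ELBO (`kl_weight = 1`) the reconstruction term, summed over
thousands of genes, dwarfs the KL term; within ~100 epochs the model
memorizes individual outlying entries (reconstructions converge to the
corrupted values and the within-gene rank of aberrant divergence scores
collapses). Memorizing one aberrant entry buys a reconstruction gain on
the order of the squared aberration amplitude (~10 in standardized units)
and costs a few extra nats of KL; weighting the KL term by ~50 makes that
trade unprofitable while structure shared by many samples (which amortizes
its nat cost across the cohort) remains profitable. Empirically, at weight
50 the median per-gene correlation between counts and reconstructions
stays ~0.56 on a 60-sample cohort, a two-group covariate affecting 20% of
genes still separates cleanly in the latent space (best single-dimension
point-biserial |r| ≈ 0.99), and injected aberrations sit above the 0.95
within-gene |D| quantile on average.

## Scores

- Ratio `L = (k+1)/(k̂+1)`; pseudocounts keep zero counts finite.
- Divergence `D = (L − mean L)/sd L`, standardized **per gene across
  samples** (the per-sample axis is available as an option). An axis with
  zero spread yields D = 0.
- Delta count `Δ = log2((k̂+1)/(μ_k+1))` against the gene's mean original
  count; the printed form without pseudocounts is undefined at zero.

## Regression diagnostics

Per gene, Δ is regressed on D (OLS with intercept; the regression
direction is configurable but the shipped tree was trained with this
default). Features per observation:

- `typeerror`: internally studentized residual `e/(s√(1−h))` — scale-free
  across genes, unlike raw residuals;
- `hat`: leverage `1/n + (D−D̄)²/S_DD`; sums to 2 per gene;
- `dfbetas`: max over {intercept, slope} of classical DFBETAS, i.e. the
  coefficient change on deleting the observation divided by the
  deleted-fit standard error (leave-one-out residual variance with an
  (n−3) divisor);
- `cooksD`: Cook's distance `(t²/2)·h/(1−h)`.

All four are computed from closed forms vectorized over genes and are
verified against explicit leave-one-out refits to 1e-8. Genes need ≥ 4
finite points (the deleted-fit variance needs n−3 > 0) and a
non-degenerate divergence axis; failing genes are excluded and reported,
never silently dropped. Exact-leverage points (h = 1) receive an infinite
sentinel and are flagged.

## Decision tree and interval rules

CART (Gini), `max_depth` 6, `min_samples_leaf` 20. Class weighting is a
**fixed misclassification-cost ratio of 100:1** for the AGE class, not
prevalence-balanced weighting: at an injection prevalence of 1e-4..1e-3,
balancing makes each aberration outweigh hundreds to thousands of normal
points, so leaves trade enormous false-positive regions for a handful of
true positives (measured background call rates of 6–19% of all points,
contradicting the premise that aberrations are rare); balancing also ties
the operating point to the simulated prevalence, which is an artifact of
the benchmark, not a property of the data. The fixed ratio states the
actual clinical trade-off (≈100 extra screened candidates per aberration
caught is acceptable; thousands are not) and transfers across datasets.

The fitted tree is flattened into exhaustive, mutually exclusive
root-to-leaf rules (feature, ≤/>, threshold) with the leaf's label,
weighted AGE fraction and size; rule predictions reproduce the tree's
exactly (including sklearn's tie convention). Rules serialize to JSON. A
"relaxed" mode re-labels leaves AGE when their weighted AGE fraction is at
least τ; lowering τ below 0.5 admits borderline leaves to recover
near-threshold aberrations. The packaged default rule set was trained on
a fully synthetic 60 × 2,000 cohort injected at probability 1e-3 (raised
for training power); it is a synthetic-trained stand-in, labeled as such
in its metadata, for users without a labeled cohort.

## Anomaly scoring

One isolation forest per gene on that gene's (D, Δ) cloud, 100 trees,
subsample `min(64, n)`; the reported score is the classic
`s(x) = 2^(−E[h(x)]/c(m))` (scikit-learn's `score_samples` negated),
strictly inside (0, 1), larger = more isolated. Per-gene seeds derive
deterministically from the run seed. Scores are computed for every
observation; the AGE label only drives reporting order.

## Synthetic cohorts and the injection model

`generate_cohort` draws negative-binomial counts with log-normal gene
means (default mean log 200, sd 1.5 on the natural-log scale — spanning
the few-to-tens-of-thousands count range of bulk RNA-seq), gene-level
dispersion 0.1 (var = μ + 0.1μ²), log-normal size factors (sd 0.2 ≈ ±50%
depth range), and optional categorical covariates multiplying a random
gene subset by a fold change. `inject_aberrations` implements the
corruption `k → round(s·2^(μ_u ± e^N σ_u))` on the `u = log2(k/s+1)`
profile with `N ~ Normal(log 3, log 1.6)` (natural logs; the amplitude
`e^N` has median 3, i.e. the typical aberration sits three profile-sds
from the gene mean), i.i.d. entry selection, fair-coin direction, clipping
at zero. Selections in zero-variance genes are skipped and counted;
replacements that round back to the original value stay masked but are
removed from benchmark truth (undetectable in principle). The benchmark
grid (6 sizes × 3 probabilities = 18 datasets) and the small-cohort
protocol (6 sizes × 10 replicates = 60 datasets, always retaining a fixed
anchor set) reproduce the benchmark designs the method is evaluated with.

**What the simulator does not emulate:** real cohorts carry correlated
gene modules, batch effects beyond simple multiplicative covariates,
library-preparation artifacts, and — importantly — genuine biological
aberrations with no ground-truth label. Passing the synthetic benchmarks
shows the machinery is self-consistent and recovers known corruptions of
an NB cohort; it does not certify calibration on real tissue data.

## Benchmark metrics

A predicted AGE counts only on an exact (gene, sample) match. Precision,
recall and F1 come from plain set arithmetic; PR curves sweep |score|
descending with ties handled as blocks, and their step-wise area matches
an exhaustive all-thresholds computation to 1e-12. Rankings by divergence,
delta and anomaly score are reported; the anomaly ranking is invariant to
monotone score transforms.

## Reproducibility

A single seed fans out to fixed per-stage offsets (VAE +1, tree +2,
forest +3). Every phase rerun with the same seed reproduces its outputs
bitwise — including VAE training, since the numpy implementation has no
nondeterministic parallelism. CLI runs write a manifest (version,
parameters, input hashes).

## Problem sizes used in the shipped checks

The test suite exercises the full pipeline on a 60-sample × 2,000-gene
cohort injected at probability 1e-3 (~120 aberrations, raised from the
benchmark's 1e-4 for statistical power at this size), with three planted
8-sigma outliers; unit fixtures use 40 × 300. The acceptance script
measures the injection fraction on a 250 × 20,000 cohort and the protocol
cardinalities at 2,000 genes.

## Known limitations

- **Depth-extreme samples over-accumulate calls.** The divergence score
  standardizes the raw-scale ratio L per gene across samples, so samples
  with unusual sequencing depth have systematically noisier ratios and
  collect more AGE calls (per-sample call counts correlate ~0.8 with
  |log s_i| on synthetic cohorts). Typical samples carry few calls; the
  tail does not. Inspect `summary_` before interpreting per-patient counts.
- Precision at the default operating point is modest (a few percent on
  dense injection benchmarks); the method is a candidate screen ranked by
  anomaly score, not a calibrated test.
- The VAE needs a cohort to learn from; below ~20 samples reconstruction
  quality and therefore detection degrade.
- Single-tissue, highly sparse matrices (many zero-inflated genes) are out
  of the model's design envelope.
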