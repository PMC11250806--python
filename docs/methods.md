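# Methods

## Scope and shape

`methbench` is a library: its public face is the importable API plus the
narrative scripts in `examples/`. The pipeline stages (simulate →
preprocess → cells → harmonize → EWAS → meta → select → classify →
evaluate) are plain functions over one shared container,
`MethylationDataset` (samples × probes matrix, scale flag, sample sheet,
probe annotation). On disk the matrix is stored probes-as-rows (the GEO
series-matrix convention) with 1-based Illumina-style coordinates;
readers transpose to the in-memory samples × probes contract.

## The simulator

`generate_study` emulates a pooled case/control blood-methylation study
assembled from eight cohort batches. The M-value of sample *i* at probe
*j* is

    M_ij = logit2(w_i · R_j) + δ·case_i·1[j ∈ signal] + γ_b + ε_ij,
    ε_ij ~ N(0, (σ √λ_b)²)

where `w_i` is the sample's cell-mixture vector (Dirichlet over a
six-type blood reference panel `R`, granulocyte-dominated), `δ` the
planted case effect (`effect_size_m`, default 0.5 M-units at 100 of
5000 probes), `γ_b ~ N(0, batch_mean_shift_sd²)` a per-batch location
shift and `λ_b ~ U(batch_var_scale_range)` a per-batch variance factor.
Defaults describe ~1942 samples in 8 batches with per-batch case
fractions varying between 0.25 and 0.85 (pooled ≈ 0.58 cases — a
case-heavy pooled collection whose imbalance flips direction in some
batches). Age and sex exist as covariates but carry no effect by
default, so covariate handling is testable without bias. Case counts
use half-up rounding of `fraction × n`.

Simulation is done on the M scale because Gaussian noise is defensible
there and it matches the linear-modelling assumptions downstream;
converting back to beta always lands in (0, 1). Features of real arrays
the generator does **not** emulate: probe-type chemistry, spatial/chip
artifacts, detection failures (beyond an optional MCAR mask),
correlated CpG blocks, and genomic covariate structure. Passing tests
therefore certify the statistical machinery, not performance on real
cohorts.

Two switches create deliberately pathological designs:
`confound_cells_with_status` tilts the case Dirichlet so cell
composition mimics a case effect, and `confound_batch_with_status`
makes the batch shift a deterministic function of the batch's case
fraction (γ_b = 4·sd·(fraction_b − ½)) — the ingredient of batch
leakage.

One subtlety worth knowing: sample-specific mixture weights are shared
across all probes, so they induce a low-rank correlation among probes.
For experiments that need exchangeable iid null features (the
selection-bias construction, p-value-uniformity KS checks) the study is
generated with near-degenerate Dirichlet concentrations (α = 10⁵),
freezing the composition; this is stated where used.

## Numerical choices

* **M-transform clipping**: saturated betas are clipped to
  [ε, 1−ε], ε = 10⁻⁶, before logit2 — bounded M-values with negligible
  distortion elsewhere.
* **Quantile normalization**: each sample's sorted vector is replaced by
  the cross-sample mean of sorted vectors; ties receive the mean of the
  quantile values they span (the common reference dialect). The
  operation is idempotent and permutation-equivariant, both asserted.
* **Houseman projection**: non-negative least squares with a strongly
  weighted (10³) sum-to-one row, then exact renormalization. The
  equality constraint Σw = 1 (not ≤ 1) reflects a complete blood panel
  and gives a testable invariant. Rank-deficient panels are rejected
  with the most collinear pair named.
* **Cell adjustment**: per probe, values are regressed on intercept +
  K−1 proportion columns (the last cell type is the reference, avoiding
  the simplex collinearity); adjusted = residual + probe mean. Exactly
  mean-preserving and idempotent. Performed on the analysis scale in
  use (M by default); beta-scale output is clipped back to [0, 1].
* **ComBat**: parametric empirical-Bayes priors (normal for locations,
  inverse-gamma for scales, moment-matched across probes), posterior
  iteration to 10⁻⁴ relative change. Batch labels default to the cohort
  column; biological covariates are *not* protected unless passed
  (harmonization in the modeled workflow happens before modeling).
  Cross-checked against scanpy's implementation to < 0.01 absolute on a
  fixture. A single batch is returned unchanged. Note the EB shrinkage
  leaves a fraction δ²/(n_b τ² + δ²) (≈ ½ in the simulated regimes) of
  each probe's batch-location sampling noise in place, so the residual
  standardized batch difference scales like 0.5·√(2/n_b); the
  two-batch removal check uses 500 samples/batch, where ≥ 95% of probes
  fall below |SMD| = 0.1 with margin.
* **Hypervariable probes**: "beta difference > 0.2" is read as the
  cross-sample range (max − min); IQR or max-group-difference readings
  are plausible alternatives, and range is the strictest superset of
  both. PCA runs on centered, unscaled values; label association is the
  one-way ANOVA R² of PC1/PC2 scores.
* **Moderated t**: the prior df solves
  trigamma(d₀/2) = var(e) − trigamma(d/2) by Newton inversion with
  e = log s² − digamma(d/2) + log(d/2). When the observed dispersion of
  log s² does not exceed its sampling noise, d₀ = ∞ and the prior
  variance is the geometric mean of the s² — the limit in which
  identical residual variances shrink to themselves exactly and the
  moderated t equals the ordinary t. SE is reported as u·s_post, and
  "log2FC" names the status coefficient on the analysis scale (ΔM for
  M-values).
* **Directional agreement** is computed against the sign of the pooled
  logFC (a majority-sign variant is available by flag);
  zero median differences count as disagreement.
* **BH FDR** delegates to statsmodels (`fdr_bh`) behind a domain check;
  tests hold it to a brute-force step-up oracle.
* **Sidik–Jonkman**: τ₀² = Σ(y−ȳ)²/k with the unweighted mean,
  provisional weights 1/(v/τ₀² + 1), τ̂² = Σw(y−μ̂_w)²/(k−1); the
  degenerate τ₀² = 0 case returns 0. Pooled inference is Wald-normal
  with w = 1/(v + τ̂²) (no Knapp–Hartung), Q uses fixed-effect weights,
  and I² uses the "typical within-study variance" denominator. Verified
  to 10⁻⁹ against `metafor::rma.uni(method="SJ")` on a frozen 8-study
  example. Under a heterogeneous null (τ² > 0) the Wald z runs slightly
  anticonservative (type-I ≈ 0.05–0.07 at k = 8), and conservative under
  τ² = 0, where SJ overestimates heterogeneity — the calibration checks
  use the heterogeneous null, which is where the estimator is meant to
  live.
* **Selectors**: variance-fraction counts use the ceiling rule (the only
  rule consistent with 15,239/3,048/305 from 304,765 probes at
  5%/1%/0.1%); all ranking ties break by probe order; L1 selectors pad
  to k with the largest-magnitude remaining coefficients when sparsity
  leaves fewer than k nonzero; L1 max_iter defaults to 5000.
* **Deep models**: implemented directly in numpy with explicit backprop
  and Adam (lr 10⁻⁴, batch 128), Glorot-uniform init. Encoder
  N-128-64-32, decoder 32-64-128-N, classifier head 32-16-1. The
  decoder output is sigmoid + binary cross-entropy for beta input and
  linear + squared error for M input; the joint AE loss is
  w·recon + (1−w)·clf (w = 0.5 default), the VAE loss is
  recon + KL + c·clf with KL = −½Σ(1 + log σ² − μ² − σ²) over the 32
  latent units and reconstruction summed over features. VAE scoring
  uses the posterior mean (no sampling). Gradients are verified against
  central finite differences in the test suite. Reference training
  lengths are 1000/2000/2250 epochs (DNN/AE/VAE); desk-scale runs pass
  smaller `epochs` explicitly — e.g. the reconstruction benchmark uses
  400 × 200 low-rank data and 200 epochs, where held-out reconstruction
  r ≥ 0.99.
* **Evaluation**: stratified 10×3 repeated CV by default (a plain
  random mode exists); fold metrics are averaged fold-level statistics,
  not pooled predictions; accuracy thresholds scores at 0.5; classifiers
  see CpG features only (age/sex enter selection via the EWAS design,
  not the classifier input). Every selection records `fitted_on`; the
  unbiased evaluator hard-fails if that set intersects a validation
  fold. Hold-out splits are whole cohort batches (default 5 train / 3
  test, mirroring an ~84%/16% allocation); hold-out training repeats
  over 5 seeds by default. The bias-gap report includes a paired
  sign-flip permutation p-value over fold AUC differences.

## Experiment sizes

Simulated experiment sizes were chosen so each check is decisively
powered yet runs in seconds-to-minutes on one CPU: the selection-bias
experiment uses 600 × 5000 (three independent studies, logistic +
random forest), the leakage contrast 600 × 2000 (three studies per
arm, differences averaged), the ComBat removal check 1000 × 2000, the
meta-analysis calibration 1000 probes × 8 cohorts, and the joint-AE
benchmark 400 × 200 with rank-5 structure.

## Known limitations

* Real-array preprocessing (IDAT ingestion, probe-type correction,
  detection QC, published exclusion lists) is out of scope; exclusion
  lists are accepted as user input only.
* No nonparametric/reference-batch ComBat, no surrogate variables, no
  robust or trended empirical Bayes, no τ² estimators beyond SJ.
* The deep models cover the reference architectures, dropout and L2
  weight penalties; batch normalization is not implemented. Exact
  per-layer regularization strengths of the reference configurations
  are not public, so the defaults here are the package's own.
* Headline numbers from real multi-cohort depression data (probe
  counts, AUC levels) depend on those cohorts and are not reproduced by
  simulation; the package reproduces the *phenomena* (bias gap,
  leakage contrast, calibration) directionally and quantitatively on
  synthetic data.
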