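# Methods

## Pseudobulk and normalization

Cell-level counts are summed per (cell cluster, sample). Aggregation walks
the cell dimension in blocks (all genes, a slice of cells) with a sparse
indicator product, so memory is bounded by one block plus the accumulator
and the result is exactly independent of the block partition. Cluster ×
sample pairs with no cells are absent rather than zero-filled.

Within each cluster, samples observed with fewer than `min_cells` cells
(default 10) are dropped, and clusters retaining fewer than two samples are
removed with a report. Genes are then filtered per cluster — retained if
their count is at least `min_count` (default 5) in at least `min_prop`
(default 30%) of the remaining samples. The filter is per cluster because
expressed-gene sets genuinely differ between cell types; the defaults are a
`filterByExpr`-style rule and are fully configurable. Library sizes are
plain column sums computed **after** gene filtering, and expression is

    E[i, g] = log2( (Y[i, g] + 0.5) / (lib_size[i] + 1) * 1e6 ),

the standard log2-CPM transform with the 0.5/1 pseudocounts the
mean-variance-trend machinery assumes.

## Two-level precision weights

**Cell-count weights.** A sample's pseudobulk profile averages the n_i
cells sampled from a much larger population, so the sampling variance of
its expression state scales as 1/n_i and the relative precision is n_i —
the same for every gene of the sample. Weights are normalized to mean one;
only relative weights matter in weighted regression (tested: global
rescaling leaves all inference unchanged).

**Trend weights.** Each gene is fit by linear regression weighted by the
cell-count weights; the points (average log2 count, sqrt residual sd) are
smoothed by lowess with span 0.5 and one robustness iteration. Each
observation's fitted log2 count is looked up on the curve (linear
interpolation, constant extrapolation beyond the fitted range — degenerate
edge behavior is thereby bounded) and the weight is the predicted value to
the power −4, i.e. the reciprocal variance implied by the trend. Weights
are clipped to [1e-6, 1e6] purely as a numerical guard.

**Composition.** The final weight is the product of the two levels,
rescaled to mean one per gene. Multiplication is the natural composition of
independent precision factors; per-gene rescaling is a convention without
inferential consequence (the invariance is tested). The cell-count weights
are also supplied as initial weights to the trend fit, so the trend is
estimated under the same heteroskedasticity model it refines. One round of
trend fitting is performed; no iteration between weights and coefficients.

## Per-gene weighted mixed models

The model for gene g is y = Xb + Σ_k Z_k u_k + e with u_k ~ N(0, σ²_k I)
and e_i ~ N(0, σ²_e / w_i). Categorical fixed effects use treatment coding
with the lexicographically first level as reference (configurable); aliased
columns are removed by pivoted QR and a term losing all its columns is an
error naming it. Rows with missing covariates are dropped with a count.

Estimation is REML with the residual variance profiled out, optimizing the
log variance ratios γ_k = σ²_k/σ²_e on [−12, 12] (tolerance 1e-8, max 200
iterations; bounded scalar search for one random term, L-BFGS-B otherwise).
For a single random term the problem is first whitened by sqrt(w) and
rotated into the eigenbasis of ZZᵀ, making every objective evaluation
diagonal — this is an exact reparameterization, not an approximation.
Variance components are constrained non-negative; boundary estimates are
valid fits, and with no (or zero) random terms the fit reduces exactly to
weighted least squares. Per-gene fits are independent and deterministic, so
results are identical for any worker count. Non-converged genes are flagged
and excluded from moderation (a fixed-effects fallback is available by
configuration).

## Residual degrees of freedom by chi-square mixture matching

Let V₀ = diag(1/w) + Σ_k γ̂_k Z_k Z_kᵀ be the marginal covariance in
relative-variance form and P = V₀⁻¹ − V₀⁻¹X(XᵀV₀⁻¹X)⁻¹XᵀV₀⁻¹ the REML
projection at the estimates. The weighted residual sum of squares is the
quadratic form yᵀ P W⁻¹ P y, distributed (under the model, at the plug-in
parameters) as Σ_i λ_i χ²₁ with λ_i the eigenvalues of
V₀^{1/2} P W⁻¹ P V₀^{1/2}. Matching the mean of this mixture with a single
chi-square gives

    df_r = Σ_i λ_i = tr(P W⁻¹ P V₀),

computed by the trace (the full spectrum is evaluated only on request,
since mean matching needs just the sum). The residual variance passed to
moderation is s² = yᵀ P W⁻¹ P y / df_r, and standard errors use s² with the
unscaled GLS covariance (XᵀV₀⁻¹X)⁻¹, keeping the empirical-Bayes identity
t̃ = t · s/s̃ exact.

Properties (all tested): for a pure weighted linear model df_r = n − p
exactly; at a zero variance-component boundary df_r is continuous in n − p;
as a grouping factor's variance dominates, df_r decreases monotonically to
n − rank([X Z]) — the number of residual contrasts that remain informative
about the unit-level variance. On exactly-Gaussian null data the resulting
t with df_r reference is calibrated to the nominal level (checked at 4,000
genes, n = 40).

## Empirical Bayes moderation and FDR

The prior σ² ~ s₀² d₀ / χ²_{d₀} is estimated by matching moments of log s²
against the log-F distribution: with e = log s² − ψ(df/2) + log(df/2), the
excess of var(e) over the mean sampling term ψ′(df/2) equals ψ′(d₀/2),
inverted by Newton iteration; s₀² follows from the mean equation. When the
excess is non-positive the prior is degenerate: d₀ = ∞ and s₀² is the mean
of the s². Genes with flagged fits are excluded from the prior. The
posterior variance is the convex combination s̃² = (d₀s₀² + df_r s²)/(d₀ +
df_r), the moderated t is referred to Student-t with d₀ + df_r degrees of
freedom (normal when d₀ = ∞), two-sided. On a fixture with heterogeneous
gene variances the whole chain (prior, posterior variances, t, p)
reproduces the reference bulk-RNA-seq implementation in R to 1e-8
(cross-checked via Rscript in the test suite).

FDR is Benjamini–Hochberg applied once across the concatenation of all
(cluster, gene) tests — study-wide — with a per-cluster option.

## Variance partitioning

For partitioning, every categorical source (subject, batch/pool, and also
two-level diagnosis) is modeled as a random intercept so it contributes an
estimated variance σ²_k; continuous sources stay fixed and contribute the
empirical variance of their fitted term X_k b̂_k; the residual contributes
σ²_e. Fractions are each component over the total, hence non-negative and
summing to one. The same observation weights as the differential expression
analysis are used, for internal consistency. Fractions are scale-invariant
and robust to adding a pure-noise source (both tested).

## Competitive gene set analysis

For a set of m tested genes among M total, the statistic is delta =
mean(t in set) − mean(t outside). Its null variance is the pooled
two-sample variance times (VIF/m + 1/(M−m)) with VIF = 1 + (m−1)ρ
accounting for inter-gene correlation inside the set; z = delta/se is
referred to Student-t with M − 2 df, two-sided. The default ρ = 0.01 is the
established default of camera-class methods; estimating ρ from residuals is
out of scope. At ρ = 0 the parametric p agrees with a 10,000-draw
permutation null within Monte-Carlo error (tested); increasing ρ strictly
deflates |z|. Sets are intersected with the genes tested in each cluster
and the count used is reported; a rank-based variant is available.

## Simulator

The generator emulates a multiplexed cohort: subjects are assigned to
batches (pools) of `subjects_per_batch`, case status is allocated
round-robin within batch (so batches are near-balanced, as in a permuted
design), and replicates of a subject share its batch and subject effect.
For gene g in a cell of subject i: count ~ NB(mean = depth · p_{i,g},
size = dispersion), where p_{i,g} is the softmax over genes of

    m_g + ln(2) · (a_{i,g} + b_{batch(i),g} + x_i β_g),

with baselines m_g ~ N(0, 1.5²), gene-specific subject effects a ~ N(0,
σ²_subject) and batch effects b ~ N(0, σ²_batch) on the log2 scale, and
β_g = ±lfc_de for a `frac_de` subset. Random effects must be gene-specific:
a gene-shared shift is absorbed by library-size normalization and carries
no signal.

Defaults model a desk-scale single-nucleus-like study: dispersion 3
(moderate overdispersion), 2,000 reads per cell over 2,000 genes, 100 cells
per subject, σ²_subject = σ²_batch = 0.05 on the log2 scale (about 0.22
log2 units of sd, a modest but clearly detectable structure). What the
simulator does **not** emulate: zero-inflation beyond NB sampling,
cluster-specific composition shifts, ambient RNA, doublets, depth gradients
correlated with condition, or mean-dependent dispersion. Passing
calibration here therefore shows the statistical machinery is sound under
NB sampling with hierarchical structure, not that every artifact of real
data is handled.

The permutation harness shuffles diagnosis labels independently within each
batch, preserving every batch's case/control multiset exactly, and scores
the fraction of null genes with p below each α (FPR), plus observed FDR and
power against the known DE set when effects are simulated.

## Calibration results and problem sizes

The shipped experiments use one simulated cohort of 40 subjects in 8
batches of 5 with 2,000 genes and 100 cells/subject for the FPR study
(20 permutations), and 10 replicates of 30 subjects × 2 technical
replicates for the FDR study — sizes chosen so the full suite runs on a
laptop-class single core in minutes. At these sizes the observed FDR is
comfortably below nominal, and the FPR sits within a few tenths of a
percentage point of the nominal 5% (slightly above it): the REML plug-in
test on log-transformed counts is approximate at n = 40, and the residual
df approximation is documented as improving with sample size. The
equivalent model on exactly-Gaussian data is calibrated to 0.050, which
localizes the gap to the count-data approximation rather than the
estimation machinery.

## Known limitations

- Random intercepts only; no random slopes or correlated random effects.
- No small-sample contrast corrections (Satterthwaite/Kenward–Roger per
  contrast); the df route is the mixture matching above.
- No robust (winsorized) prior estimation.
- ρ for gene set analysis is fixed, not estimated from residuals.
- The simulator's parameters are configuration, not estimates from any
  real dataset.
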