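# Methods

## Model

Expression profiles x ∈ ℝᵖ are modelled as multivariate normal with
covariance η. The conjugate prior on η is inverse Wishart with scale λz and
the estimate is the posterior mean

    η⁰ = (λ z + S) / (λ + n),    S = Σₖ (xₖ − μ′)(xₖ − μ′)ᵀ,

where μ′ is the sample mean (the model treats the mean as known; in practice
it is replaced by the sample mean and S uses the divisor-free form, so S/n is
the maximum-likelihood covariance).

**Working scale.** Covariance and correlation are used interchangeably in
this setting, so one scale has to be fixed: each variable is standardized to
mean 0 and variance 1 (divisor n) before estimation. Then S/n equals the
sample correlation matrix R, z (a correlation matrix) is commensurate with
S/n, and η⁰ is the convex blend w·z + (1−w)·R with w = λ/(λ+n). η⁰ is
re-standardized to exact unit diagonal (`R_eb`); a covariance-scale output is
available by rescaling with the sample standard deviations. Consequences
worth knowing: η⁰ is positive definite whenever λ > 0 (z is PD by
construction, R is PSD), its entries lie in [−1, 1], and for every
within-block pair |R_eb − γ_b| ≤ |R − γ_b| while every between-block entry
shrinks in magnitude.

## The prior z

A partition of the p genes into blocks is turned into z by setting every
off-diagonal entry inside block b to γ_b, the unweighted mean of the sample
correlations among the block's members (signed values are averaged; with
co-repressed members a block's γ can legitimately be negative). γ_b is
clamped into (−1/(m_b−1)+ε, 1−ε) with ε = 1e−6, which is exactly the open
interval on which a constant-correlation block of size m_b is positive
definite (eigenvalues 1+(m_b−1)γ and 1−γ). Singleton blocks contribute a 1×1
identity block; an all-singleton partition recovers the independence prior
z = I.

Partitions come from one of three routes:

1. **Known groups** — caller-supplied assignments (e.g. annotated operons);
   unassigned genes become singletons.
2. **Threshold** — the graph on genes with an edge wherever |r_ij| ≥ t is
   split into connected components. Absolute values are used because strong
   negative correlation is equally informative about shared regulation.
   Raising t only refines the partition (edges are only removed), a
   monotonicity the tests exercise.
3. **AIC** — t is scanned over {0.05, 0.10, …, 0.95} (no canonical grid
   exists; 0.05 spacing resolves every materially different partition at
   these sample sizes). Each candidate partition defines a Gaussian model
   whose covariance is the averaged-correlation block matrix rescaled by the
   sample standard deviations, scored by
   AIC(t) = 2k(t) − 2 lnL, with k(t) = Σ_b m_b(m_b+1)/2 the free entries of
   a block covariance and lnL = −(n/2)[ln det Ω + tr(Ω⁻¹ S/n) + p ln 2π].
   Ties are broken toward the larger threshold (the sparser model). Note
   AIC's penalty is mild: merging a noise pair costs 2 but gains n·r² in
   2 lnL, so on null data the chosen partition is near-singleton rather than
   exactly singleton.

## The prior strength λ

The sampling variance of a correlation around its prior value satisfies,
to first order, E[(r_ij − z_ij)²] ≈ (1 − z_ij²)²/(λ+3). Each pair gives a
noisy λ estimate; the implementation aggregates as a ratio of means,
λ = mean[(1 − z_ij²)²] / mean[(r_ij − z_ij)²] − 3 over all i < j (including
between-block pairs, where z_ij = 0), because a mean of per-pair ratios is
dominated by pairs whose observed discrepancy happens to be tiny. λ is
clamped to [1e−3, 1e6]: positivity is required by the inverse-Wishart
parameterization, and the upper clamp bounds the estimate when the sample
matches the prior exactly. At the default study conditions λ is moderate
(≈6 at n=10 to ≈17 at n=20), i.e. the prior is worth roughly one extra
experiment's worth of samples.

## Significance, FDR and TPR

A pair is called significant by the two-sided t-test on the *estimated*
correlation, t = r√((n−2)/(1−r²)) with df = n−2, at raw level α = 0.05 — the
same test for every estimator, with no df adjustment for shrinkage and no
multiple-testing correction, so that differences between methods reflect the
estimates and not the testing procedure. Entries that are exactly zero
(masked baselines) have t = 0 and are never called. |r| = 1 is called by
convention. Scoring against a truth matrix counts an unordered off-diagonal
pair as positive iff it lies inside a true block (valid because the default
truth has exact zeros between blocks); FDR = FP/max(FP+TP, 1),
TPR = TP/(TP+FN).

Because shrinkage of between-block entries is multiplicative ((1−w)·r) and
not exact zeroing, the known-groups estimator's FDR is *nearly* but not
*identically* zero: a between-block |r| exceeding r_crit/(1−w) (≈0.9 at
n=10) survives occasionally, ~0.003 mean FDR over replicates, which is zero
at two-decimal reporting precision.

## Synthetic truth

The generator produces constant-correlation block matrices — within-block
correlation ρ (default 0.7), zero between blocks — optionally perturbed in
the spirit of the constructive noise recipe for realistic correlation
matrices: ε·(UᵀU − I) with U columns uniform on the unit sphere, which
preserves the unit diagonal and keeps the matrix PD whenever ρ + ε < 1.
Samples are i.i.d. mean-zero MVN draws via Cholesky. Defaults: p = 50 genes
in 5 blocks of sizes (5, 8, 10, 12, 15) — five blocks of distinct sizes
summing to 50, the study's stated shape — ε = 0 (the unperturbed case, so
within-block correlations are exactly 0.7 and the block/no-block truth is
unambiguous), sample sizes 10/15/20, 100 replicates.

What the generator does *not* emulate: count-distributed (RNA-seq) noise,
heavy tails, condition-dependent structure, overlapping regulons, or
unequal within-block correlations. Passing tests therefore demonstrate
correct behaviour under the Gaussian block-diagonal model, not robustness to
real-data violations of it.

## Study harness and numerical choices

Each replicate draws a fresh truth and one sample per sample size; per
replicate the harness fits the EB estimator with known groups, with
threshold-derived blocks (t = 0.7, the known correlation level), and with
AIC-chosen blocks, plus Pearson and shrinkage ("corpcor"-style, analytic
intensity δ = min(1, Σvar̂(r_ij)/Σr_ij²) toward the zero-off-diagonal
target) baselines masked to known or threshold-derived blocks. Metrics are
the Frobenius distance to truth over within-block entries and over the full
matrix (both triangles; the unit diagonals cancel), and FDR/TPR as above.
Seeding uses a spawning sequence from one master seed, so every replicate is
independently reproducible. The full 100-replicate, three-sample-size study
takes ~12 s on one core; tests and the acceptance script run it at full
scale.

Degenerate inputs are rejected with named errors rather than repaired:
constant genes (no correlation defined), n < 3 (no t-test df), thresholds
outside [0, 1), partitions that overlap or fail to cover, infeasible ρ/ε
combinations.

## Known limitations

* The block-average prior assumes one shared correlation level per block;
  blocks with genuinely heterogeneous within-block structure are flattened
  toward their mean.
* λ is a single global scalar: a few badly mis-specified blocks deflate it
  for everyone.
* AIC block selection inherits AIC's liberality (spurious small blocks on
  null data) and, at very small n, its instability.
* The t-test is applied to shrunken correlations without a df correction,
  so its nominal 5% level is approximate; behaviour under heavy-tailed data
  is unverified.
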