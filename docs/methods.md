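# Methods

This note documents the statistical procedures implemented in `refstab`,
the estimation and numerical choices behind them, what the synthetic-data
generator does and does not emulate, and known limitations.

## Data model and preprocessing

Input is a long table of wells: `(sample, group, plate, run, gene,
replicate, cq)`. Missing Cq values are explicit (NaN), never a sentinel
cycle number, because the mixed-model stability measure is designed to
tolerate randomly missing data while the classic algorithms handle it
pairwise. Validation is total: malformed input raises a typed
`ValidationError` naming the offending rows or keys.

**Replicate QC.** Technical replicates are averaged arithmetically on the
Cq scale (equivalently, geometrically on the quantity scale). Flags, in
precedence order: `missing_replicate` (fewer than `min_replicates = 2`
usable wells), `spread_exceeded` (max−min Cq > `max_spread = 1.0` cycle),
`above_max_cq` (mean Cq > `max_cq = 34`, the stochastic single-template
regime for reference genes). Bench practice is to re-assay wide
triplicates; software cannot, so flagged records are excluded from
stability input by default, with the exclusion set configurable.

**Relative quantification.** Per gene, either calibrator mode
`RQ_s = E^(Cq_min − Cq_s)` (most-abundant sample = 1) or threshold mode
`RQ_s = N_q · E^(−Cq_s)` with plate-matched efficiency `E ∈ (1, 2]` and
quantification-threshold fluorescence `N_q`. Threshold mode is absolute per
plate and therefore composes naturally with inter-plate correction; it is
preferred when `N_q` is available. Exponentials are evaluated in log space
to avoid overflow. Efficiencies are *inputs* (typically from standard-curve
fits); the package deliberately does not estimate them from fluorescence
curves.

**Inter-plate factor correction.** Plates within a run behave as
multiplicative session effects. Per gene, the factor for plate *p* is
derived by centering the per-plate means of log2 RQ — the least-squares
solution for a multiplicative session effect — and renormalized so the
geometric mean of the factors across plates is exactly 1 (tolerance 1e-6).
Corrected RQ = RQ × factor of the sample's plate. With balanced plate
composition this also preserves each gene's overall geometric mean exactly
(the two constraints coincide); with unbalanced plates the geometric-mean-1
constraint on the factors takes precedence. The correction is idempotent,
and for two plates the fitted factors form reciprocal pairs.

## Classic stability algorithms

All logarithms are base 2; all rankings break ties by input gene order so
results are deterministic.

* **geNorm.** `M_j` = mean over partners k of the sample SD (n−1) of
  log2(RQ_j/RQ_k). Stepwise: remove the arg-max M and recompute until two
  genes remain; the reported per-gene M is the first-pass (all-genes) value,
  which is the conventional summary. The pairwise variation `V_n` is the SD
  of log2(NF_n/NF_{n+1}) between successive geometric-mean normalisation
  factors; `V_n < 0.15` flags that the (n+1)-th gene adds nothing.
* **NormFinder.** On within-sample-centered log2 RQ: per-group intergroup
  differences `d_ig`, bias-corrected intragroup variances (subtracting the
  across-gene mean variance divided by the gene count, floored at 1e-12),
  a moment estimate of the between-group variance `γ²` used to shrink
  `d_ig`, and stability `mean_i(|d̃_ig| + sqrt(Var d_ig))`. A single-group
  design reduces to the square root of the bias-corrected centered
  variance. Combination stability averages the set's shrunken differences
  and pooled difference variances; the best pair minimizes it. All
  intermediates are exposed in the result object for audit.
* **BestKeeper.** Per-gene dispersion is the mean absolute deviation of Cq
  about the arithmetic mean (the original BestKeeper "SD"), CV = 100·SD/mean;
  genes with SD > 1 cycle are flagged unreliable. The index is the per-sample
  geometric mean of Cq over genes (complete samples only), and genes are
  ranked by Pearson r against it. No outlier removal by default; an optional
  flag drops samples whose index deviates from the median by > 3×MAD.
* **Comparative ΔCq.** Gene score = mean over all pairs containing the gene
  of the sample SD of the pairwise Cq difference. On a shared log scale
  this coincides with geNorm's first-pass M (both are mean pairwise SDs),
  which the test suite exploits as a cross-check.

## Consensus ranking

Both the unweighted Spearman footrule (sum of absolute rank displacements
over lists) and the weighted dialect decompose into independent
(gene, position) costs, so the exact minimizer is found by linear
assignment (Hungarian algorithm) — identical to full enumeration, which the
tests retain as an oracle. In the weighted dialect each list's scores are
oriented so smaller = more stable (correlation-type scores negated),
min–max normalized to [0, 1] within the list, and rank displacements are
measured on that normalized-score scale. The published formulation of
weighted rank aggregation leaves the exact weight normalization open; the
unweighted objective is therefore always available alongside. The
cross-entropy sampler keeps a gene × position probability matrix, samples
permutations sequentially, refits the matrix on the elite 10% of 2000
samples per iteration with multiplicative smoothing 0.7, and stops after 5
stale iterations; it is seed-reproducible and agrees with the exact solver
on small ensembles in 49+/50 seeded trials.

## Mixed-model ICC stability

A combination of k genes is modelled as k repeated measurements of each
sample: fixed gene, group, and gene×group effects; random sample intercept
nested in groups; response log2 RQ (option `neg_cq` fits −Cq directly for
efficiency-1 workflows). The modeling scale must be logarithmic for
variance components to be comparable across genes. Stability is
ρ = σ²_sample/(σ²_sample + σ²_error): how much of the combination's
variation is the shared per-sample signal a reference should track.

**Estimation.** With a single variance ratio λ = σ²_sample/σ²_error the
generalized least squares whitening is closed-form per sample block
(shrinking each block mean by 1 − 1/√(1 + k_s λ)), so REML and ML reduce to
a one-dimensional profile likelihood in λ, optimized by bounded scalar
search on the log scale with the λ = 0 boundary checked explicitly. This
makes a single fit ~1 ms, which the bootstrap, the combination search
(exhaustive per size; 957 fits for 10 candidates up to size 5) and the
Monte-Carlo validation suites depend on. Missing gene measurements simply
shrink a sample's block. The engine is cross-checked against statsmodels
`MixedLM` (REML components and ML deviance agree to ≥ 5 significant digits
on balanced, unbalanced and missing-data fixtures).

**Confidence intervals.** For complete data (every retained sample measured
on all combination genes) the F-based consistency interval is used:
F = MS_samples/MS_error from the least-squares decomposition with
gene×group cells and sample indicators, with rank-based degrees of freedom
(df_samples = n − g, df_error = N − kg − (n − g) = (k−1)(n−g) for balanced
data), transformed by (F/F_crit − 1)/(F/F_crit + k − 1) and truncated to
[0, 1]. For incomplete data a seeded parametric bootstrap (default 1000
refits, percentile interval) replaces it; on balanced data the two agree
within 0.03 at n = 50. If numerical truncation would exclude the point
estimate the interval is expanded to contain it and the event flagged.

**Systematic-effect test.** Group and gene×group effects are tested jointly
by a likelihood-ratio test of ML fits (full vs gene-only fixed effects)
against χ² with (g−1)·k degrees of freedom. The raw asymptotic statistic is
measurably anticonservative at study-sized n (empirical size ≈ 6% at
nominal 5% with 60 samples), so by default the statistic is scaled by
(N − p_full)/N — the Bartlett-type degrees-of-freedom correction, which is
near-exact for fixed-effect tests in the linear-model limit and restores
uniform null p-values in the calibration suite (`lrt_correction="none"`
recovers the raw statistic). A small p-value means the "reference" genes
move with treatment; the flag never auto-excludes a combination, since a
winning combination may legitimately sit near the threshold.

**Combination search.** All size-2 combinations are fitted, then size-3,
and so on (to `max_k = 5`); the search stops when the best lower 95% bound
fails to increase with size — ranking by the lower bound guards against
selecting an ICC estimated too imprecisely to trust. Ties break by
narrower interval, then input order. Reliability bands on the ICC scale:
< 0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, ≥ 0.9 excellent; labels span
the band of the lower bound to the band of the point estimate.

**Degenerate inputs.** σ²_sample estimated at the boundary 0 yields ρ = 0
with a boundary flag; data with no variation at all (both components ≈ 0
relative to the response scale) yield ρ = 1 with a degenerate-fit flag —
the perfect-agreement reading, so a noiseless end-to-end pipeline reports
ICC 1.

**Sample-size planning.** Bonett's approximation (see README) with
z = 1.959964 at the 95% level and the result rounded up. ICC values are
conventionally entered at two decimals (0.86 → 106; entering 0.858 gives
108). The planning grid spans k = 2..5, ρ = 0.70..0.90 (step 0.01) and
widths 0.1/0.2. The formula is non-increasing in width everywhere and in ρ
for ρ ≥ 0.5; for k ≥ 3 it *increases* in ρ near zero, which is outside any
planning range but worth knowing.

**Variance of a normalized product.** For power reasoning about
GOI/normalisation-factor quotients, `variance_of_product` evaluates
Var(XY) = Var(X)Var(Y) + Var(X)μ_y² + Var(Y)μ_x² for independent X, Y, and
the exact moment identity
Var(XY) = Cov(X², Y²) + (Var X + μ_x²)(Var Y + μ_y²) − (Cov(X, Y) + μ_x μ_y)²
in the dependent case (this is E[X²Y²] − E[XY]² rewritten; both forms are
verified against Monte Carlo on correlated lognormals). Any covariance
between GOI and reference inflates the quotient variance — the quantitative
reason unstable references cost experimental power.

## GOI normalization

NRQ = GOI RQ / geometric mean of the reference combination's RQs per
sample. Relative standard errors propagate first-order on the log scale:
rSE² = rSE_goi² + (1/k²)·Σ rSE_ref²; replicate-level rSEs derive from the
replicate Cq SD via ln(E)·SD/√n. Group testing of NRQs (ANOVA et al.) is
out of scope; tables export cleanly for external statistics.

## Synthetic-data generator

The generator emulates the study design the package targets: 7 treatment
groups × 8 samples, 10 candidate genes with study-like baseline Cq values
and efficiencies in (1.85, 2.0], triplicate wells, samples alternating
between 2 plates, well noise SD 0.1 cycles. Latent log2 expression is
`shift_gi + b_s + ε_gs` with shared sample effect SD σ_b = 1.0 and per-gene
noise σ_e from 0.4 (ACTB, PABPN1) to 1.8 (18S) — calibrated so the best
pair's generating ICC (σ_b²/(σ_b² + mean σ_e²) ≈ 0.86) matches the
reliability regime the method is meant to resolve, and the noisy genes are
unambiguously worst. Cq values map through each gene's own efficiency
(slope log 2 / log E), so efficiency-naive and efficiency-corrected
pipelines measurably diverge — a deliberate test surface. Plate offsets are
additive in log2 quantity (±0.25 by default), matching the factor-correction
model.

What it does *not* emulate: amplification curves and fluorescence,
co-regulated gene families (gene noises are independent given the sample
effect), heteroscedastic well noise at late cycles, plate-position effects,
and any biology of the injury models. Passing recovery tests therefore show
the estimators are correct under the stated model, not that real kidney
panels satisfy it.

## Validation summary

The test suite checks, among others: parameter recovery (mean ICC within
0.02 of truth at n = 200 over 500 seeded studies) and 95% CI coverage
within [92.5%, 97.5%]; LRT null uniformity (KS at 1%, 1000 replicates,
n = 60) and > 80% power against a 1-log2 group shift at the 7×8 design;
exact-vs-enumeration equality of the footrule solver and 49+/50 CE
agreement; hand-computed oracles for every classic algorithm; and the
plate-factor geometric-mean and conservation invariants. Problem sizes in
the stochastic suites (500–1000 replicates at n = 60–200) were chosen to
keep Monte-Carlo error well below the asserted tolerances.

## Limitations

* Continuous systematic covariates are a documented extension point; the
  implemented design is categorical groups (with nesting), which is what
  the combination search exercises.
* The F-based interval assumes the consistency (not absolute-agreement)
  ICC; with strongly unbalanced groups the REML point estimate and the
  ANOVA-based interval can diverge slightly (the interval is then expanded
  to contain the point estimate and flagged).
* BestKeeper and comparative ΔCq operate on Cq values; when only RQs are
  available the pipeline substitutes −log2 RQ, which preserves dispersion
  structure up to per-gene efficiency scaling but is not identical to raw
  Cq input.
* Between-run calibration (shared calibrator samples across runs) is not
  implemented; plate correction operates within a run.
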