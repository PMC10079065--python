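# Methods

## Data model

All analysis operates on a probe × sample matrix of already-normalized
log2 expression intensities aligned to a sample table with columns
`sample_id`, `case_id`, `region` (`vulnerable` / `resistant`), `diagnosis`
(`case` / `control`) and arbitrary covariate columns. In matched mode each
individual (`case_id`) contributes exactly one sample per region; the
pipeline detects matching automatically and falls back to the unmatched
rearrangement of the ratio-of-ratios statistic when pairing is absent.

Because intensities are log2-transformed, the geometric average of
intensities within a group equals the arithmetic mean of log2 values, so
all fold-change algebra is done with plain mean differences.

## Covariate correction

Per probe, an ordinary least-squares fit of
`y ~ intercept + protected + nuisance` is computed and the fitted
contribution of the nuisance columns is subtracted. Protected terms
default to diagnosis, region, and their interaction so that all four
diagnosis × region cell means survive correction; the interaction is
coded as the product of reference-coded dummies. Nuisance columns
(categorical dummies and continuous values alike) are mean-centered
before subtraction, which preserves the grand mean exactly and makes the
operation idempotent. OLS is used rather than generalized least squares:
without a specified correlation structure GLS reduces to OLS, and the
deterministic path is testable. Missing covariate values are an error —
no silent imputation. Rank deficiency is detected by pivoted QR and
reported with the names of the collinear columns.

A consequence of modular correction: the two-group variance estimated
downstream uses df = n₁ + n₂ − 2 and does not know that correction
consumed a few residual degrees of freedom. With ~10 nuisance columns and
hundreds of samples the variance deflation is ≲ 3% and downstream null
p-values are very slightly anti-conservative; at desk scale the null
uniformity checks (KS at 5,000 null genes) pass.

## Moderated t and the variance prior

Per-gene variances are modeled as σ²_g ~ s0²·d0/χ²(d0). The prior is fit
by moment matching on z = log s²: var(z) = trigamma(df/2) + trigamma(d0/2),
inverted for d0 by bisection (tolerance 1e-10), with s0² from mean(z) via
a digamma correction. Spread at or below the sampling floor yields
d0 = ∞ (full shrinkage). The posterior variance
s2_post = (d0·s0² + df·s²)/(d0 + df) feeds t = effect/(√s2_post · c) with
df_total = df + d0, where c is the design constant √(1/n₁ + 1/n₂). This
is the classic empirical-Bayes moderation; the implementation is verified
against limma's `eBayes` to 1e-12 in the test suite (dual route: our code
vs the reference implementation through Rscript). Benjamini-Hochberg
adjustment is applied within each contrast family (vulnerable contrast,
resistant contrast, RoR contrast) separately. Probes with zero pooled
variance are rescued by moderation whenever s0² > 0; all-zero-variance
input (constant matrices) degenerates to d0 = ∞ with an arbitrary unit
scale, under which every t is 0 — the only self-consistent answer.

## Ratio of ratios, Priority Score, set extraction

Matched: `d_i = log2(vul_i) − log2(res_i)` per case, then a single
moderated two-sample t of d between diagnosis groups. Unmatched:
`logRoR = logFC_vul − logFC_res` with standard errors combined in
quadrature and Welch–Satterthwaite df on the moderated variances; on
matched data the two point estimates are algebraically identical
(asserted to 1e-12 per probe).

Ranks are taken on magnitudes, rank 1 = largest |statistic|, average
ranks for ties. `P = rank_fc / rank_ror` on the base-10 log scale, with
the orientation fixed so that log P > 0 ⇔ the probe is more extreme under
RoR than under the region-only contrast. Magnitude ranking (rather than
signed ranking) is used because contrasting genes of both RoR signs are
of interest. The output table is sorted by probe id so it is invariant to
input order.

Set 1 = top `n_limb` (default 500) probes by log P filtered to RoR
p < α (default 0.05); Set 2 = bottom `n_limb` filtered to p ≥ α. The
filter basis is the raw moderated p by default, with a config switch
(`p_basis: q`) for BH-adjusted values. Gene lists are distinct annotated
symbols. With a 25,000-gene universe, planted signals at |δ| = 1 log2
unit and n = 100/100, roughly 95% of planted resistant-region contrasting
genes land in Set 1, no contrasting gene lands in Set 2 (the significance
filter excludes them), and ~88–89% of planted parallel genes land in
Set 2 — the losses being the ~5% of truly-RoR-null parallel genes the
RoR test rejects at its nominal size, plus bottom-limb competition from
null genes with luckily small rank ratios. The vulnerable-region-only
contrasting class is, by construction of the score, *not* RoR-amplified
(it is strong in both rankings) and is claimed by neither set.

## PVCA

Probes are centered, the sample–sample covariance eigendecomposed, and
the smallest set of leading PCs whose cumulative eigenvalue fraction
reaches `var_threshold` (default 0.6) retained. Each retained eigenvector
is fit with a linear mixed model containing every covariate as an
independent random intercept, estimated by EM-REML (all covariates
jointly; max 500 iterations, tolerance 1e-8 on the variance-component
updates). Continuous covariates are discretized into quantile bins
(default quartiles) to serve as grouping factors; single-level covariates
are excluded with a warning; a PC whose fit does not converge is counted
as pure residual, again with a warning (EM converges promptly for PCs
carrying real covariate signal and crawls only when components sit at the
zero boundary, so the fallback biases toward residual on noise PCs).
Covariate proportions are averaged across retained PCs with
eigenvalue-fraction weights and normalized to sum to one.

The panel helper runs PVCA on three views of one matched dataset:
vulnerable-region-only, resistant-region-only, and the within-case
interregional ratio matrix. Per-sample quality covariates (pH, RNA
integrity) appear twice in the ratio view — once per region — giving nine
covariates against seven in the single-region views; the ratio view's
batch is taken from the vulnerable-region sample. Only the qualitative
pattern is a contract (batch dominant before correction, residual > 65%
after); exact bar heights depend on the variance-component estimator and
binning and are not reproduction targets.

## Synthetic cohorts

The generator emulates a matched post-mortem brain cohort:

* `y[g,s] = μ_g + r_g·1[vulnerable] + Σ covariate effects +
  δ_{class(g),region(s)}·1[case] + ε`, ε ~ N(0, σ²_g),
  σ²_g ~ s0²·d0/χ²(d0) with defaults d0 = 4, s0² = 0.05 (mean residual
  SD ≈ 0.3 log2 units, heavy-tailed — typical of microarray residuals).
* Planted classes: `contrasting_resistant_up` δ = (0, +1),
  `contrasting_vulnerable_up` δ = (+1, 0), `parallel_up` (+1, +1),
  `parallel_down` (−1, −1), `null` (0, 0); 200 genes per class by
  default. The magnitude 1.0 log2 unit is a calibration choice (a
  two-fold disease effect), not an empirical estimate.
* Covariates: age (60–95 y), sex, post-mortem interval (2–30 h),
  preservation method per individual; pH (5.8–7.2) and RNA integrity
  (5–9) per sample; batch (8 levels) round-robin over individuals with
  the resistant-region sample shifted one batch so batch is never
  confounded with region. Demographic/quality effects are per-gene random
  coefficients; batch is a per-batch offset shared across genes with
  per-gene lognormal scaling — the low-rank structure that makes batch
  dominate sample covariance as in real array data. Default effect SDs
  (batch 0.40, sex/preservation 0.10, pH 0.12, RIN 0.05, age 0.004/y,
  PMI 0.006/h log2 units) were chosen once to make batch the dominant
  non-random component.
* All randomness flows from one integer seed split hierarchically by
  purpose, so adding covariates does not perturb the gene noise stream.

What the generator does **not** model: probe-level cross-hybridization,
dye or normalization artifacts, correlated gene modules, cell-type
composition shifts, or covariate–disease confounding (covariates are
drawn independently of diagnosis). Passing recovery tests therefore shows
the statistics behave as designed under the stated noise model, not that
real cohorts are this clean.

## Problem sizes and numerical choices

Tests run the full stack at 25,000 genes × 200 individuals (the largest
check), with smaller fixtures elsewhere; the acceptance script uses the
same sizes. Floats are serialized at 12 significant digits; identical
configurations reproduce byte-identical output files. Tie-breaks in
priority ordering are deterministic (log P, then probe id). The
trigamma inversion brackets from above by doubling and bisects to 1e-10.

## Known limitations

* The residual-df mismatch after covariate correction (above) makes
  downstream p-values very slightly anti-conservative; fitting a single
  joint linear model per probe would remove it at the cost of the modular
  stage structure.
* EM-REML near zero-variance boundaries is declared non-convergent and
  counted as residual; a Fisher-scoring or profiled-likelihood estimator
  would converge there but can leave the parameter space.
* Unmatched mode ignores any within-individual correlation that matched
  mode exploits; its standard errors are conservative when samples are in
  fact paired.
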