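# Methods

## Scope and design

`twostepmr` implements two-sample Mendelian randomization (MR) from GWAS
summary statistics, the sensitivity analyses conventional in that
literature, and two-step (product-of-coefficients) mediation. All
estimators consume a `HarmonizedSet` — per-SNP exposure/outcome effect
pairs expressed for a common effect allele — so harmonization is the single
entry point for data quality and every method downstream is purely
numerical. The estimators follow the scikit-learn protocol (constructor
hyper-parameters, `fit`, trailing-underscore fitted attributes) so they
compose with sklearn tooling; module-level functions wrap them for
one-line use.

## Harmonization

Outcome records are aligned to the exposure's effect allele by label
matching, allowing for swapped labels and strand complements. Palindromic
SNPs (A/T, C/G) cannot be resolved by labels; the default policy
(`infer_by_eaf`) aligns them by which side of 0.5 the effect-allele
frequency falls on in each study, and drops them when either frequency is
missing or lies inside the ambiguity band [0.42, 0.58]. A `drop` policy
removes all palindromic SNPs. Duplicate variant IDs within one study keep
the smallest-p row; irreconcilable allele pairs are removed and logged.
These policies are package choices — common practice in two-sample MR —
since the upstream convention is not otherwise pinned down.

## Instrument selection

Defaults: p < 5×10⁻⁸ (strict inequality), greedy LD clumping at r² ≤ 0.001
within a 10,000 kb window, MR-PRESSO outlier removal, then an F = β²/SE²
≥ 10 filter (F exactly 10 is kept; "less than 10" is excluded). Clumping
visits SNPs by ascending p, breaking ties by lexicographic variant ID for
cross-platform determinism; when variant coordinates are absent the window
is ignored and r² alone governs. LD is always supplied as a matrix
(square TSV with a header of variant IDs); SNPs absent from it are treated
as independent, with a log entry. The pipeline applies PRESSO after
harmonization (it needs outcome betas) and before the F filter, matching
the order the selection cascade is usually described in.

## Estimators

* **Wald ratio**: beta = b_y/b_x, se = s_y/|b_x| (first order, exposure
  uncertainty ignored). b_x = 0 is a degenerate-instrument error.
* **IVW**: beta = Σ w b_x b_y / Σ w b_x², w = 1/s_y². The default
  `multiplicative_random` effects model inflates the fixed-effects SE by
  √(Q/(n−1)) only when that factor exceeds 1; `fixed` never inflates. One
  instrument falls back to the Wald ratio (logged); p-values are two-sided
  normal.
* **MR-Egger**: WLS of b_y on b_x with a free intercept, weights 1/s_y²,
  each SNP oriented so b_x ≥ 0 first. SEs use se_fixed × max(1, σ̂) —
  the convention of the standard two-sample MR tooling — and p-values are
  t with n−2 df for both slope and intercept. Requires ≥ 3 instruments.
* **Weighted median**: ratios sorted, normalized cumulative weights
  w_j = 1/se(ratio_j)² accumulated as (cumsum(w) − w/2)/Σw, and the
  estimate interpolated linearly where that crosses 0.5. SE by parametric
  bootstrap (resampling b_x, b_y from normal(b, s)), default 1000
  replicates, fixed seed.
* **Simple/weighted mode**: the argmax of a Gaussian KDE over the ratios
  (equal weights or 1/se²), bandwidth = `bandwidth_factor` × 0.9 ×
  min(sd, MAD) × n^(−1/5) (modified Silverman; MAD normal-consistent).
  The KDE is evaluated on a 512-point grid spanning the ratios ± 3
  bandwidths. When the bandwidth degenerates to zero (e.g. a majority of
  identical ratios makes the MAD zero) the estimator returns the discrete
  weighted mode, ties toward the smallest ratio — this keeps consensus
  datasets exact rather than grid-limited. SE by the same parametric
  bootstrap.

`run_all_methods` reports all five with IVW primary; with two instruments
only IVW is reported (others flagged absent), with one the IVW falls back
to the Wald ratio.

## Sensitivity diagnostics

Cochran's Q uses weights b_x²/s_y² around the supplied IVW estimate with a
χ²(n−1) upper tail; heterogeneity is flagged at p < 0.05. The Egger
intercept test reports pleiotropy at p < α and a screening pass only for p
strictly greater than 0.05. Leave-one-out refits IVW omitting each SNP and
flags "driving" SNPs whose omission flips the estimate's sign or moves p
across 0.05. Scatter- and funnel-plot data are emitted as tables (b_x vs
b_y with fitted lines; ratio vs precision), not images.

**MR-PRESSO.** The global test computes the weighted residual sum of
squares of leave-one-out IVW predictions and ranks it within `n_sim`
(default 1000) parametric simulations of the outcome betas under the
no-pleiotropy model; the per-SNP outlier test ranks each observed squared
residual within its simulated tail, Bonferroni-adjusted over the
instrument count at α = 0.05; removal is applied once (no recursion). The
distortion test ranks the |full − corrected| IVW shift against bootstrap
resamples of the non-outlier instruments. All resampling is vectorized
and deterministic given the seed. Empirical p-values can be exactly zero
for gross outliers; the global p uses the (1+k)/(1+n) convention.

## Mediation and screening

Beta XY = Beta X × Beta Y exactly; direct = total − Beta XY, so the
decomposition closes to machine precision by construction. The product CI
uses the first-order delta method, Var = Beta X²·se_y² + Beta Y²·se_x²,
omitting the second-order se_x²·se_y² term — this choice reproduces the
published bound arithmetic recomputed by `scripts/acceptance.py`. The
proportion CI divides the product-CI bounds by the total-effect point
estimate, in division order (bounds may therefore print "reversed" when
the total is negative); uncertainty in the total effect is ignored, again
matching the published arithmetic. Mediation labels combine the
proportion's sign (partial vs attenuating) with the mediated effect's sign
(negative/positive mediation): a protective total effect with a negative
mediated component of the same sign is a "partial negative mediation".

Screening retains a pair only if (1) IVW p is below the stage cutoff
(0.05 by default; 0.01 is conventional for the mediator→outcome stage),
(2) all five methods agree in sign, and (3) the Egger intercept p is
strictly above 0.05. Passing pairs are "significant" below the
Bonferroni-corrected level 0.05/n_tests and "suggestive" otherwise. Stage
family sizes are configurable (`bonferroni_n`); the pipeline defaults use
179 exposure screens, 15 exposure→mediator screens, and 731
mediator→outcome screens, the family sizes of the motivating study.
Screens short-circuit: only triples passing every stage reach mediation.

## Synthetic data generator

The generator emulates the *statistical shape* of a two-step MR study, not
any particular cohort: marginal SNP effects from the structural model
X = Σγ_j G_j, M = αX + Σδ_k G_k, Y = τ′X + b_m M (+ pleiotropy), with
estimated betas drawn as b̂ = b_true + N(0, se), se = 1/√(2·maf·(1−maf)·n),
and independent noise in the three cohorts (no sample overlap). Defaults:

| parameter | default | rationale |
|---|---|---|
| instruments per trait | 30 each | typical post-clumping count for a well-powered trait |
| γ ~ N(0.2, 0.05) | exposure SNP effects | z ≈ 38 at n_exp: instruments are genuinely genome-wide significant, F ≈ 1400 |
| δ ~ N(0.35, 0.10) | mediator SNP effects | at n_med = 3757 a mediator locus needs β ≈ 0.15 for 5×10⁻⁸; immune MFI traits have such large-effect loci |
| α = 0.4, b_m = 0.25, τ′ = 0.1 | structural effects | true mediated proportion 0.5, a clearly detectable signal |
| n_exp = 100,000 | exposure cohort | modern lipid-GWAS scale; keeps weak-instrument regression dilution negligible |
| n_med = 3,757 | mediator cohort | flow-cytometry immune GWAS scale; also keeps the exposure's SNPs *below* 5×10⁻⁸ in the mediator study, so step-2 instrument selection is uncontaminated, as in the naive two-step design |
| n_out = 31,430 | outcome cohort | effective sample size 4/(1/cases+1/controls) of a ~2%-prevalence case-control study of ~400k, since the SE model has no case-fraction term |
| maf ~ U(0.1, 0.4) | common variants | keeps all EAFs outside the palindrome ambiguity band so harmonization is exercised without attrition |
| palindrome fraction 0.2 | allele labels | exercises the EAF-inference path |

Binary outcomes are simulated directly on the log-odds summary-statistic
scale rather than via individual-level logistic sampling: two-sample MR
consumes only summary statistics, and this keeps a full tripartite study
below a millisecond. LD blocks, when configured, share one causal signal
per block (members duplicate the block's γ) so clumping has real work to
do; the block-diagonal r² matrix has constant within-block r² and zero
between blocks.

What the generator does **not** emulate: winner's-curse selection of
instruments from the same data, sample overlap between cohorts, allele
errors, population stratification, INDELs/multi-allelics, or realistic LD
decay. Passing recovery and calibration tests therefore demonstrates
correctness of the estimators under the stated model, not robustness of
MR itself to those real-data pathologies.

## Numerical choices and degenerate inputs

Normal quantiles use Φ⁻¹(0.975) (≈1.96) throughout; printed-CI widths are
interpreted as 3.92 SEs when SEs are recovered from published intervals.
Exact-zero SEs are tolerated in `HarmonizedSet` (useful for algebraic
tests); p-values then degenerate to 0 or 1. Egger's design matrix always
includes an explicit intercept column even when exposure betas are
constant (the fit is then minimum-norm and effectively unidentified — real
instrument sets vary in strength). Clumping, bootstraps, PRESSO and the
generator are deterministic given their seeds; bootstrap SEs use ddof=1.

## Simulation sizes

The validation suite uses 500 replicates for IVW parameter recovery, 2000
for Egger-intercept type-I calibration, 100 seeds for PRESSO outlier
detection, 1000 for IVW coverage, and 200 full pipeline runs for
mediated-proportion recovery — sizes at which the Monte-Carlo error of
each checked quantity is several times smaller than its acceptance band,
while the whole suite stays interactive (well under a minute of
simulation time).

## Known limitations

* No multivariable MR, Steiger directionality filtering, radial MR, or
  simultaneous multiple-mediator decomposition; mediators are treated one
  at a time and the delta-method CI ignores covariance between stages.
* The proportion CI conditions on the total-effect point estimate; for
  totals near zero the proportion and its CI are unstable (a zero total is
  an error).
* LD must be supplied; there is no reference-panel computation, liftover,
  or VCF ingestion.
* The PRESSO distortion test is a bootstrap approximation and its p-value
  should be read qualitatively.
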