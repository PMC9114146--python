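# Methods

This note records the statistical model behind each pipeline, the defaults
and why they hold, the numerical choices, and the limits of what the
synthetic-data validation can show.

## Allele-count reconstruction

For one SNP in one study the published triple (OR, SE of log OR, and the
study-level sizes N_cse, N_cnt) determines the 2×2 allele-count table
through the Woolf estimator

    OR  = (a_cse·u_cnt)/(a_cnt·u_cse),
    SE² = 1/a_cse + 1/u_cse + 1/a_cnt + 1/u_cnt,

together with the margins a_cse + u_cse = 2N_cse and
a_cnt + u_cnt = 2N_cnt.  Solving the OR equation for
a_cnt = 2N_cnt·x / (OR·(2N_cse − x) + x) with x = a_cse reduces the system
to one equation, SE²(x) = SE²_target, on the open interval (0, 2N_cse).
SE²(x) diverges at both endpoints and is strictly convex between them, so
the solution set is empty (SE below the attainable minimum — flagged
infeasible and skipped in batch runs), a single tangent point, or two
roots.

**Identifiability.** The two-root case is not a numerical artefact: the
full system is invariant under simultaneously swapping allele labels and
case/control status, e.g. (900, 1100, 700, 1300) and (1300, 700, 1100,
900) produce identical (OR, SE) at N = 1000/1000.  No inverse can separate
the two from summary data alone.  The package returns the solution whose
pooled effect-allele frequency is ≤ 0.5 — the minor-allele convention
common to most GWAS outputs — and falls back to the smaller-a_cse root if
both candidates fall on one side.  Users whose effect allele is the major
allele should flip alleles before reconstruction.  All round-trip
guarantees (and tests) are stated within this identifiable region.

**Numerics.** The minimiser of SE²(x) is located by bisecting the analytic
derivative (90 iterations, bracketing interval shrinks below 1e-25 of its
width), each monotone branch is then bisected for its root and polished
with three Newton steps.  Reconstruction of 10⁵ SNPs takes about one
second; cell-level round-trip error is at machine precision (~1e-14
relative).  Counts are kept fractional throughout — they are effective
counts, not observed integers.  Genotype counts follow from within-group
HWE as N·p², 2N·p·q, N·q²; GWAS-grade inputs are assumed to have had
HWE-violating SNPs removed upstream.

## Weighted logistic regression

All pipelines fit Bernoulli log-likelihoods over *patterns*: distinct
covariate rows (intercept, genotype 0/1/2, study covariate) carrying
fractional case/control weights.  This aggregation is lossless because the
likelihood depends on the data only through pattern counts, and fractional
weights are required downstream (overlap deflation scales counts by
non-integer factors).  Newton/IRLS iterates until the L1 norm of the
coefficient update drops below 1e-4 (the convergence threshold common in
GWAS tooling; because Newton converges quadratically, the remaining error
is O(10⁻⁸)); max 25 iterations.  Standard errors come from the inverse of
the final Hessian X'DX.

Firth's bias correction maximises the Jeffreys-penalised likelihood via
the hat-value-adjusted score U = X'(W(y−μ) + h(½−μ)), max 100 iterations;
standard errors use the Fisher information at the Firth estimate (the
standard choice in penalised-logistic software).  It is engaged
automatically when the total case/control ratio or the max/min study size
ratio reaches 5 — the regime where plain logistic regression is
anti-conservative — and can be forced on or off (`--firth on|off`).
Estimates with |β| > 30 are flagged as separated; non-convergence yields a
flagged row rather than an exception in batch runs.

## Fixed-effect meta-analysis

Per SNP, each study's reconstructed genotype counts are pooled into one
regression Pr(y=1|g,s) = sigmoid(β₀ + β₁g + β₂s).  For two studies s is a
0/1 indicator; for L > 2 it is the per-study overall effect-allele
frequency I_ℓ = (a_cse+a_cnt)/(a_cse+a_cnt+u_cse+u_cnt) — a single
continuous covariate that both orders the studies and absorbs between-study
stratification.  When I is constant across studies for a SNP (identical
cohorts) the covariate is dropped for that SNP and the fit reported with a
`NO_STUDY_COVARIATE` flag, preserving per-SNP output in a corner the model
cannot identify.

**Sample overlap.** Declared overlap enters as effective-sample-size
deflation λ_cse = N_cse/(N_cse + N_shr_cse) (controls analogous), with
shared counts summed over partner studies and off-diagonal shared samples
(case in one study, control in the other) counting half toward each group.
Allele *frequencies* are reconstructed at the reported sizes and the
genotype *counts* are then formed at λ·N.  Deflating before reconstruction
instead is not generally feasible: the published SE can lie below the
minimum attainable SE at the deflated size (at full self-overlap it always
does), whereas frequency-level reconstruction is defined for every valid
input and makes the full-overlap self-meta-analysis reproduce the
single-study SE (observed within 0.3%, tested at 2%).  Increasing declared
overlap never decreases a SNP's SE.

**Overlap estimation.** With unknown overlap, the Pearson correlation r of
the two studies' Z-scores over SNPs that look null in both (|Z| < 1.96; at
least 500 such SNPs required) is inverted through
r·√(N₁N₂) = N_shr_cse·√(N₁cnt·N₂cnt/(N₁cse·N₂cse)) + N_shr_cnt·√(…⁻¹),
assuming shared samples split like min(N₁cse,N₂cse):min(N₁cnt,N₂cnt).
Negative r clamps to zero; estimates cap at the smaller study's group
sizes.  The assumed split is logged with the estimate.  A duplicated study
recovers its full size within 5%; independent studies estimate ≈ 0.

## Case-case GWAS

Study-1 cases versus study-2 cases are regressed on genotype (intercept +
genotype only), giving β_case = β_g + β_s; the same regression on the two
control groups — assumed to carry neither trait — gives the stratification
component β_s; β_g = β_case − β_s is the trait-differential effect.

**Variance of β_g.** The case-only and control-only regressions use
disjoint samples, so their errors are independent and
SE_g² = SE_case² + SE_s².  We deliberately do *not* treat β_s as a fixed
offset (SE_g = SE_case): at balanced sizes that choice doubles the
variance of the null z-statistic (measured var = 2.00 over 4·10⁴ null
SNPs) and inflates the type-I error at p < 5·10⁻⁵ by two orders of
magnitude, which is incompatible with the error control this design is
meant to deliver (and with the calibration the validation suite asserts).
With propagation the null z is standard normal (measured var = 1.00, KS
uniform).  Both components are reported per SNP.

SNPs whose stratification estimate is noisy (SE_s > 0.05, roughly the
precision of ~2000 controls per study at common frequencies) are flagged
`FILTERED`, written to the audit file and excluded from the primary
output; the threshold is a flag (`--se-s-max`).  β_g is antisymmetric
under study swap, with identical p-values.

## Group PRS

With base weights S_i = log OR (default; log OR/SE behind `--weight z`)
over M SNPs surviving the p-value threshold, the target study's group
means and variances follow from reconstructed case/control frequencies:
mean = Σ S_i p_i / M and Var = Σ S_i² p_i q_i / (2M²), the latter assuming
HWE and between-SNP independence — hence the base must be pre-clumped
(clumping itself is out of scope; a `--snp-list` filter is provided).  The
case/control comparison is a two-sample t with pooled-frequency variance
and df = N_cse + N_cnt − 2.  Group means equal brute-force individual
means identically (they depend on genotypes only through frequencies); the
estimated SD matches the empirical SD of simulated cohorts within ~1% at
20,000 individuals × 500 SNPs.  Declared base/target overlap deflates the
target's group sizes (df and the t denominator) by the meta-module λ
factors — an effective-sample-size approximation, logged when applied.
The 1/(2M) score scaling is kept fixed, so absolute PRS values are
comparable only at equal M.

## Synthetic-data generator

The generator reproduces the validation conditions: ancestral effect-allele
frequency 0.3 per SNP; per-study subpopulation frequencies drawn from the
Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F) at F_st ∈ {0.01, 0.05, 0.1}
(F_st = 0 returns p exactly); multiplicative allelic risk r ∈
{1.15, 1.2, 1.3} for causal SNPs with the rare-disease approximation
p_case = r·p/(r·p + 1 − p), controls at the population frequency — a
construction whose realised case/control allelic OR equals r exactly.
Genotype counts are drawn multinomially over HWE class probabilities
(distributionally identical to materialising individuals and orders of
magnitude faster); shared samples are a separately drawn block added to
both studies' counts.  Summary statistics come from the resulting allele
tables via the Woolf estimator with a +0.5 continuity correction on zero
cells; this stands in for running a per-individual GWAS per study, which
is exact in expectation here because each simulated study is internally
homogeneous (no admixture, so covariate correction would be a no-op).
All randomness flows from one integer seed in a fixed order; runs are
bit-reproducible.

Three SNP classes drive the case-case evaluation: trait-differential
(effect in exactly one study), null, and stress (the same effect in both
studies).  Rates are scored at p < 5·10⁻⁵; stress SNPs whose realised
per-study ORs differ by ≥ 0.1 are excluded from the stress error rate, as
their apparent divergence is generator sampling noise.

**What passing does and does not show.** The generator has no LD, no
admixture within a study, no covariates, no genotyping error, and its
disease model is the rare-disease allelic construction.  Calibration and
power results therefore validate the reconstruction-and-regression
machinery under exactly these conditions; on real data, power additionally
depends on how the per-study GWAS was produced (penetrance-model effects
make realised ORs exceed the generating relative risk, covariate-adjusted
ORs are not collapsible with unadjusted ones) and error control on how
much residual within-study structure the original GWAS left uncorrected.
Panel sizes in the validation suite are 10⁴–5·10⁵ SNP tests per scenario,
chosen to put Monte-Carlo error well below the effects being measured.

## Known limitations

* Reconstruction is exact only for statistics that behave like a 2×2
  allelic (or equivalent logistic) test; covariate-adjusted or
  mixed-model effect sizes violate the Woolf relation by an amount the
  package cannot detect per SNP.
* The minor-allele convention silently picks the wrong table when the
  effect allele is the major allele overall; orient inputs first.
* Strand-ambiguous (A/T, C/G) SNPs are matched literally, never
  strand-flipped; irreconcilable allele pairs are dropped and counted.
* Case-case GWAS assumes control groups free of both traits and supports
  no overlap correction between the two case cohorts.
* Between-pair overlap for L > 2 uses pairwise sums only (no three-way
  de-duplication), and estimated overlap resolves per study pair, not per
  SNP.
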