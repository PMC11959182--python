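# Methods

## Problem

Differential abundance analysis (DAA) asks, per microbial taxon, whether
its *absolute* abundance differs between two sample conditions, given only
sequencing counts.  Two features of metagenomics count tables make this
hard.  First, they are sparse: a zero count may mean the taxon is absent
(biological zero) or merely unsequenced at the sample's depth (sampling
zero), and any pseudo-count imputation conflates the two.  Second, counts
are compositional: a library of size `L_i` measures only each taxon's
share, so absolute comparisons require a scaling factor linking relative
to absolute abundance.

This package addresses both with two ideas.  Zeros are treated as
**left-censored observations** at the detection limit `d` (default 1, the
smallest observable integer count): a zero in a sample of library size
`L_i` says only that the relative abundance is below `d / L_i`, which is
exactly what a censored likelihood term encodes.  The compositional gap is
closed by a **reference set of non-DA taxa**: if `T0` contains only
non-differentially-abundant taxa, then for every taxon j

    (R_j(2) / sum_{k in T0} R_k(2)) / (R_j(1) / sum_{k in T0} R_k(1))
        = A_j(2) / A_j(1),

i.e. relative abundances normalized by the summed reference share recover
absolute fold changes.  Two further exact identities drive reference
selection: fold-change *order* is preserved between relative and absolute
scales, and under a minority-DA assumption a taxon's relative-abundance
fold change equals the median fold change exactly when the taxon is not
DA.  The test-suite's noise-free profile harness asserts all of these to
floating-point accuracy.

## Censored regression (Tobit) with a Jeffreys penalty

For taxon j, the response is a per-sample log abundance quantity `v_ij`
(log relative abundance in stage 1, log reference-normalized count ratio
in stage 3), modeled as `v = x_i' beta_j + sigma_j eps`, eps standard
normal, left-censored at a known per-sample bound `c_i = log(d / D_i)`
(`D_i` the normalization denominator).  The log-likelihood is the usual
censored-Gaussian sum: density terms for observed values, `log Phi` terms
for censored ones (`scipy.special.log_ndtr` handles the deep tail).

Rare taxa frequently exhibit complete separation — detected only in one
condition — under which the unpenalized fold-change estimate diverges.
All per-taxon fits therefore maximize a penalized likelihood

    l(beta, log sigma) + 0.5 * logdet I(beta, log sigma),

with `I` the *expected* Fisher information of the censored model,
accumulated per observation from closed-form weights in the standardized
censoring point `alpha_i = (c_i - x_i' beta) / sigma`:

    I_mumu    = [(1 - Phi) + Pq] / sigma^2
    I_musigma = [phi + alpha * Pq] / sigma^2
    I_sigsig  = [2 (1 - Phi) + alpha phi + alpha^2 Pq] / sigma^2

where `Pq = phi * (alpha + lambda)` and `lambda = phi / Phi` is the
inverse Mills ratio at `alpha`.  As `alpha -> -inf` (censoring out of
reach) these reduce to the Gaussian information `X'X / sigma^2` and `2n`
for `log sigma`; as the fit drifts toward explaining all censored data
with an arbitrarily low mean the information vanishes, the log-det penalty
diverges to minus infinity, and the estimate stays finite.  The
information is computed jointly over `(beta, log sigma)`; the expected
(not observed) form needs every observation's censoring bound, which the
response object carries.

**Likelihood-ratio testing under penalization.**  Comparing maximized
penalized objectives of a full and a column-deleted null model is
miscalibrated: the two penalties have different dimension and their
log-det difference does not vanish (measured type-I error ~0.30 at
nominal 0.05).  Instead the null fit constrains the tested coefficient to
zero *inside the full model*, keeping the penalty's information matrix
full-dimensional — the construction used by Firth-penalized logistic
regression (`logistf`).

**Small-sample calibration.**  Even so, the chi-square(1) reference is
anti-conservative at microbiome-study sample sizes: with *no censoring at
all* a 1-df Gaussian-regression LRT at n=50 has size ~0.07, because the
exact reference there is F(1, n-k).  The statistic `T` is therefore
mapped to the F scale, `F = (n - k)(exp(T/n) - 1)` referred to
`F(1, n-k)` — algebraically the classical F test in the uncensored
Gaussian limit, a close approximation under censoring, and convergent to
chi-square(1) as n grows.  Measured sizes across censoring levels at
n=50 are 0.037–0.058, and the suite asserts KS-uniformity of null
P-values.

**Optimization.**  L-BFGS-B on `(beta, log sigma)` from a deterministic
start (least squares on proxied responses; `log sigma` at the log residual
RMS, floored at 1e-3), gradient tolerance 1e-8, at most 200 iterations,
`log sigma` box-bounded in [-12, 12] to keep degenerate zero-variance fits
from running away.  Both gradients are analytic: the likelihood score in
closed form, and the penalty gradient via
`d logdet M / d theta = tr(M^-1 dM/d theta)`, which collapses to one
weighted pass over observations because every information block is a
per-observation sum.  A singular information matrix returns a large
negative guard value rather than NaN.  Non-convergence yields a flagged fit, never
an exception: one pathological taxon must not kill a 500-taxon run.

## Skewness gate: beta-uniform mixture

If no taxon is DA, the pooled stage-1 P-values are approximately uniform.
Excess small P-values are detected by fitting
`w ~ pi U(0,1) + (1 - pi) Beta(alpha, 1)` with `0 < pi <= 1`,
`0 < alpha < 1` (constraining the beta component to right skew), and
testing `H0: pi = 1`.  The uniform null has log-likelihood exactly 0, so
the LRT statistic is twice the fitted log-likelihood, clipped at zero.
Fitting uses a deterministic grid multi-start (10 x 10 over pi and alpha,
vectorized scan, three best starts refined by L-BFGS-B); P-values are
floored at 1e-12 because the density involves `w^(alpha - 1)`.

Because the null pins `pi` on the boundary with `alpha` unidentified,
neither chi-square(1) nor the `0.5 chi2(0) + 0.5 chi2(1)` boundary mixture
is exactly calibrated — the latter was measured at type-I 0.086 for 500
pooled P-values.  The default reference is therefore a parametric
bootstrap: the null LRT distribution under uniform P-values depends only
on how many there are, so 499 null statistics are simulated once per set
size (fixed internal seed, hence deterministic) and cached; the test
P-value is the usual `(1 + #{null >= stat}) / (1 + B)`.  The boundary
mixture remains available (`method="mixture"`).  The gate level defaults
to 0.05.

## Reference selection by iterative halving

Given stage-1 fold-change estimates `b_j`, distances
`d_j = |b_j - median(b)|` are computed and the strict rule
`{k : d_k < median(d)}` keeps roughly the half of taxa closest to the
median.  When mass ties make the strict set empty or larger than half,
the `floor(P/2)` smallest-distance taxa are kept (stable ties by original
order); if every distance is identical there is nothing to distinguish
and the whole set is returned.  Each candidate subset is vetted by
refitting Tobit models to within-subset count proportions
(`y*_ik / sum_{k' in subset} y_ik'`) and applying the skewness gate to the
pooled P-values; halving repeats on the surviving subset (median
recomputed within it) until the P-values look uniform or left-skewed.
The subset may not shrink below `max(10, ceil(0.05 P))` — a reference of
one or two taxa makes the normalization denominator's variance explode;
the floor is configurable.  If the floor is reached without a clean
verdict the last admissible subset is returned flagged `exhausted`.

Normalization denominators sum **raw** counts (the censoring proxy
appears only in the numerator); summing proxied counts instead is
available via `denominator_mode="starred"`.  A sample whose subset
denominator is zero has it replaced by the detection limit, with a logged
warning, so the design matrix stays intact.

## Pipeline and outputs

1. Prevalence filter (default: drop taxa nonzero in strictly fewer than
   5% of samples; taxa exactly at the cutoff are kept), metadata
   alignment (intercept + condition + optional covariates; fail-fast on
   missing values), censoring transform.
2. Stage 1: per-taxon Tobit on log relative abundance; skewness gate.
   If the gate does not reject, the global-null verdict is set and the
   stage-1 fits are final — normalizing by all taxa equals normalizing by
   the library size.
3. Otherwise stage 2 selects the reference and stage 3 refits **every**
   taxon (reference taxa included; a reference taxon flagged DA is
   reported as a contamination diagnostic) against the log ratio to the
   summed reference counts.
4. Benjamini-Hochberg adjustment (statsmodels) of the final P-values;
   a taxon is called DA when its adjusted P-value is below `alpha`
   (default 0.05).  Effect sizes are reported as log10 fold changes of
   absolute abundance (natural-log coefficients internally).

Even under a global-null verdict the per-taxon P-values are reported and
BH-adjusted, so false-positive-rate evaluation and real-data workflows
behave identically in both branches.

## Synthetic data generator

The generator emulates the standard zero-inflated log-normal /
multinomial picture of amplicon sequencing: per-taxon log-mean drawn from
Normal(0, sd 2), log-sd from Uniform(0.5, 2), baseline absence
probability from Uniform(0.2, 0.8) — neutral hyperpriors chosen to yield
the 60–80% zero fraction typical of 16S tables.  Per sample, taxa are
silenced Bernoulli-wise, present taxa get log-normal abundances
(optionally sharing a single-factor Gaussian copula, the
`taxa_correlation` knob), the composition is renormalized, the library
size is log-normal (mean per condition, log-sd 0.5), and counts are one
multinomial draw — so zeros arise both biologically and from sampling,
and sampling zeros co-vary with library size.

A DA taxon shifts both its presence logit and its log-mean between
conditions, partitioned so that its *expected absolute abundance* changes
by exactly the configured fold (default 5): presence responds by a logit
shift of the signed log fold, and the log-mean absorbs the remainder.
`direction="unbalanced"` puts all shifts on one side (the regime that
breaks symmetric-normalization methods); `"balanced"` alternates signs.
An optional confounder is a continuous covariate correlated with the
condition (`rho`, default 0.5) affecting a configurable 10% of taxa.

What the generator does **not** emulate: taxon-taxon ecological
interaction structure beyond the single-factor copula, overdispersion
beyond the log-normal/multinomial hierarchy, real taxonomic abundance
spectra (hyperparameters are neutral, not estimated from reference
cohorts), or longitudinal designs.  Passing tests therefore demonstrate
calibration and power under this stylized but standard generative family,
not under any particular real cohort.

## Evaluation harness

`run_experiment` simulates, analyzes and scores seeded replicates
(replicate r uses `base_seed + r`).  FPR is the fraction of truly non-DA
taxa with raw P < 0.05 (the raw scale is the conventional type-I error
reading); FDR and the zero-discovery ("null decision") accuracy use the
BH-adjusted calls at 0.05; FDR is 0 when there are no discoveries, and
power counts discovered true DA taxa against all planted DA taxa,
including any removed by the prevalence filter.  Replicate failures are
counted and warned about, never silently dropped.  An oracle mode reruns
stage 3 with the true non-DA set as reference and reports the Jaccard
overlap of the two call sets.

## Problem sizes and defaults used in shipped experiments

The acceptance script and end-to-end tests run 100 replicates per
scenario at P=100 taxa with N=50 (null; mean library size 1e4) or N=100
(DA scenarios; 10% and 20% DA, fold change 5, unbalanced, library size
2e4).  These sizes keep a full run in the ten-minute range on one core
while leaving Monte-Carlo standard errors small enough for the reported
rates to be meaningful; larger designs (e.g. 500 taxa, 500 replicates)
are reachable by configuration.

## Known limitations

- The F calibration of the penalized LRT is exact only in the uncensored
  Gaussian limit; under heavy censoring the measured per-test size drifts
  mildly conservative (~0.04 at 70–85% censoring, n=50).
- Two-condition (or continuous) designs with fixed effects only: no
  multi-group contrasts, no random effects or longitudinal structure.
- The detection limit is a single global scalar; per-sample limits are
  out of scope.
- The BUM gate's bootstrap calibration assumes the pooled P-values are
  independent under the null; compositional coupling between taxa makes
  them mildly dependent, which the gate tolerates but does not model.
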