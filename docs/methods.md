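# Methods

This note documents the statistical models implemented in `stratgwas`,
the choices made where the design was open, and what the synthetic-data
validation does and does not establish.

## Stratified design

The package analyzes gene–environment interaction for a dichotomizable
exposure (age group, sex) by **stratification** rather than by an
interaction term in a single model. Stratified fitting makes no
assumptions about how the other covariates interact with the exposure;
comparing the per-stratum genotype coefficients then tests the
interaction directly.

For the age axis, strata are defined by separate cutoffs for cases and
controls — the median age within each status group — with `<=` assigned to
the younger stratum. Splitting cases and controls at their own medians
keeps both strata close to the original case-control balance even when
cases are systematically older than controls. A sensitivity preset
contrasts "truly young" cases (≤65 y) with "truly old" cases (≥85 y),
dropping the intermediate cases, with controls still split at their
median. The sex axis uses the recorded category. All downstream machinery
is stratum-label-agnostic: the sex analysis is the age analysis relabeled.

## Per-stratum association: Firth-penalized logistic regression

Each variant is fitted additively (dosage in [0, 2] as a continuous
allele count, the standard treatment for imputed data) in
`status ~ dosage + PC1 + PC2 + WGA`. The likelihood is penalized by the
Jeffreys prior, `PL(β) = l(β) + ½ log det I(β)`, removing the
leading-order bias of ML and guaranteeing finite estimates under complete
separation — routine when rare variants meet modest strata. The penalized
score `U*(β) = X'(y − π + h∘(½ − π))`, with `h` the hat-matrix diagonal,
is solved by Newton iteration with step-halving that never lets the
penalized likelihood decrease; convergence is declared when the score
max-norm falls below 1e−6 (cap: 50 iterations, 10 halvings per step;
non-convergence is flagged on the result and warned about, never silently
returned). Standard errors come from the penalized information matrix.

P-values are **Wald**, `2·Φ(−|β̂/se|)`. A penalized-likelihood-ratio test
would be slightly better calibrated in tiny samples, but the difference
and joint statistics consume (β̂, se) pairs, and Wald keeps the per-stratum
P, the difference test and the joint test mutually consistent.

Variants with stratum **minor allele count < 20** are excluded (computed
on dosages within the stratum, after any upstream filtering — the MAC
filter precedes the genomic-control estimate). Monomorphic variants are
skipped with a logged reason.

## Genomic control

λ_GC = median(z²)/0.4549364 over variants outside exclusion windows
(known loci ±10 Mb), per stratum. The correction inflates standard errors
by √max(1, λ): β̂ is left untouched so that the correction propagates into
the difference and joint tests through the se terms, and deflation is
never applied (λ floored at 1). A configurable floor on the number of
retained variants (default 1,000) guards against estimating λ from a
handful of variants.

## Difference and 2df joint tests

With per-stratum estimates (β̂_A, se_A), (β̂_B, se_B):

    Z_diff  = (β̂_A − β̂_B) / √(se_A² + se_B² − 2 r se_A se_B)
    C_joint = (β̂_A/se_A)² + (β̂_B/se_B)²,  P_joint = exp(−C_joint/2)

`r` is a single genome-wide scalar — the Spearman rank correlation of the
two strata's β̂ across the variant intersection — not a per-variant
quantity. For disjoint strata it is near zero (the package default is
0.03, matching what median-split case-control data typically show), and
it is re-estimated from the scans whenever ≥100 shared variants are
available. All tests are two-sided. Variants surviving the MAC filter in
only one stratum are excluded from both tests (logged), since both pairs
are required.

The joint test is the source of power when effects are concentrated in or
differ between strata: two per-stratum P-values of ~1e−5 each, far from
genome-wide significance alone, jointly clear 5e−8.

The focused candidate lookup tests a supplied list of m known lead
variants at the Bonferroni threshold 0.05/m and annotates qualitative
interaction: an effect nominally present in exactly one stratum, or
nominally significant effects of opposite sign.

## Regions, conditional analysis, loci

Clumping is greedy: sort by P ascending (ties: chromosome, then
position), take the best unassigned variant as lead, absorb unassigned
variants within ±10 Mb on the same chromosome, repeat. Within a region,
conditional analysis re-runs the stratified Firth fits with the dosages
of all accumulated leads as extra covariates and re-applies the
difference/joint test to the conditioned (β̂, se); while the smallest
conditioned P clears 5e−8 the best variant joins the lead list. Variants
with r² > 0.95 with any current lead are skipped as collinear (this
covers conditioning a variant on itself). The loop is bounded by the
region's variant count.

Locus boundaries: all variants with r² > 0.5 with the lead (squared
Pearson correlation of dosages, computed on all samples by default;
controls-only is a caller choice), extended by 500 kb each side, floored
at position 1. Genes whose 1-based span intersects the boundaries are
attached. Coordinates are 1-based inclusive internally; BED output
converts to 0-based half-open.

## Fine-mapping

Single-causal Wakefield approximate Bayes factors from association
z-scores: `ln BF = ½ ln(se²/(se²+W)) + ½ z² W/(se²+W)` with prior
variance `W = (prior sd)²` on the log-odds effect. The prior sd defaults
to **0.2**, a conventional value for case-control log-odds effects; it is
exposed in configuration. Posteriors are the softmax of the log-BFs (flat
prior over which variant is causal); the 99% credible set is the smallest
descending-posterior prefix reaching 0.99. The z supplied by the pipeline
is the inverse-variance-weighted combination of the two stratum estimates
(an overall-association z computed from the fits already in hand); a
caller can instead pass a single stratum's z. Regions with more than one
independent signal from the conditional analysis are refused — the
one-causal model does not apply — rather than silently mis-modeled.

## Gene priority score

Equal-weight sum of eleven binary evidence columns per gene (expression
in retina and in RPE/choroid at FPKM > 1 — strictly greater; mouse eye
phenotype; ≥1 credible-set variant; protein-altering; 5'/3' UTR; other
exonic/splice; promoter ±1 kb; local eQTL; essentiality; Mendelian
retinopathy). `'+'` scores 1; `'-'`, `'0'` and `'NA'` score 0, with
unknown (`NA`) preserved distinctly from absent on output. Ranking is by
descending score with alphabetical tie-break. A weight vector is accepted
for reuse but defaults to ones.

## Power

The difference-test power uses the standard case-control variance
approximation under HWE, `se² = (1/N_case + 1/N_ctrl)/(2·EAF·(1−EAF))`
per stratum, noncentrality `|ln OR_A − ln OR_B|/√(se_A²+se_B²−2 r se_A se_B)`,
and two-sided normal power `Φ(−z_{α/2}+ncp) + Φ(−z_{α/2}−ncp)`. When the
two odds ratios coincide this returns α exactly. The allele frequency
behind a power claim must be supplied; 0.3 is the default, and the
≥80%-power conclusions for the shipped sex-difference scenarios hold
across EAF ∈ [0.2, 0.5].

## Synthetic data: what it emulates, and what it does not

The generator draws variant allele frequencies from a configurable
spectrum (default U(0.05, 0.5)), genotypes under Hardy–Weinberg, and
optionally imputation-like truncated-normal dosage jitter bounded in
[0, 2] (default 0: hard calls). An optional block-LD mode builds each
haplotype as a copying chain — allele j+1 copies allele j with
probability `decay`, else is drawn fresh at the block's frequency — so
adjacent-variant correlation is `decay` and r² is `decay²`; blocks share
one frequency to keep the chain stationary and reversible, which is what
lets causal-conditional regeneration propagate both directions.

Disease status follows a logistic model `logit P(case) = logit(prev) +
Σ_v β_{stratum,v} g_v (+ optional covariate effects)` with prevalence
0.05 by default. Sampling is **retrospective**: group quotas (stratum ×
status) are filled by rejection from the population, which leaves the
genotype log-odds-ratio identified while absolute risk is deliberately
not modeled. Unattainable quotas (e.g. huge protective effects at tiny
prevalence) fail explicitly after bounded attempts. Only causal variants
inform status, so their columns (and LD blocks) are regenerated
status-conditionally; all other variants keep unconditional draws — exact
under the no-LD-with-causal factorization.

Ages are drawn per group around the configured cutoffs (defaults shaped
around case median 77.8 y / control median 71.0 y) and recorded to 0.1 y;
just enough younger ages are tied exactly at the cutoff that the pooled
within-status median equals it, so a median split reproduces the
configured group sizes exactly — the same mechanism (ties at a rounded
cutoff) that makes unequal younger/older counts possible in real data.
Group templates whose younger side cannot contain the pooled median are
rejected as unattainable. PCs are standard normal, WGA is Bernoulli
(p=0.1), sex is Bernoulli (p_female=0.55) on the age axis; covariate
effects on disease default to zero. Identical configurations (including
seed) reproduce byte-identical datasets.

Not emulated: population structure and relatedness (the PCs are pure
noise covariates), chromosome-scale recombination maps, imputation
quality varying with frequency, age–genotype confounding, and cohort
effects. Passing calibration/recovery tests therefore demonstrates
correctness of the statistical machinery under the stated model, not
robustness to those real-data complications.

## Validation scales and numerical choices

The test suite's calibration block scans 50,000 null variants (strata of
1,000 cases + 1,000 controls, simulated in 10,000-variant chunks to bound
memory): difference-test type-I error at 0.05 is checked against its 99%
binomial interval and per-stratum λ_GC against [0.98, 1.02] on the full
set, while the joint-P uniformity KS check (α = 0.01) runs on a
10,000-variant chunk — at much larger n the KS test becomes sensitive to
the benign ~1% finite-sample shrinkage of penalized Wald z at stratum
size 2,000, which is a property of the per-stratum statistic at that
sample size, not of the 2df combination rule. Effect recovery uses 200
replicates of a strong age-interacting variant (stratum ORs 2.29/1.81,
group sizes 7,959/9,072/7,934/8,653, MAF 0.5), requiring ≥90% CI coverage
per stratum and mean bias below 0.05; credible-set coverage uses 200
single-causal 21-variant LD regions (decay 0.95, OR 1.5, MAF 0.2–0.4),
requiring the causal variant in ≥95% of 99% sets.

Tie-breaks are deterministic throughout (stable sorts; clump ties by
chromosome then position; GPS ties alphabetical; credible-set ties by
variant id). Degenerate inputs fail loudly: rank-deficient designs name
the collinear columns, monomorphic variants are skipped or reported as
r² = 0 with a warning, empty strata and non-binary outcomes raise.

## Known limitations

* Wald-based inference is slightly conservative at small stratum sizes
  (z sd ≈0.987 at n=2,000), visible only at very large variant counts.
* The single-scalar `r` is an approximation; per-variant correlation
  would matter if strata overlapped substantially.
* Fine-mapping assumes exactly one causal variant per locus and a single
  shared prior width; multi-causal regions must be conditioned first and
  are otherwise refused.
* Conditional analysis is exact (refit with lead covariates) and thus
  needs individual-level data; no summary-statistic approximation is
  provided.
* The power module covers the difference test only, not the 2df joint
  test.
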