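# Methods

`prognosig` implements a hybrid gene-signature discovery and risk-scoring
pipeline for expression cohorts with survival follow-up, together with the
evaluation machinery (survival stratification, enrichment, cell-line
chemoresponse) used to characterize such signatures.  This note documents
the models, their assumptions, the tunable parameters, and the numerical
conventions fixed by the implementation.

## Prognosis dichotomization

Patients are split at a survival horizon (default 60 months): death at or
before the horizon is *high-risk*, survival past the horizon is *low-risk*,
and censored cases whose follow-up ended before the horizon are excluded as
uninformative.  Two boundary conventions are fixed and configurable only by
changing the horizon: a death at exactly the horizon is high-risk, and a
case censored at exactly the horizon reached it alive and is low-risk.
Times are handled internally in months.

## Differential-expression screening

Two per-gene two-sample t-tests are provided: the Welch statistic with
Welch–Satterthwaite degrees of freedom (`different_variance`, the default
screen) and the pooled-variance statistic with n1+n2−2 df.  Genes with zero
spread in both classes are reported as t = 0, p = 1 with a flag rather than
NaN.  All p-values are two-sided.

The SAM screen computes the moderated relative difference
d_i = (x̄₁ − x̄₂)/(s_i + s₀), where s_i is the gene-specific pooled standard
error and s₀ an exchangeability constant that stops low-variance genes from
dominating.  With s₀ = 0 the statistic is exactly the pooled t statistic —
asserted per-gene on random matrices in the test suite.  In `auto_percentile`
mode s₀ is chosen among the percentiles (0, 5, …, 100) of s_i to minimize
the coefficient of variation of the median-absolute-deviation of d across
100 quantile windows of s_i, the standard recipe for making the spread of d
independent of s.  The null is built from B label permutations (default
B = 300, minimum 25); the expected relative difference d̄_(i) is the mean of
the i-th permutation order statistics.  For a threshold δ the asymmetric
cuts scan outward from the origin of the observed-vs-expected plot: the
first ordered gene departing by ≥ δ fixes the cut and everything beyond it
is significant, which makes the significant set non-increasing in δ by
construction.  FDR(δ) is the median across permutations of the number of
permutation statistics beyond the cuts, divided by the observed count (π₀
fixed at 1 by default; a 90th-percentile variant of the numerator is not
provided).  δ is searched on the sorted grid of observed |d_(i) − d̄_(i)|
deviations, so resolution adapts to the data; the smallest δ achieving the
target FDR (default 25%) is taken, and an unreachable target raises an
error reporting the minimum achievable FDR.

Candidate genes are the intersection of the t-test screen (p < 0.01 by
default) and the SAM significant set, in expression order.

## Relief ranking and stepwise selection

Relief scores each candidate gene by local class separation.  The default is
ReliefF with k = 10 nearest hits and misses (k = 1 recovers classic Relief):
for each sampled patient (default: all, in order), neighbors are found under
Manhattan distance on range-normalized values, and
W(A) accumulates +diff/(m·k) toward misses and −diff/(m·k) toward hits with
diff(A, x, y) = |x_A − y_A|/range(A).  A constant gene has range 0, diff
defined as 0, hence weight exactly 0.  Distance ties break by sample order;
equal weights keep input probe order (stable sort); weights are invariant to
positive affine rescaling of any single gene.

The ranked list feeds a forward wrapper search: the top gene is always
taken, each subsequent gene is kept iff the stratified k-fold (default 10)
cross-validated accuracy of the Gaussian Naive Bayes classifier strictly
increases, and the search stops at the first rejection.  The folds are drawn
once from the seed and reused at every step so accuracy differences reflect
gene sets, not fold noise.  This strict stopping rule is deliberately
conservative; on noisy labels it tends to select small signatures (one to
six genes in the synthetic studies below).

## Naive Bayes risk score

The risk model assumes conditionally independent Gaussian expression per
gene given the class.  Priors are maximum-likelihood class frequencies (no
smoothing); means and SDs are per-class sample statistics (denominator
n−1).  Each SD is floored at 1e−6 times the gene's observed range (with a
tiny absolute fallback) so a within-class constant gene still defines a
proper density; published parameter tables with means up to ~2500 and SDs
~580 motivate doing all likelihood arithmetic in the log domain, with
log-sum-exp normalization.  The posterior probability of the high-risk class
is the continuous risk score; the decision rule is strictly greater than
0.5 (a posterior of exactly 0.5 is low-risk).  A published 12-gene lung
adenocarcinoma model (priors 0.45/0.55 and all per-class Gaussian
parameters) ships as a checksum-verified TSV and can be applied without
retraining.  The calibration curve bins samples by posterior (default width
0.05), reports 1 − KM survival at the horizon per bin with Greenwood
(log-log) 95% CIs, and flags bins with fewer than 5 samples as unstable.

## Survival evaluation

Kaplan–Meier estimation, the log-rank test, and Cox proportional-hazards
fits are delegated to lifelines, with conventions pinned: Greenwood log-log
confidence intervals, and Efron handling of tied event times (month-
resolution follow-up ties heavily).  Categorical covariates expand against
declared reference levels.  The concordance probability estimate is the
Gonen–Heller form K = (2/n(n−1)) Σ_{i<j} 1/(1+exp(−|η_i−η_j|)) on the Cox
linear predictors — censoring-independent, exactly 0.5 for constant
predictors.  Horizon sensitivity/specificity take truth from the
dichotomization rule; censored-before-horizon cases are excluded from both
denominators (the declared handling for an operation the source material
leaves unspecified).

## Enrichment

Genes are ranked by signal-to-noise (μ₁−μ₂)/(σ₁+σ₂) with each σ floored at
max(0.2·|μ|, 1e−8) — so a globally constant gene scores 0 — or by Welch t;
ties break by probe id.  The enrichment score is the signed extremum of the
weighted Kolmogorov–Smirnov running sum (hit increments ∝ |score|^p
normalized over the set, default p = 1; uniform miss decrements).  At p = 0
the ES equals the classic two-sample KS statistic between hit and miss rank
distributions, which the tests exploit for hand-checkable oracles, and the
p = 1 walk is cross-checked against gseapy.  Phenotype labels are permuted
(≥ 100 permutations), NES is the observed ES over the mean same-sign
permutation ES, and the FDR q follows the standard pooled positive/negative
NES procedure.

## Chemoresponse

A drug's log10(GI50) profile is z-normalized over the cell lines with data
(missing values excluded, never imputed); lines at least +0.5 SD above the
mean are resistant, at least 0.5 SD below sensitive, the rest intermediate
(boundaries inclusive).  Intermediate lines are excluded from
classification.  The reference classifier is k-nearest-neighbor (k = 3,
Euclidean on per-gene z-scored profiles) under leave-one-out
cross-validation; any callable with a (train_X, train_y, test_X) signature
can be plugged in instead.  Reported "sensitivity" is the fraction of
resistant lines called correctly (detection of chemoresistance),
"specificity" the fraction of sensitive lines.  Significance compares the
observed overall accuracy with that of random same-size gene signatures
drawn uniformly from the profiled universe (default 1000), with the +1
correction p = (1 + #{random ≥ observed})/(n_random + 1), so p is never 0
and its floor at 1000 draws is ≈ 0.001.

## Synthetic data generator

The cohort generator draws what the pipeline assumes: each sample belongs to
a latent prognosis class (fair coin); informative genes are
Normal(μ ± effect·σ/2, σ) per class (defaults μ = 300, σ = 60, effect 1.0,
20 informative among 2000 genes, n = 300); all other genes are
class-independent.  Negative draws are truncated at 0 — truncation rather
than resampling keeps the draw count, and hence reproducibility, independent
of parameters.  Survival is Weibull (shape 1 = exponential, the default)
with low-risk median 90 months and the high-risk hazard multiplied by 3,
which yields roughly 55% deaths within the 60-month horizon — the mortality
scale of a resectable lung adenocarcinoma cohort.  Censoring is independent
Uniform(0, c) with c solved numerically so the expected censored fraction
matches the requested rate (default 20%).  One root seed expands into
independent child streams (class, expression, survival, censoring) via
`SeedSequence.spawn`, so enlarging the gene panel never perturbs the
clinical draws.

Note that the dichotomized prognosis labels are a noisy readout of the
latent class: with these defaults about a third of true low-risk patients
die before the horizon and a quarter of true high-risk patients survive it.
This label noise attenuates every downstream statistic relative to the
latent truth — deliberately, since real five-year outcomes are equally
noisy proxies of tumor biology.  What passing tests show is therefore
recovery of planted structure *through* that noise; the generator does not
attempt Affymetrix probe-level noise, batch effects, correlated gene
modules, or non-Gaussian intensity distributions, so performance on real
arrays is not implied.

The panel generator gives each cell line a latent standard-normal response
that is added (in SD units) to each signature gene and scaled by
`response_effect` (default 1.5) into the log10(GI50) vector plus unit noise.
At effect 2 the signature-restricted kNN-LOOCV accuracy averages ≈ 0.89
over seeds; near-perfect separation needs effect ≈ 4.

## Problem sizes

The test suite and the acceptance script run at the study scale the
generator defaults define: discovery on 2000-gene, 300-sample cohorts
(25 seeds for signature recovery, 20 for independent-cohort
stratification), 10,000 fuzzed posterior-oracle cases, 1000-replicate
log-rank and 10,000-p-value Welch calibration checks, 500-replicate Cox
coverage, and 200 null panels for the permutation-p super-uniformity check.

## Known limitations

- The stepwise stopping rule (strict first-failure) is faithful to its
  description but greedy; with noisy labels it often stops at very small
  signatures whose held-out stratification varies widely between cohort
  draws.  Training the risk model on a known (e.g. published or planted)
  signature is far more stable.
- SAM's FDR estimate uses π₀ = 1, which is conservative when many genes are
  differential.
- The Cox wrapper supports neither time-dependent covariates, stratified
  baselines, nor competing risks.
- GSEA provides phenotype permutation only (no gene-set permutation) and no
  leading-edge reporting.
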