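# Methods

This note records the models implemented in `m6apattern`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic-data
tests do and do not establish about real cohorts.

## Consensus clustering and k selection

Samples are clustered on a feature subset (by convention the 21 m6A
regulators), z-scored per gene so regulators with heterogeneous dynamic
ranges contribute equally. Each of `B` rounds (default 1000; the test and
reference configurations use 100, which is already stable for separable
data) draws `ceil(p_item · n)` samples without replacement (`p_item =
0.8`) and clusters them with the base clusterer. The consensus matrix is
the ratio of co-cluster to co-sample counts; sample pairs never co-drawn
(negligible at `B ≥ 100`, `p_item = 0.8`) contribute 0 with a logged
warning. Final labels cut an average-linkage tree on `1 − M` at `k`.

**Base clusterer.** The default is k-means with a *single random
initialization per resample*. This is a deliberate choice: PAC-based k
selection measures the instability of the partition across resamples, and
a fully deterministic base (hierarchical clustering) produces near-binary
consensus matrices at every `k` at or below the true cluster count — the
same merge happens in every resample — leaving PAC nothing to
discriminate on (measured: PAC(2) ≈ 0.01 < PAC(3) ≈ 0.02 on cleanly
3-clustered data, selecting k = 2 every time). Random restarts make
over-merged solutions visibly unstable (PAC(2) ≈ 0.67, PAC(3) ≈ 0.03; k =
3 selected in every replicate). Agglomerative clustering with 1 − Pearson
distance and average linkage remains available via `base="agglomerative"`
and is the right choice when one wants a deterministic consensus matrix at
fixed `k` rather than a k-selection scan.

**k selection.** `k* = argmin_k PAC(k)` with `PAC = F(0.9) − F(0.1)`; ties
go to the smaller k. The consensus-CDF area and its relative increase
(delta-area) are reported for audit but do not drive the choice.

## ssGSEA

Integer rank weights (`z = N, …, 1`) rather than raw expression values are
used in the weighted in-set running sum — this stabilizes scores across
normalization conventions when array and RNA-seq cohorts are mixed.
`α = 0.25`, and the score is the *summed* deviation `Σ_i (P_in − P_out)`
over all N positions, not the maximal deviation. Expression ties are
broken by lexicographic gene id, making scores deterministic and invariant
to input gene order. Sets overlapping the matrix in fewer than 2 genes are
dropped with a warning; a set covering every gene is an error (the
out-of-set CDF is undefined). Optional normalization divides the whole
score matrix by its global max − min range (per-set range by flag).

## Moderated differential expression

Two-group pooled-variance t-tests with empirical-Bayes shrinkage of the
per-gene variance toward a common prior: `s̃²_g = (d0·s0² + d_g·s²_g) /
(d0 + d_g)`, moderated t with `d0 + d_g` degrees of freedom. The prior is
fit by method of moments on the log sample variances (digamma/trigamma
moment equations, trigamma inverted by Newton iteration); when the moment
equation has no positive solution the prior df is infinite and the prior
variance is the plain mean of the sample variances. This matches the
standard moderated-t estimator, verified against the R reference
implementation in the test suite. Phenotype-related genes are the
*intersection* of the three pairwise DEG sets at BH-adjusted p < 0.001
("overlap" read as intersection; union available by flag). No fold-change
filter is applied. An infinite prior df is encoded as `inf` in the output
and capped at 1e7 when used as a t df.

## Survival machinery

Kaplan–Meier is the plain product-limit estimator with Greenwood variance;
`survival_at` evaluates the right-continuous step function. The log-rank
test uses hypergeometric per-event-time expectations with the k-group
variance matrix and `k − 1` df.

Cox proportional hazards maximizes the Breslow partial likelihood by
Newton–Raphson with step-halving on any likelihood decrease; convergence
at max |score| < 1e-8 or 50 iterations. Breslow tie handling was chosen
over Efron because the pipeline's inputs are continuous expression scores
and survival times where ties are rare; on tie-free data the two coincide
(the test suite cross-checks coefficients and standard errors against an
independent survival library). A monotone likelihood (separation) is
flagged as non-converged with |β| capped at 20; screened genes that fail
to converge are never kept. Covariates are centered internally (the
partial likelihood is translation-invariant); categorical covariates are
one-hot encoded with the lexicographically first level as reference.

The max-stat cutpoint evaluates the standardized two-group log-rank
statistic `z(c) = (O1 − E1)/√V` at every distinct observed score value `c`
whose groups (`score ≤ c` vs `> c`) both hold at least `ceil(minprop · n)`
samples (`minprop = 0.1`), and picks the |z|-maximizer, ties to the
smaller cutpoint. The computation is vectorized over candidates via
cumulative at-risk/death counts in score order. No p-value is attached to
the maximal statistic: the selection inflates its null distribution far
beyond the nominal normal (the suite demonstrates |z| > 1.96 in well over
20% of null replicates), so downstream KM/log-rank contrasts on the chosen
groups are reported as descriptive.

## m6Ascore

Signature genes are z-scored across samples (correlation-scale PCA — the
score must be comparable across platforms with different dynamic ranges),
the samples × genes matrix is decomposed by SVD, and the score is the sum
of the first two principal-component projections. Using only PC1 + PC2
concentrates the score on the largest block of mutually (anti)correlated
signature genes and down-weights genes that do not track the rest of the
set. SVD component signs are arbitrary; they are fixed deterministically
(largest-|loading| gene made positive) and, when a reference signature is
supplied (e.g. a stromal or macrophage panel mean), each component is
flipped independently so it tracks the reference non-negatively. The
per-component flip matters: a single global flip cannot reconcile two
components that load on the reference with opposite signs. With the
reference orientation, a high m6Ascore carries the stromal/immune-excluded
meaning and a low score the inflamed meaning.

## Association statistics

Spearman (tie-aware, t-approximation p), Kruskal–Wallis (tie-corrected,
chi-square p; all-identical input returns H = 0, p = 1), Mann–Whitney
(exact for small untied samples, otherwise normal approximation with tie
correction), rank AUC (`U/(n1·n0)`, mid-rank ties), and the conditional
Fisher exact test (two-sided by the probability-mass rule, not doubling;
sample odds ratio `ad/bc` with a 0.5 continuity add when a cell is zero;
a zero margin yields p = 1 with the OR flagged undefined). TMB is the
nonsilent record count per sample (Missense, Nonsense, Frame_Shift_Ins/
Del, Splice_Site, In_Frame_Ins/Del); counts rather than per-megabase rates
because panel sizes are not part of the handled formats. Mutation
frequency uses distinct mutated samples per gene.

## Synthetic cohort generator

The generator emulates an ACRG-like gastric-cancer cohort and is the
substrate of every recovery test. Defaults: 300 samples; patterns A/B/C at
0.37/0.33/0.30; gene baselines N(5, 1) on the log2 scale with N(0, σ²)
noise, σ = 1; cluster templates separated by δ·σ with δ = 1.5.

- **Regulators (21, the real symbols):** each gene elevated by δ·σ in one
  pattern, round-robin, giving each pattern its own elevated regulator
  subset.
- **DEG block (200):** two anticorrelated transcriptional programs, as
  real phenotype-related blocks have — 70% a stromal/prognostic program
  whose pattern means track the latent-score ordering (A +δ, B −δ, C 0)
  and 30% an adaptive-immune program (B +δ, C −δ, A 0), with alternating
  member signs. Every gene separates all three pattern pairs (required by
  the intersection rule), and the block's leading principal axis aligns
  with the hazard-driving phenotype (presumed by the PC1 + PC2 score).
- **Cell-type markers (8 × 15):** innate/stromal populations (NK,
  macrophage, mast, MDSC, plasmacytoid DC) shifted +1.2 in pattern A and
  +0.2 in B; adaptive populations (CD8 T, CD4 T, B cell) +1.2 in B and
  +0.2 in A; pattern C flat — the immune desert.
- **Latent score:** `L = μ(label) + N(0, 0.5²)`, μ(A) = +1, μ(C) = 0,
  μ(B) = −1 (the stromal pattern scores highest, the inflamed lowest).
- **Survival:** exponential with hazard `0.01·exp(0.7·L)` per month,
  uniform censoring on (0, 120] — constant baseline hazard so closed-form
  checks are available (Weibull was rejected for exactly this reason).
- **TMB:** negative-binomial, mean `exp(3.0 − 0.5·L)`, dispersion 2 —
  medians in the tens with realistic overdispersion, anti-correlated with
  the score; records materialized in random genes with nonsilent classes,
  plus a Poisson(1) sprinkle of Silent records to exercise the class
  filter.
- **Response:** Bernoulli(logistic(−0.5 − 1.0·L)) — response rates near
  40% for low-score patients and ~15% for high-score ones.
- **Age:** N(62, 10), a null covariate for multivariable models.

Five RNG streams (latent, expression, survival, mutations, response) are
spawned from the master seed so single layers can be regenerated without
disturbing the others; identical parameters give bit-identical cohorts.

**What passing tests show and do not show.** The generator produces
Gaussian noise, block-structured means, proportional hazards, and
independent genes within blocks. Recovery there demonstrates the
implementation is correct and the procedures are consistent under their
own assumptions. It does not establish robustness to real-data features
that are absent by design: gene–gene correlation beyond block structure,
batch effects, heavy-tailed or count-valued expression, non-proportional
hazards, or informative censoring.

A note on one ceiling: the latent score carries within-cluster noise (sd
0.5) that no expression-derived, label-driven score can rank, so the
Spearman correlation between a perfect recovery and the latent score is
itself only ≈ 0.82 (range 0.79–0.84 across seeds). The score-recovery
check is therefore evaluated as a median over a 10-seed simulation, where
the implemented score sits at that ceiling.

## Pipeline

Stages run in a fixed order (load → cluster → TME → DEGs → Cox screen →
m6Ascore → cutpoint/survival → mutation → ICB) with per-stage logging and
wall-times (informational only, never serialized). Optional inputs (MAF,
response column) skip their stages with a recorded `skipped` status; any
stage error aborts with the stage name after persisting the partial
report. All randomness flows from the single config seed (per-k consensus
seeds are derived from it), JSON is written with sorted keys, and floats
are rounded at the 12th decimal, so a fixed config yields a byte-identical
`report.json`.

Problem sizes used by the test suite and the acceptance script: reference
cohorts of n = 300 with 100 consensus resamples; Cox recovery at n = 500
over 200 replicates; cutpoint recovery at n = 500 over 10 seeds; null
error-control batteries at 20–500 replicates.

## Known limitations

- Efron tie handling, time-dependent covariates, and competing risks are
  not implemented; Breslow is adequate for continuous scores but will
  differ on heavily tied time grids.
- The maximal-statistic selection-bias-corrected p-value (improved
  Bonferroni / asymptotic process approximations) is out of scope; the
  cutpoint is reported with descriptive downstream contrasts only.
- ssGSEA here is the rank-weight variant; kernel-density (GSVA-style)
  scores and deconvolution methods are intentionally not provided.
- Probe-to-gene mapping, batch correction, and cohort merging are outside
  the package: inputs are assumed already gene-level and comparable.
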