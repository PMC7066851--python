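# m6apattern

Quantifying N6-methyladenosine (m6A) modification patterns in bulk tumor
expression cohorts, and scoring their tumor-microenvironment (TME)
consequences per patient.

m6A is a reversible mRNA modification controlled by 21 regulator proteins
(8 writers, 2 erasers, 11 readers). In gastric cancer, regulator expression
stratifies tumors into modification patterns with distinct immune
phenotypes — stromal/immune-excluded, immune-inflamed, and immune-desert —
that differ in survival, mutation burden, and checkpoint-blockade response.
`m6apattern` implements that analysis as a tested, seed-reproducible Python
pipeline for anyone with a gene-by-sample expression matrix, a clinical
table, and (optionally) mutation calls and immune-cell marker gene sets.

## What it computes

1. **Modification patterns** — resampling consensus clustering of samples
   on the 21 regulators. For `B` resamples of fraction `p` of samples, the
   consensus matrix entry `M_ij` is the fraction of co-draws in which `i`
   and `j` co-cluster. The cluster number `k` minimizes the proportion of
   ambiguous clustering, `PAC = F(0.9) − F(0.1)`, where `F` is the ECDF of
   off-diagonal consensus values.
2. **TME cell infiltration** — single-sample gene-set enrichment (ssGSEA).
   Per sample, genes are ranked (weights `z = N, …, 1`) and for a marker
   set `S`,
   `ES(S) = Σ_i [ P_in(i) − P_out(i) ]` with
   `P_in(i) = Σ_{g∈S, rank(g)≤i} z_g^α / Σ_{g∈S} z_g^α` (α = 0.25) and
   `P_out` the uniform CDF over non-members.
3. **Phenotype-related genes** — empirical-Bayes moderated t-tests between
   each pattern pair (prior `(d0, s0²)` fit by method of moments on log
   sample variances; `s̃²_g = (d0·s0² + d_g·s²_g)/(d0 + d_g)`),
   Benjamini–Hochberg control at adjusted p < 0.001, and intersection of
   the pairwise DEG sets.
4. **m6Ascore** — a univariate Cox screen keeps prognostic phenotype genes
   (Wald p < 0.05 on z-scored expression); PCA of the z-scored signature
   submatrix then gives `m6Ascore_s = PC1_s + PC2_s`.
5. **Survival dichotomization** — maximally selected rank statistics: the
   standardized two-group log-rank statistic over all admissible score
   cutpoints (`minprop = 0.1`), followed by Kaplan–Meier curves, log-rank
   tests, and uni/multivariable Cox models (Breslow ties, Newton–Raphson
   with step-halving).
6. **Associations** — tumor mutation burden (nonsilent counts), per-gene
   mutation frequencies, pairwise co-occurrence Fisher tests, Spearman
   score–TMB correlation, and checkpoint-response AUC / Fisher contrasts.

A first-class synthetic-cohort generator (`m6apattern.simulate`) produces
ACRG-like cohorts (~300 samples, 3 latent patterns on the 21 regulators, a
phenotype DEG block, cell-type marker structure, proportional-hazards
survival driven by a latent score, TMB anti-correlated with the score,
Bernoulli response) with the full generating truth recorded, so every
stage is testable against known ground truth.

## Worked example

```bash
m6apattern simulate --out cohort --seed 7 --n-samples 300
m6apattern run --config config.yaml
```

with `config.yaml`:

```yaml
expression: cohort/expression.tsv
clinical: cohort/clinical.tsv
regulators: cohort/regulators.txt
markers_gmt: cohort/markers.gmt
maf: cohort/mutations.maf.tsv
response_col: response
orient_to: Macrophage
outdir: out
consensus_reps: 100
seed: 7
```

`out/report.json` then contains (abridged, exactly as produced by the run
above):

```
"k_selection":   {"chosen_k": 3, "pac": {"2": 0.672, "3": 0.00002, "4": 0.255, "5": 0.320}}
"cluster_sizes": {"1": 100, "2": 93, "3": 107}
"phenotype_genes": {"n": 202}
"cox_screen":    {"n_tested": 202, "n_kept": 160}
"survival":      {"hr_high_vs_low": 2.51, "logrank_p": 5.7e-08,
                  "km_survival_60m": {"low": 0.589, "high": 0.306}}
"tmb":           {"tmb_spearman_rho": -0.40}
"icb":           {"auc_low_score_vs_response": 0.64}
```

Reading: PAC is minimized at k = 3, recovering the three generating
patterns; 202 phenotype-related genes survive the pairwise-intersection
rule, 160 of them prognostic; the high-m6Ascore group has a hazard ratio
of 2.5 versus the low group with 5-year survival 59% vs 31%; the score is
negatively correlated with mutation burden; and a low score predicts
checkpoint-blockade response above chance (AUC 0.64). All of this mirrors
the stromal/immune-excluded (high score) versus inflamed (low score)
biology the pipeline is designed to expose.

Every subcommand (`simulate`, `cluster`, `tme-score`, `deg`, `score`,
`survival`, `mutation`, `associate`, `run`) is a thin wrapper over the
library; the estimator classes `ConsensusCluster`, `SSGSEA` and
`M6AScorer` follow scikit-learn `fit`/`transform` conventions and compose
with sklearn pipelines.

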