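# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic cohorts do and do not emulate,
and the numerical conventions that make results reproducible.

## Quantification and sample QC

TPM is computed per sample over the selected long-RNA biotypes
(protein-coding + lncRNA by default): length-normalized rates RC_i/L_i are
scaled to sum to 10⁶, so the denominator runs over the *retained* genes
only. Construction of a `tpm`-tagged matrix enforces the column-sum
invariant at relative tolerance 1e-9. No between-sample normalization is
applied beyond TPM. All downstream work uses log₂(TPM + 1); the pseudocount
(default 1) is configurable.

Sample QC removes samples whose median pairwise correlation with all other
samples falls below a threshold (default 0.9). Correlation is Pearson on
log₂(TPM+1): the log damping keeps a handful of very abundant genes from
dominating the coefficient; Spearman and raw-TPM variants are exposed
because the choice of scale is a genuine free parameter here. Because the
score is rank-based downstream of QC only through sample inclusion, QC runs
once on the full cohort, before the train/validation split.

## Moderated-t differential expression

The contrast is the difference of group means of log₂(TPM+1) — a
linear-model log-fold-change, *not* log₂ of the ratio of group mean TPMs.
The two disagree in general (a gene can show mean-TPM ratio 2.1 with
fitted log₂FC 1.9); tables report both the log₂FC and the raw group mean
TPMs so the distinction stays visible.

Gene-wise pooled variances s_g² with d_g = n−2 df are shrunk toward a
scaled-inverse-χ² prior (d₀, s₀²). The prior is estimated on the
log-variance scale: with e_g = log s_g² − ψ(d_g/2) + log(d_g/2), the excess
of var(e) over ψ′(d_g/2) equals ψ′(d₀/2), inverted by Newton iteration
(trigamma inverse); s₀² follows from the mean of e. When the excess is
non-positive the prior df is +∞ (full shrinkage) — the degenerate case of
no detectable spread in the true variances. Zero-variance genes are floored
at machine epsilon with a warning and excluded from the prior fit. The
implementation agrees with the reference empirical-Bayes implementation in
the Bioconductor ecosystem to ~1e-15 on shared inputs (checked in the test
suite via Rscript).

Multiple testing uses our own BH step-up (cross-checked against a
brute-force tail-minimum oracle and statsmodels). The signature-candidate
rule is applied verbatim: biotype ∈ {protein-coding, lncRNA}, log₂FC >
0.59 (the published constant, not log₂1.5 = 0.585 — both exposed),
adjusted p < 0.05, expression frequency > 0.5. "Expression frequency" has
no standard definition in this context; we use the detection fraction
(share of samples with TPM above a threshold, default 0) and flag it as a
choice. Candidate order is deterministic: descending log₂FC, gene_id
tie-break.

## mRMR(MIQ) and incremental feature selection

Mutual information needs discrete inputs, so expression is three-state
coded per gene: −1 below μ−ασ, +1 above μ+ασ, else 0, with α = 1 over the
training samples (the classic mRMR preprocessing; continuous-MI estimators
were rejected for determinism). MI is the plug-in estimate in bits; empty
cells contribute zero. Greedy MIQ selection maximizes
I(f; class) / mean_{s∈S} I(f; f_s), with the redundancy denominator floored
at 1e-12 and argmax ties broken by gene_id, which makes the ranking
invariant to candidate input order.

IFS evaluates the top-k prefix for k = 1..K by leave-one-out
cross-validation: each held-out sample is scored by an SVM trained on the
rest, with per-feature z-scaling computed inside the fold (constant
features scale to zero contribution). The AUC is the rank-statistic
estimator P(score_pos > score_neg) + ½P(tie). Ties on the maximal AUC go to
the smallest k (parsimony). The SVM is C-classification, linear kernel,
C = 1, inverse-frequency class weights (the cohorts are imbalanced roughly
1:1.7); an RBF kernel (γ = 1/n_features) is available. Kernel and
regularization are design choices, not reconstructions — linear is the
reproducible default for n ≪ p gene panels.

## Frozen-model evaluation

The final SVM is refit on all training samples with the selected features.
Probability calibration is a Platt sigmoid fit by maximum likelihood on the
*training LOOCV scores* (not resubstitution scores, which would be
optimistic). The decision threshold maximizes Youden's J on the same LOOCV
scores, over midpoints of consecutive distinct scores, ties to the lower
threshold. Everything — features, scaler statistics, support
vectors/weights, Platt coefficients, threshold — is then frozen and
serialized to JSON; validation, independent-cohort and subgroup evaluation
only apply the stored rule. This is asserted structurally in tests
(shuffling evaluation labels cannot change a prediction).

AUC confidence intervals use DeLong's placement-variance method by default;
a stratified bootstrap (2,000 resamples, seeded) is available and agrees
within ~0.03 half-width at n ≥ 100. Subgroup plans select disjoint
case/control sets on design columns (cohort, stage, CEA status); subgroup
controls reuse the pooled cohort by default. The adenoma-vs-healthy
signature is the same pipeline invoked with case=CRA, control=healthy.

## ssGSEA, over-representation, group tests

The ssGSEA score of set S in a sample ranks genes by expression (average
ranks on ties, gene_id order as the final tie-break so scores are invariant
to row order) and sums, over the descending-rank list, the difference
between the weighted in-set ECDF (weights rank^α, α = 0.25) and the uniform
out-of-set ECDF. Being rank-based, the score is invariant to any strictly
monotone within-sample transform — which is also why the TPM-vs-log-TPM
ambiguity is immaterial here. "Range" normalization divides the whole
matrix by its largest absolute score, bounding it in [−1, 1]. This is the
scoring core used by signature-based cell-type estimation; spillover
compensation and calibrated reference signatures of the full xCell method
are out of scope — users supply their own marker GMTs, and the survival
screen consumes any score matrix.

Over-representation uses the exact hypergeometric upper tail
P[X ≥ overlap] after intersecting each pathway with the supplied universe,
BH-adjusted across pathways. Cohort comparisons use the Wilcoxon rank-sum
test per pair (exact when both groups ≤ 10 samples, tie-corrected normal
approximation otherwise) and one-way ANOVA on the scores directly across
the three cohorts, plus a flag for strictly ordered group medians
(healthy < CRA < CRC or reverse), the pattern expected of a
carcinogenesis-linked activity.

## Survival

Kaplan–Meier is the product-limit estimator; a sample censored exactly at
an event time counts as still at risk there (censoring after events). The
two-group comparison is the standard log-rank χ² with hypergeometric
variance at each event time (the test is the conventional companion of KM
analysis; it is cross-checked against lifelines). The screen dichotomizes
CRC samples at the median score, ties to the low group; direction is +1
when the high-score arm fares better (median survival, falling back to the
KM curves at the last event time). Controls never enter the survival
analysis. No Cox regression or multivariable adjustment is attempted.

## Synthetic cohorts

`simulate_cohort` emulates the statistical shape of a three-cohort plasma
exLR profile:

| parameter | default | rationale |
|---|---|---|
| n_genes | 15,000 | long-RNA genes detected in plasma EV libraries |
| cohort sizes | 72 / 42 / 80 | study-scale CRC/CRA/healthy design (scalable) |
| baseline abundance | log-normal, σ = 2.5 (nat. log) | log₂ sd ≈ 3.6, the 10–15 log₂-unit dynamic range of bulk profiles; yields inter-sample correlations ≈ 0.95, so QC at 0.9 behaves as on real cohorts |
| counts | NB, var = μ + φμ², φ = 0.2 | typical bulk RNA-seq overdispersion |
| library size | U(5·10⁶, 1.5·10⁷) | per-sample depth over the gene panel |
| gene length | U(200, 10,000) bp | enters both expected counts and TPM |
| planted genes | 20, log₂FC ∈ [1, 2] in CRC | drawn from the upper-half-abundance long-RNA genes (an undetectable marker could never pass the frequency rule); CRA gets the half effect (2^(FC/2)) to create the ordered trend |
| dropout | 5% overall, logistic in log μ | technical zeros concentrate in weakly expressed genes; uniform dropout would be unphysical and destroy sample correlations |
| survival | h(z) = 0.02·HR^z per month, HR = 2 per SD, 30% censoring | exponential times with log-hazard linear in a latent N(0,1) score; uniform censoring horizon solved to hit the target rate |

What it does *not* emulate: batch/center effects, GC or length bias in
capture, correlated gene modules (genes are independent given the cohort),
circRNA backsplice structure, and any real marker identity. Passing tests
therefore demonstrate that the *pipeline machinery* recovers planted signal
of the stated effect size under NB noise — not that any particular gene
panel works on real plasma. At the default planted effect (log₂FC 1–2) the
simulated problem is easier than the real one, which is why simulated AUCs
approach 1.0 while real-cohort AUCs of this design sit near 0.94.

## Numerical conventions and degenerate cases

- Single top-level seed; every stochastic step uses `numpy.random.default_rng`
  derived from it; reruns of deterministic stages are bit-identical.
- Problem sizes in the default test run and the acceptance script (2,000
  genes, half-scale cohorts, K ≤ 40, 100-rep power studies) were chosen so
  the whole suite completes in a few minutes on one core while keeping every
  statistical check well-powered.
- Trigamma inverse: Newton iteration with the asymptotic branches 1/x (x
  small) and x^(-1/2) (x large), tolerance 1e-10.
- BH uses a stable mergesort so tied p-values keep input order.
- Empty subgroups are skipped with a warning, not errors; disjointness of
  case/control filters is a hard error.
- A gene set with no member in the matrix is skipped (or raises under
  `strict=True`); universes and DEG lists are validated for containment.
- Zero-event log-rank returns NaN with a warning; zero-variance score sets
  are skipped in the survival screen.

## Known limitations

- The moderated-t engine covers the plain two-group contrast only (no
  covariates, pairing, or precision weights) — matching the analysis it
  implements, not the full generality of the reference implementation.
- mRMR discretization (α = 1 three-state coding) and the SVM kernel are
  explicit conventions; other choices can reorder mid-ranking candidates.
- DeLong CIs are asymptotic; at very small subgroup sizes the bootstrap
  option is preferable.
- The ssGSEA core scores any user-supplied marker sets; it does not attempt
  xCell's spillover correction, so scores of closely related cell types
  remain correlated.
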