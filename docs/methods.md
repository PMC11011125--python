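# Methods

This note documents the models and procedures the package implements, the
parameter choices that matter, what the synthetic cohorts do and do not
emulate, and the numerical conventions. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

Bone-marrow samples from allogeneic HSCT recipients, profiled before and/or
after transplant on a targeted RNA panel of 1408 cancer-associated genes at
roughly ten million fragments per sample, expression in FPKM. Endpoints are
binary: acute GvHD of any stage (observed in about two thirds of patients)
and overall survival (for modelling, the event is death). The analysis
predicts each endpoint from the expression matrix alone: select genes, train
a classifier, report ROC operating characteristics on a held-out third of
the cohort.

## Synthetic cohort generator

The motivating cohort is available only on request, so the package generates
cohorts with the statistical structure the analysis assumes:

* **Counts.** Negative binomial per gene and sample. Baseline mean counts at
  nominal depth are log-normal (median 60, log-sd 1.6), so FPKM spans
  several decades, as targeted panels do. Dispersion is shared across genes
  (default 0.3, within the range typically estimated for bulk RNA-seq of
  heterogeneous human tissue) and configurable.
* **Depth and lengths.** Library sizes uniform on (8, 12) million fragments
  around the nominal ten million; gene lengths log-uniform on 500–10,000 bp.
  Lengths exist only to make the FPKM conversion
  `counts * 1e9 / (length * total_fragments)` non-trivial.
* **Signal.** `n_informative` genes receive a signed log2 fold-change of
  common magnitude `effect_log2fc` in cases (sign random per gene), applied
  to the count mean before FPKM conversion. Defaults mirror the
  post-transplant arm: 119 samples, prevalence 0.67, 92 informative genes at
  log2FC 1. The untouched endpoint is drawn independently at the published
  rate (aGvHD 80/119; death 32/119).
* **Correlation.** Optional Gaussian copula within consecutive gene blocks
  (`block_size`, `block_rho`). The default is independence (`block_rho` 0):
  stability selection behaves differently under correlated features, so
  correlation is an explicit experimental dial rather than a hidden default.
  When `block_rho` is 0 the counts are drawn directly as a gamma–Poisson
  mixture; otherwise through the copula's NB quantile transform. Both paths
  are deterministic given the seed.
* **Onset days.** Cases get a log-normal onset day parameterized by its
  median (default 37.5 days, log-sd 0.6) — a cosmetic realism channel only;
  nothing downstream reads it.
* **Seeding.** One master seed; every draw comes from a named,
  counter-derived substream (`SeedSequence(seed, spawn_key=(k,))`), so adding
  a new feature never perturbs earlier draws.

What the generator does **not** emulate: batch effects, longitudinal pairing
of pre/post samples from the same patient, gene–gene correlation beyond the
block copula, isoform structure, zero-inflation beyond what NB produces, or
any coupling between the two endpoints. Passing tests on these cohorts
therefore show that the pipeline recovers planted marginal group differences
under overdispersed FPKM noise at realistic sample sizes — not that it would
attain any particular accuracy on real marrow data.

## Gene selection

Rank statistics throughout, so selection is invariant to any strictly
monotone transform of a gene's values (a property the suite tests):

* per-gene performance: tie-corrected two-sample AUC, folded to
  max(A, 1−A), averaged over 5 stratified inner folds (ranking needs no
  fitting, so "cross-validated" per-gene AUC is the mean held-out-fold AUC);
* per-gene significance: two-sided Wilcoxon rank-sum. The scalar API uses
  scipy (exact on small tie-free inputs); matrix-wide paths use the
  vectorized tie-corrected normal approximation with continuity correction —
  the only tractable form at 1408 genes × 100 subsamples × 12 folds. A gene
  constant across all samples gets p = 1 by convention.
* multiplicity: Benjamini–Hochberg across the panel. The original analysis
  does not state a correction; at 1408 genes some control is indispensable,
  and BH at α = 0.05 empirically keeps the null selection rate near zero
  (tested).
* stability: the fraction of B = 100 stratified 80% subsamples in which the
  gene passes the per-replicate BH criterion, in the spirit of
  Meinshausen–Bühlmann subsampling stability selection. Selected =
  (p_adj ≤ α) AND (frequency ≥ τ = 0.6). `max_genes` optionally truncates by
  cross-validated AUC (ties: smaller adjusted p, then symbol), to emulate
  fixed-size panel requests.

Defaults B = 100, fraction 0.8, τ = 0.6, α = 0.05 are package choices — the
original description ("performance of each gene with cross-validation …
stability measures using statistical significance tests") names no numbers —
and all are exposed in `SelectionConfig`.

## The GMB classifier

Gaussian class-conditional densities on log2(FPKM + 1) — the package-wide
transform for all Gaussian-model steps; the standard variance-stabilizing
choice for FPKM with closed-form fitting. Fitting uses per-class sample
means and unbiased (ddof = 1) variances, clipped from below at
`variance_floor` (default 1e-3 on the log2 scale) so constant genes cannot
produce infinite densities. Priors are empirical training class frequencies
by default, with an `equal` switch.

The class likelihood is the geometric mean of per-gene densities,
`G̃_c = exp(mean_g log f(x_g|c))`, and the reported score is
`π₁G̃₁ / (π₁G̃₁ + π₀G̃₀)`, computed as a logistic of the log-space margin. The
1/G exponent is the defining feature: it makes scores comparable across
panel sizes and invariant to duplicating the feature set, and it keeps the
margin bounded by the average (not the sum) of per-gene log-density ratios,
so 1000-gene panels with per-gene densities near 1e-300 score without
saturating (tested; the plain product variant is retained only as a
comparison arm and demonstrably fails both properties).

Cross-validated training scores: stratified k-fold, default k = 12, seeded
shuffle; every sample is scored exactly once out of fold. Two modes:

* `nested` (default): gene selection re-run inside each k−1 training
  portion — no selection leakage into the out-of-fold scores. A fold whose
  inner selection is empty is scored with the class priors alone (the naïve
  Bayes limit with no features): a constant, uninformative score. This is
  what makes the global-null calibration well defined — under no signal most
  folds select nothing and the out-of-fold AUC sits at chance.
* `paper`: one selection computed on the full training cohort is reused in
  every fold. This mirrors pipelines that select before cross-validating;
  it inflates apparent training performance (near-perfect training AUCs are
  its signature) and is retained deliberately so both behaviours are
  reproducible.

## ROC evaluation

Thresholds descend, with sentinels at ±∞; a score equal to the threshold is
called positive (≥ rule). The AUC equals both the trapezoidal area and the
tie-corrected Mann–Whitney probability (the suite checks the equivalence
exhaustively on small inputs). Standard errors use Hanley–McNeil's closed
form, Q1 = A/(2−A), Q2 = 2A²/(1+A) — note both reduce to 1/3 at A = 0.5 —
and the 95% interval is the unclipped Wald interval A ± 1.96·SE: published
intervals with upper bounds above 1 are only representable unclipped, so
clipping is left to the caller. The p-value is a two-sided normal test of
A = 0.5 using the null SE (the same closed form evaluated at A = 0.5 with
the observed class counts); conventions: p = 1 when SE = 0 and A = 0.5, the
smallest positive float when SE = 0 and A ≠ 0.5, and p is clipped into
(0, 1]. The cut-off rule is Youden's J = sens + spec − 1, ties broken toward
the smallest cut-off (favouring sensitivity); with completely uninformative
scores J = 0 everywhere and the −∞ sentinel is returned (sens 1, spec 0).
The original reports cut-offs without naming a rule; Youden is this
package's choice and is applied to training scores only, with the resulting
value transferred to the validation set (`cutoff_on="validation"` exists to
mimic the alternative reading).

## Pipeline and reproducibility

`run_endpoint_analysis`: stratified 2/3–1/3 split (training size exactly
round(2n/3); per-stratum apportionment by largest remainder, so class
proportions in the two halves differ by at most one sample's worth) →
selection on training only → k = 12 out-of-fold training scores → training
ROC and Youden cut-off → final model on the full training set → validation
scoring and ROC at the transferred cut-off. Validation labels are read only
at the final ROC; an empty selection stops the run with a structured
"no informative genes" report rather than an error. `run_all` executes the
four analyses (pre/post × aGvHD/survival) with independent derived seeds.
Every stage seeds from the run seed through named substreams; reports
serialize to sorted-key JSON, and rerunning with the same inputs reproduces
every artifact byte for byte (tested).

Problem sizes used by the test suite and acceptance script — 50 null
cohorts of 160 samples × 1408 genes for calibration, 20 planted-signal
cohorts of the same shape for recovery, 119-sample cohorts for the
study-scale demonstrations — were chosen as the smallest sizes at which the
tested properties are stable Monte-Carlo statements.

## Known limitations

* The selection screen is univariate: genes informative only jointly (e.g.
  through interactions) are invisible to it, and correlated informative
  genes split their stability frequencies.
* Gaussian-on-log densities are a modelling convenience; heavy-tailed or
  multimodal expression within a class violates them. The variance floor
  bounds, but does not remove, the effect of near-constant genes.
* The Hanley–McNeil interval is a large-sample normal approximation; at the
  validation sizes here (~40 samples) its coverage is approximate, and the
  unclipped bounds can exceed [0, 1] by construction.
* Binary endpoints only: no censoring-aware survival modelling, no
  multiclass grading of GvHD severity, no covariate adjustment.
* `paper` mode exists for comparability, not as a recommendation; its
  training metrics are optimistically biased by design.
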