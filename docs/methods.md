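# Methods

## Problem setting

Breast cancer tumors can be partitioned into three immune-infiltration
clusters — A (low), B (intermediate) and C (high) — with the intermediate
cluster B carrying the worst overall-survival prognosis. `immunosig`
implements a feature-selection pipeline that compresses a genome-wide
expression matrix into a small gene signature that (i) reproduces the
Cluster-B-vs-rest partition and (ii) separates prognosis on held-out
cohorts, followed by a classifier that needs no cohort-level
normalization and is therefore applicable to a single new sample.

## Pipeline

### Rank-sum pre-filter

Every gene is tested (two-sided Wilcoxon rank-sum) for differential
expression between Cluster B and the pooled A∪C samples; genes with
p > α are removed (α = 0.1 by default — deliberately permissive, since
this stage only prunes the search space for the elimination loop). The
implied false-discovery rate of the screen is reported with the plug-in
estimate α·m/k (m genes tested, k kept, all-null π₀ = 1). The rank-sum
p-value uses exhaustive enumeration of rank splits below a combined
sample size of 20 (exact, tie-aware via mid-ranks) and the tie-corrected
normal approximation with a 0.5 continuity correction at or above it;
the switchover point is where enumeration stops being cheap and the
approximation is standard.

### Iterative lasso backward elimination

An L1-penalized logistic model (one-vs-rest over the three clusters,
λ = 1, i.e. inverse regularization C = 1 in the liblinear convention;
the intercept follows liblinear's lightly-penalized-bias convention) is
refit on the active gene set. Gene importance is the largest absolute
coefficient across the three class models; ties break toward keeping
earlier-listed genes. While more than 900 coefficients are nonzero
(paper-scale default), the max(1, ⌊0.1·|Ω|⌋) least-important genes are
dropped per iteration; below that, one gene per iteration, stopping when
at most 50 remain. Both thresholds scale with the gene universe and are
configuration fields: the scaled-down synthetic studies shipped with the
package (200-gene pools) use 100/10, keeping the two-phase structure
proportionate. Every iteration's active set, weights and validation
metric are recorded in a trace; refits are from scratch, so a trace is
a deterministic function of data, configuration and seed.

### Model selection: Point A and Point B

Two criteria pick the final signature from the trace:

* **Point A (accuracy-driven)** — each iteration is scored by
  Cluster-B-vs-rest accuracy (three-class prediction collapsed to
  binary) on a held-out fraction of the training samples (20% at paper
  scale; 1/3 in the scaled study, giving a 400/200 split).
* **Point B (survival-driven)** — the test cohorts are split 50/50;
  each iteration is scored by the log-rank p-value between predicted
  B and not-B samples on the validation half; the untouched half is
  reserved for reporting. A predictor that sends all validation samples
  to one group is scored p = 1, which keeps the trace total while
  penalizing degenerate models.

Ties prefer the smaller gene set (the efficiency objective), then the
earlier iteration. Splits are stratified by cohort (and cluster where
labels exist) and fully seeded.

### Rank-decile classifier

For the Point-B signature Γ (N = |Γ|), each sample d is reduced to the
within-sample ranks R(g, d) of its signature genes (ascending, rank 1 =
lowest; ties broken stably by signature order so ranks are a full
permutation) and the decile features

    Q(g, d) = ⌈n_deciles · R(g, d) / N⌉,  n_deciles = 10 by default.

A categorical Naive Bayes model over Q separates GPx (good prognosis,
called not-Cluster-B) from BPx (bad prognosis, called Cluster-B), with
Laplace smoothing (α = 1; unsmoothed zero-count cells would send log
likelihoods to −∞) and empirical class priors. Posteriors are computed
in log space; an exact 0.5 posterior is called GPx, the conservative
default. Because Q depends only on within-sample order, the classifier
is invariant to any strictly increasing per-sample transform of the raw
data — the property that removes the need to normalize a new sample
into the training cohorts' context. This invariance is asserted over a
transform catalogue (affine with positive slope, exponential, power).

## Survival statistics

Kaplan-Meier curves use the product-limit estimator with Greenwood's
variance and an exponential-Greenwood (log(−log)) 0.95 envelope, which
respects the [0, 1] range; events precede censorings at tied times. The
Q3 marker is the first event time at which Ŝ(t) ≤ 0.75. The log-rank
test is the standard unstratified two-group form: observed-minus-
expected events over hypergeometric variance, summed across distinct
event times, referred to χ²(1). Both are validated against `lifelines`
in the test suite.

## Characterization statistics

* Hypergeometric enrichment/depletion of binary flags (e.g. somatic
  mutations) in the BPx class, exact tail sums inclusive of the
  observed count; depletion is the lower tail.
* Benjamini-Hochberg step-up for gene-level screens (via statsmodels).
* Pearson χ² independence for class-vs-PAM50 tables, no continuity
  correction.
* Tie-corrected Kruskal-Wallis for the lymphoid-score trend across the
  three clusters.
* Stability-intersection bound: k genes common to r repeated selection
  runs with set sizes s₁..s_r from a universe of U genes are scored
  under a uniform/independent null — per-gene all-runs inclusion
  probability q = Π sᵢ/U, bound P(X ≥ k) for X ~ Binomial(U, q),
  evaluated in log space so bounds far below 10⁻¹⁰⁰ remain finite. The
  degenerate single-run case returns 1 (a single set of size s ≥ k
  contains k of its own genes with certainty). The default universe is
  the post-filter gene count, since selection operates on filtered
  genes; the bound is insensitive to any plausible choice.

## Synthetic data

The generator emulates the structure the pipeline assumes, not any real
cohort: per-gene N(0, 1) normalized expression; a planted informative
subset with an additive mean shift (effect size in SD units) in Cluster
B only; cluster labels drawn i.i.d. with probabilities (0.4, 0.3, 0.3);
exponential survival with per-cluster hazards (0.08, 0.16, 0.08) per
year — Cluster B at double hazard — and uniform-within-interval
censoring at rate 0.3; a lymphoid score increasing A→B→C (unit step per
cluster plus unit Gaussian noise); PAM50 labels drawn independently of
cluster (they are consumed, never derived); and a raw-scale matrix
raw = exp(normalized + per-sample offset), strictly positive and a
within-sample monotone image of the normalized values — the link the
rank classifier's invariance tests rely on. Cohorts differ only by
independent sampling (no batch effects), mirroring input data that is
already cross-cohort normalized. Default dimensions follow the study
scale (13 cohorts × 453 samples, 9461 genes, 658 informative).

One consequence of the planted model deserves note: informative genes
all shift by the *same* amount in Cluster B, so a signature composed
almost entirely of informative genes carries little within-signature
rank signal (the genes move together and their relative order barely
changes). The rank classifier therefore shows its strength when the
signature mixes strongly and weakly informative genes — as a large
real signature does — and the end-to-end tests construct it that way.

What the generator does **not** emulate: gene-gene correlation,
cohort-specific batch or platform effects, non-proportional hazards,
informative censoring, and cluster structure beyond a single mean-shift
axis. Passing recovery tests therefore demonstrate correctness of the
machinery under the assumed model, not performance on real cohorts.

## Scaled study conditions used in tests

The planted-recovery studies run at a reduced scale chosen once:
200 genes with 20 informative at effect size 1.5; 8 cohorts × 100
samples — 6 training cohorts (400 fit / 200 validation for the
accuracy-driven split) and 2 test cohorts (100/100 validation/test
halves for the survival-driven flow); elimination thresholds 100/10 as
above; 5 seeds with medians reported. At this scale a full pipeline run
takes about a second, and recovery of the planted genes (precision and
recall) is the measurable analogue of the full-scale signature quality.

## Numerical and degenerate-input choices

* Rank direction in the decile transform is ascending; only the
  consistency of the convention matters for the classifier.
* Exact WRS enumeration compares deviations with a 1e-9 slack so
  floating-point mid-rank sums do not drop tied extreme tables.
* All-identical pooled samples give WRS p = 1; identical survival
  distributions give log-rank statistic 0, p = 1; an all-censored group
  yields a flat KM curve with undefined Q3.
* Hypergeometric and binomial tails are computed via scipy's
  log-accurate routines or explicit log-gamma sums; no naive factorial
  products anywhere.
* Seeds propagate from a single configuration seed; stability runs use
  seed + split-index offsets.

## Known limitations

* The one-vs-rest scheme is one reading of a "three-way" lasso logistic
  loss; a multinomial-softmax variant could select slightly different
  genes. The λ ↔ C translation follows the plain liblinear convention.
* The plug-in FDR assumes π₀ = 1 and a fixed threshold; it is an
  estimate attached to the screen, not an FDR-controlling procedure.
* The stability bound's independence assumption across runs sharing
  training data is optimistic in principle; it is used as an upper-tail
  yardstick, not an exact p-value.
* Log-rank-driven selection optimizes a noisy objective; selected set
  sizes vary visibly across splits (the stability subcommand measures
  exactly this).
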