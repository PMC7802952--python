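# immunosig

Survival-driven selection of efficient immune-related prognostic gene
signatures in breast cancer, with a normalization-free rank-decile
classifier.

## What it does

Breast cancer tumors fall into three immune-infiltration clusters —
A (low), B (intermediate), C (high) — and the intermediate cluster B
carries the worst overall-survival prognosis. Given a genome-wide
expression matrix with cluster labels and survival data, `immunosig`
derives a compact gene signature for the B-vs-rest partition in three
stages:

1. **Rank-sum pre-filter** — drop every gene whose two-sided Wilcoxon
   rank-sum p-value for Cluster B vs the rest exceeds α (default 0.1),
   and report the plug-in false-discovery rate α·m/k of the screen.
2. **Iterative lasso backward elimination** — refit an L1-penalized
   one-vs-rest logistic model (λ = 1) over the three clusters; while
   more than 900 coefficients are nonzero drop the 10% least-important
   genes per iteration (importance = largest |coefficient| across
   classes), then one gene per iteration down to a floor of 50.
3. **Model selection** — score every iteration on held-out data and
   keep the best set: by Cluster-B-vs-rest validation accuracy
   ("Point A"), or by the log-rank p-value between predicted B and
   not-B survival on a validation half of the test cohorts ("Point B").

The Point-B signature Γ (N genes) then powers a classifier that needs
no cohort normalization: within each sample the signature genes are
ranked (R = 1 for the lowest) and mapped to relative deciles

    Q(g, d) = ⌈10 · R(g, d) / N⌉,

and a Laplace-smoothed categorical Naive Bayes model over Q calls each
sample GPx (good prognosis) or BPx (bad prognosis). Because Q depends
only on within-sample order, the call is invariant to any strictly
increasing per-sample transform of the raw data — a single new sample
can be classified as-is.

The package also ships the surrounding statistics (Kaplan-Meier with
exponential-Greenwood envelope and Q3 marker, two-group log-rank,
hypergeometric enrichment/depletion, Benjamini-Hochberg, χ²
independence, Kruskal-Wallis, and a binomial tail bound for the
significance of gene-set intersections across repeated splits) and a
seeded synthetic-cohort generator with planted ground truth for
validating the whole pipeline.

## Worked example

Run the survival-driven flow on a planted synthetic study (200 genes of
which 20 are informative at effect size 1.5; 8 cohorts × 100 samples,
two held out as test cohorts):

```python
from immunosig import PipelineConfig, run_pipeline
from immunosig.datagen import SyntheticConfig

config = PipelineConfig(
    synthetic=SyntheticConfig(
        n_cohorts=8, samples_per_cohort=100,
        n_genes=200, n_informative=20, effect_size=1.5, seed=2,
    ),
    test_cohorts=["cohort_07", "cohort_08"],
    validation_fraction=1 / 3,
    phase1_threshold=100, phase2_floor=10,   # thresholds scaled to 200 genes
    seed=2,
)
result = run_pipeline(config, "pointB")
print(f"filtered genes : {result.filter_result.k_passing} of "
      f"{result.filter_result.m_total} (plug-in FDR {result.filter_result.fdr:.2f})")
print(f"signature size : {len(result.gene_set)}")
print(f"held-out log-rank p = {result.report['logrank_p']:.2e}")
print(f"group sizes    : {result.report['n_per_group']}")
```

prints

```
filtered genes : 34 of 200 (plug-in FDR 0.59)
signature size : 12
held-out log-rank p = 2.68e-04
group sizes    : {'B': 38, 'not_B': 62}
```

The filter keeps 34 genes (the 20 planted ones plus rank-sum survivors
of the 180 noise genes — hence the high plug-in FDR at this small
scale); elimination plus log-rank-driven selection compresses them to a
12-gene signature whose predicted B / not-B split separates survival on
the untouched test half at p ≈ 3 × 10⁻⁴.

The same pipeline is available from the shell:

```sh
immunosig simulate --seed 2 --outdir sim/
immunosig select --config config.yaml --flow pointB --seed 2 --outdir run/
immunosig stability --config config.yaml --n-splits 10 --outdir stab/
```

`select` writes the signature (`signature.txt`), the per-iteration
trace (`trace.jsonl`), a KM plot with its underlying step tables, a
JSON report and a reproducibility manifest; `stability` re-runs
selection under shifted seeds and bounds the significance of the
gene-set intersection.

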