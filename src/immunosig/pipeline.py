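"""End-to-end flows: accuracy-driven (Point A), log-rank-driven (Point B),
and the rank-decile prognostic classifier.

All three flows share the same front end — rank-sum filtering on the
training cohorts followed by iterative lasso backward elimination — and
differ in what drives model selection and what is reported:

* ``pointA``: each elimination iteration is scored by Cluster-B-vs-rest
  accuracy on a held-out fraction of the training samples; the selected
  signature is evaluated on the test cohorts with a Kaplan-Meier /
  log-rank report.
* ``pointB``: iterations are scored by the log-rank p-value of predicted
  B vs not-B survival on one half of the test cohorts; the selected
  signature is evaluated on the untouched other half.
* ``rankclf``: the Point-B signature is re-expressed as within-sample
  rank deciles on the raw-scale matrix, a categorical Naive Bayes model
  is trained for GPx/BPx, and held-out samples are scored the same way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import filtering, rankclf, selection
from .datagen import generate_dataset
from .io import PipelineConfig, read_clinical, read_expression
from .survival import SurvivalCurve, km_curve, logrank

__all__ = ["PipelineResult", "load_inputs", "stratified_split", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    flow: str
    gene_set: list[str]
    trace: selection.SelectionTrace | None
    filter_result: filtering.FilterResult | None
    report: dict = field(default_factory=dict)
    curves: dict[str, SurvivalCurve] = field(default_factory=dict)
    calls: pd.DataFrame | None = None
    model: rankclf.RankNBModel | None = None


def load_inputs(config: PipelineConfig):
    """Materialize (normalized, raw, clinical) from files or the generator."""
    if config.synthetic is not None:
        ds = generate_dataset(config.synthetic)
        return ds.normalized_expr, ds.raw_expr, ds.clinical
    if config.expression_path is None or config.clinical_path is None:
        raise ValueError("config needs either a synthetic block or input paths")
    normalized = read_expression(config.expression_path)
    raw = (
        read_expression(config.raw_expression_path)
        if config.raw_expression_path
        else None
    )
    clinical = read_clinical(config.clinical_path)
    if set(normalized.columns) != set(clinical.index):
        raise ValueError("sample IDs differ between expression and clinical inputs")
    return normalized, raw, clinical.loc[normalized.columns]


def stratified_split(
    clinical: pd.DataFrame, fraction: float, seed: int, strata_cols=("cohort", "cluster")
) -> tuple[list[str], list[str]]:
    """Split sample IDs into (kept, held_out) with held_out ~= fraction.

    The split is stratified by the given clinical columns (those present)
    and fully determined by the seed.
    """
    cols = [c for c in strata_cols if c in clinical.columns]
    rng = np.random.default_rng(seed)
    kept, held = [], []
    groups = clinical.groupby(cols, sort=True).groups if cols else {"all": clinical.index}
    for _, idx in sorted(groups.items(), key=lambda kv: str(kv[0])):
        ids = list(idx)
        perm = rng.permutation(len(ids))
        n_held = int(round(fraction * len(ids)))
        held.extend(ids[i] for i in perm[:n_held])
        kept.extend(ids[i] for i in perm[n_held:])
    return sorted(kept), sorted(held)


def _default_test_cohorts(clinical: pd.DataFrame, config: PipelineConfig) -> list[str]:
    if config.test_cohorts:
        return list(config.test_cohorts)
    cohorts = sorted(clinical["cohort"].unique())
    n_test = max(1, round(len(cohorts) * 0.25))  # ~3 of 13 by default
    chosen = cohorts[-n_test:]
    logger.info("no test cohorts named; holding out %s", chosen)
    return chosen


def _km_report(clinical: pd.DataFrame, group_b: np.ndarray, label_b="B", label_not="not_B"):
    """Two-group log-rank + KM curves keyed by group label."""
    t, e = clinical["time"].to_numpy(), clinical["event"].to_numpy()
    if group_b.all() or (~group_b).all():
        logger.info("degenerate final predictor: every sample in one group; p=1")
        only = label_b if group_b.all() else label_not
        return (
            {
                "logrank_p": 1.0,
                "logrank_statistic": 0.0,
                "n_per_group": {label_b: int(group_b.sum()), label_not: int((~group_b).sum())},
                "events_per_group": {label_b: int(e[group_b].sum()), label_not: int(e[~group_b].sum())},
                "q3_time": {only: km_curve(t, e).q3_time},
            },
            {only: km_curve(t, e)},
        )
    res = logrank(t[group_b], e[group_b], t[~group_b], e[~group_b])
    curves = {
        label_b: km_curve(t[group_b], e[group_b]),
        label_not: km_curve(t[~group_b], e[~group_b]),
    }
    report = {
        "logrank_p": res.p_value,
        "logrank_statistic": res.statistic,
        "n_per_group": {label_b: int(group_b.sum()), label_not: int((~group_b).sum())},
        "events_per_group": dict(zip([label_b, label_not], res.events_per_group)),
        "q3_time": {k: c.q3_time for k, c in curves.items()},
    }
    return report, curves


def run_pipeline(config: PipelineConfig, flow: str) -> PipelineResult:
    """Execute one of the three flows end to end; fully seeded."""
    if flow not in ("pointA", "pointB", "rankclf"):
        raise ValueError(f"unknown flow {flow!r}")
    normalized, raw, clinical = load_inputs(config)
    test_cohorts = _default_test_cohorts(clinical, config)
    is_test = clinical["cohort"].isin(test_cohorts)
    train_ids = list(clinical.index[~is_test])
    test_ids = list(clinical.index[is_test])
    if not train_ids or not test_ids:
        raise ValueError("both training and test cohorts must be non-empty")

    if flow == "pointA":
        fit_ids, val_ids = stratified_split(
            clinical.loc[train_ids], config.validation_fraction, config.seed
        )
        filt = filtering.filter_genes(
            normalized.loc[:, fit_ids], clinical.loc[fit_ids, "cluster"], config.wrs_alpha
        )
        expr_val = normalized.loc[filt.passing_genes, val_ids]
        labels_val = clinical.loc[val_ids, "cluster"].to_numpy()

        def metric(w):
            return selection.evaluate_accuracy(w, expr_val.loc[w.genes], labels_val)

        trace = selection.backward_eliminate(
            normalized.loc[filt.passing_genes, fit_ids],
            clinical.loc[fit_ids, "cluster"].to_numpy(),
            config.regression,
            metric,
            phase1_threshold=config.phase1_threshold,
            phase2_floor=config.phase2_floor,
            removal_rate=config.removal_rate,
        )
        gamma = selection.select_point(trace, "accuracy")
        trace.point_A = gamma
        final = selection.fit_l1_multinomial(
            normalized.loc[gamma, fit_ids],
            clinical.loc[fit_ids, "cluster"].to_numpy(),
            config.regression,
        )
        pred_b = selection.predict_clusters(final, normalized.loc[:, test_ids]) == "B"
        report, curves = _km_report(clinical.loc[test_ids], pred_b)
        report["test_accuracy"] = selection.evaluate_accuracy(
            final, normalized.loc[:, test_ids], clinical.loc[test_ids, "cluster"].to_numpy()
        )
        report["n_genes"] = len(gamma)
        return PipelineResult("pointA", gamma, trace, filt, report, curves)

    # pointB front end, shared by rankclf
    val_half, test_half = stratified_split(
        clinical.loc[test_ids],
        1.0 - config.test_cohort_validation_fraction,
        config.seed,
        strata_cols=("cohort",),
    )
    # stratified_split holds out `fraction`; here the held-out part is the
    # final test half, the kept part the selection-time validation half
    filt = filtering.filter_genes(
        normalized.loc[:, train_ids], clinical.loc[train_ids, "cluster"], config.wrs_alpha
    )
    expr_val = normalized.loc[filt.passing_genes, val_half]
    clin_val = clinical.loc[val_half]

    def metric(w):
        return selection.evaluate_logrank(w, expr_val.loc[w.genes], clin_val)

    trace = selection.backward_eliminate(
        normalized.loc[filt.passing_genes, train_ids],
        clinical.loc[train_ids, "cluster"].to_numpy(),
        config.regression,
        metric,
        phase1_threshold=config.phase1_threshold,
        phase2_floor=config.phase2_floor,
        removal_rate=config.removal_rate,
    )
    gamma_b = selection.select_point(trace, "logrank")
    trace.point_B = gamma_b
    final = selection.fit_l1_multinomial(
        normalized.loc[gamma_b, train_ids],
        clinical.loc[train_ids, "cluster"].to_numpy(),
        config.regression,
    )

    if flow == "pointB":
        pred_b = selection.predict_clusters(final, normalized.loc[:, test_half]) == "B"
        report, curves = _km_report(clinical.loc[test_half], pred_b)
        report["n_genes"] = len(gamma_b)
        return PipelineResult("pointB", gamma_b, trace, filt, report, curves)

    # rankclf: normalization-free classifier on the raw scale
    if raw is None:
        raise ValueError("the rankclf flow needs a raw-scale expression matrix")
    q_train = np.vstack(
        [
            rankclf.decile_transform(raw.loc[gamma_b, s].to_numpy(), config.n_deciles)
            for s in train_ids
        ]
    )
    nb_labels = np.where(clinical.loc[train_ids, "cluster"] == "B", "BPx", "GPx")
    model = rankclf.fit_rank_nb(
        q_train, nb_labels, config.smoothing_alpha, config.n_deciles, genes=gamma_b
    )
    calls = rankclf.predict_samples(model, raw.loc[gamma_b, test_half])
    is_bpx = (calls["call"] == "BPx").to_numpy()
    report, curves = _km_report(clinical.loc[test_half], is_bpx, "BPx", "GPx")
    report["n_genes"] = len(gamma_b)
    return PipelineResult("rankclf", gamma_b, trace, filt, report, curves, calls, model)
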