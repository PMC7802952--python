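"""Backward elimination: fits, importance, schedule, metrics, selection."""

import numpy as np
import pandas as pd
import pytest

from immunosig.selection import (
    RegressionConfig,
    SelectionTrace,
    TraceIteration,
    WeightMatrix,
    backward_eliminate,
    evaluate_accuracy,
    evaluate_logrank,
    fit_l1_multinomial,
    gene_importance,
    predict_clusters,
    removal_count,
    select_point,
)


def make_expr(X, genes=None):
    genes = genes or [f"g{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X.T, index=genes, columns=[f"s{i}" for i in range(X.shape[0])])


def proximal_l1_logistic(X, y, C, n_iter=500_000, intercept_scaling=1.0):
    """Independent proximal-gradient solver for the liblinear objective
    ||w||_1 + |b|/scaling + C * sum log(1 + exp(-y (x.w + b))).

    liblinear appends the bias as a scaled penalized column; the
    per-coordinate threshold reproduces that without its conditioning.
    """
    Xa = np.hstack([X, np.ones((X.shape[0], 1))])
    penalty = np.ones(Xa.shape[1])
    penalty[-1] = 1.0 / intercept_scaling
    ys = 2 * y - 1
    lr = 1.0 / (C * 0.25 * np.linalg.norm(Xa, 2) ** 2)
    u = np.zeros(Xa.shape[1])
    for _ in range(n_iter):
        m = ys * (Xa @ u)
        grad = C * (Xa.T @ (-ys / (1 + np.exp(m))))
        u_new = u - lr * grad
        u_new = np.sign(u_new) * np.maximum(np.abs(u_new) - lr * penalty, 0.0)
        if np.max(np.abs(u_new - u)) < 1e-14:
            return u_new
        u = u_new
    return u


class TestFitL1:
    @pytest.mark.parametrize("seed", range(3))
    def test_matches_proximal_gradient_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((6, 3))
        labels = np.array(["A", "B", "C", "A", "B", "C"])
        cfg = RegressionConfig(lam=1.0, tol=1e-10, max_iterations=100_000)
        w = fit_l1_multinomial(make_expr(X), labels, cfg)
        for ci, cls in enumerate(w.classes):
            u = proximal_l1_logistic(X, (labels == cls).astype(float), C=1.0)
            np.testing.assert_allclose(w.weights[:, ci], u[:-1], atol=1e-4)
            np.testing.assert_allclose(w.intercepts[ci], u[-1], atol=1e-4)

    def test_separating_gene_dominates(self, rng):
        n = 60
        labels = np.array(["B"] * 20 + ["A"] * 20 + ["C"] * 20)
        X = rng.standard_normal((n, 10))
        X[:, 0] = np.where(labels == "B", 3.0, -3.0) + 0.1 * rng.standard_normal(n)
        w = fit_l1_multinomial(make_expr(X), labels)
        assert int(np.argmax(gene_importance(w))) == 0

    def test_constant_gene_zeroed(self, rng):
        # a zero-variance gene is 0 after standardization (the pipeline's
        # input convention) and carries no signal for the lasso to keep
        X = rng.standard_normal((40, 4))
        X[:, 2] = 0.0
        labels = np.where(rng.uniform(size=40) < 0.5, "B", "A")
        w = fit_l1_multinomial(make_expr(X), labels)
        assert np.all(w.weights[2] == 0.0)

    def test_single_class_raises(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError):
            fit_l1_multinomial(make_expr(X), np.array(["B"] * 10))

    def test_nnz_excludes_intercepts(self):
        w = WeightMatrix(
            genes=["a", "b"],
            classes=["A", "B"],
            weights=np.array([[0.0, 0.0], [1.0, 0.0]]),
            intercepts=np.array([5.0, -2.0]),
        )
        assert w.nnz == 1


class TestGeneImportance:
    def test_max_over_classes(self):
        w = WeightMatrix(
            genes=["a", "b", "c"],
            classes=["A", "B"],
            weights=np.array([[0.1, -0.5], [0.0, 0.0], [0.3, 0.2]]),
            intercepts=np.zeros(2),
        )
        np.testing.assert_allclose(gene_importance(w), [0.5, 0.0, 0.3])

    def test_argsort_matches_pairwise_comparison(self, rng):
        weights = rng.standard_normal((8, 3))
        w = WeightMatrix(
            genes=[f"g{i}" for i in range(8)], classes=list("ABC"),
            weights=weights, intercepts=np.zeros(3),
        )
        scores = gene_importance(w)
        order = np.argsort(scores, kind="stable")
        for i, j in zip(order, order[1:]):
            assert scores[i] <= scores[j]


class TestSchedule:
    @pytest.mark.parametrize(
        "n_active,nnz,expected", [(6557, 6557, 655), (901, 901, 90), (900, 900, 1), (60, 60, 1)]
    )
    def test_removal_counts(self, n_active, nnz, expected):
        assert removal_count(n_active, nnz, 900, 0.1) == expected

    def test_start_at_floor_single_iteration(self, rng):
        X = rng.standard_normal((60, 12))
        labels = np.array(["A", "B", "C"] * 20)
        expr = make_expr(X)
        trace = backward_eliminate(
            expr, labels, RegressionConfig(), lambda w: 0.0, phase2_floor=12
        )
        assert len(trace.iterations) == 1
        assert trace.iterations[0].active_genes == list(expr.index)

    def test_nested_sets_and_schedule_conformance(self, rng):
        """Sizes shrink per the loop-guard arithmetic and sets are nested."""
        X = rng.standard_normal((80, 40))
        labels = np.array(["A", "B", "C", "A"] * 20)
        trace = backward_eliminate(
            make_expr(X), labels, RegressionConfig(), lambda w: 0.0,
            phase1_threshold=20, phase2_floor=5,
        )
        for prev, cur in zip(trace.iterations, trace.iterations[1:]):
            assert set(cur.active_genes) < set(prev.active_genes)
            expected = removal_count(
                len(prev.active_genes), prev.weights.nnz, 20, 0.1
            )
            assert len(prev.active_genes) - len(cur.active_genes) == expected
        assert trace.iterations[-1].weights.nnz <= 5

    def test_deterministic_trace(self, rng):
        X = rng.standard_normal((60, 25))
        labels = np.array(["A", "B", "C", "B", "A"] * 12)
        kw = dict(phase1_threshold=15, phase2_floor=5)
        t1 = backward_eliminate(make_expr(X), labels, RegressionConfig(seed=3),
                                lambda w: 0.0, **kw)
        t2 = backward_eliminate(make_expr(X), labels, RegressionConfig(seed=3),
                                lambda w: 0.0, **kw)
        assert [it.active_genes for it in t1.iterations] == [
            it.active_genes for it in t2.iterations
        ]


class TestMetrics:
    def _constant_not_b(self, genes):
        # intercepts force class A regardless of input
        return WeightMatrix(
            genes=genes, classes=["A", "B", "C"],
            weights=np.zeros((len(genes), 3)), intercepts=np.array([10.0, 0.0, 0.0]),
        )

    def test_constant_predictor_accuracy_is_not_b_share(self, rng):
        genes = ["g0", "g1"]
        expr = make_expr(rng.standard_normal((10, 2)), genes)
        labels = np.array(["B"] * 3 + ["A"] * 7)
        acc = evaluate_accuracy(self._constant_not_b(genes), expr, labels)
        assert acc == pytest.approx(0.7)

    def test_perfect_predictor_accuracy(self, rng):
        labels = np.array(["B"] * 10 + ["A"] * 10)
        X = np.where(labels == "B", 5.0, -5.0)[:, None] * np.ones((1, 2))
        w = WeightMatrix(
            genes=["g0", "g1"], classes=["A", "B"],
            weights=np.array([[-1.0, 1.0], [0.0, 0.0]]), intercepts=np.zeros(2),
        )
        assert evaluate_accuracy(w, make_expr(X), labels) == 1.0

    def test_empty_validation_raises(self, rng):
        w = self._constant_not_b(["g0"])
        with pytest.raises(ValueError):
            evaluate_accuracy(w, make_expr(np.empty((0, 1))), np.array([]))

    def test_degenerate_predictor_logrank_sentinel(self, rng):
        genes = ["g0", "g1"]
        expr = make_expr(rng.standard_normal((12, 2)), genes)
        clin = pd.DataFrame(
            {"time": rng.exponential(5, 12), "event": np.ones(12, dtype=int)},
            index=expr.columns,
        )
        assert evaluate_logrank(self._constant_not_b(genes), expr, clin) == 1.0

    def test_informative_predictor_logrank_significant(self, rng):
        n = 200
        labels = np.array(["B"] * 100 + ["A"] * 100)
        X = np.where(labels == "B", 4.0, -4.0)[:, None] + 0.1 * rng.standard_normal((n, 1))
        w = WeightMatrix(
            genes=["g0"], classes=["A", "B"],
            weights=np.array([[-1.0, 1.0]]), intercepts=np.zeros(2),
        )
        hazard = np.where(labels == "B", 0.3, 0.1)
        clin = pd.DataFrame(
            {"time": rng.exponential(1 / hazard), "event": np.ones(n, dtype=int)},
            index=[f"s{i}" for i in range(n)],
        )
        expr = make_expr(X)
        assert evaluate_logrank(w, expr, clin) < 0.01


class TestSelectPoint:
    def _trace(self, sizes, metrics):
        iters = [
            TraceIteration(
                [f"g{i}" for i in range(s)],
                WeightMatrix([], [], np.empty((0, 0)), np.empty(0)),
                m,
            )
            for s, m in zip(sizes, metrics)
        ]
        return SelectionTrace(iterations=iters)

    def test_monotone_accuracy_picks_final_set(self):
        trace = self._trace([100, 80, 60], [0.7, 0.8, 0.9])
        assert len(select_point(trace, "accuracy")) == 60

    def test_tie_prefers_smaller_set(self):
        trace = self._trace([100, 80], [0.9, 0.9])
        assert len(select_point(trace, "accuracy")) == 80

    def test_logrank_picks_minimum(self):
        trace = self._trace([100, 80, 60], [0.5, 0.001, 0.2])
        assert len(select_point(trace, "logrank")) == 80

    def test_empty_trace_raises(self):
        with pytest.raises(ValueError):
            select_point(SelectionTrace(), "accuracy")


def test_recovery_of_planted_genes(rng):
    """Best-accuracy iteration keeps most planted genes on one seed."""
    from immunosig.datagen import SyntheticConfig, generate_dataset
    from immunosig.filtering import filter_genes

    ds = generate_dataset(
        SyntheticConfig(
            n_cohorts=2, samples_per_cohort=150, n_genes=100, n_informative=10,
            effect_size=1.5, seed=21,
        )
    )
    train = list(ds.clinical.index[:200])
    val = list(ds.clinical.index[200:])
    filt = filter_genes(ds.normalized_expr[train], ds.clinical.loc[train, "cluster"], 0.1)
    expr_train = ds.normalized_expr.loc[filt.passing_genes, train]
    labels_train = ds.clinical.loc[train, "cluster"].to_numpy()
    labels_val = ds.clinical.loc[val, "cluster"].to_numpy()

    def metric(w):
        return evaluate_accuracy(w, ds.normalized_expr.loc[w.genes, val], labels_val)

    trace = backward_eliminate(
        expr_train, labels_train, RegressionConfig(), metric,
        phase1_threshold=50, phase2_floor=5,
    )
    best = set(select_point(trace, "accuracy"))
    assert best <= set(filt.passing_genes)
    recall = len(best & ds.truth_informative) / len(ds.truth_informative)
    assert recall >= 0.8
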