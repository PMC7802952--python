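"""Normalization-free prognostic classification from within-sample ranks.

A fitted signature of N genes is turned into a classifier that needs no
cohort-level normalization: within each sample, the raw expression values
of the signature genes are ranked (1 = lowest) and each gene is mapped to
its relative decile,

    Q(g, d) = ceil(n_deciles * R(g, d) / N),

where R(g, d) is the rank of gene g in sample d.  Because Q depends only
on the within-sample ordering, any strictly increasing per-sample
transform of the raw data — scanner gain, log scale, library size —
leaves the features, and hence the classification, unchanged.

A categorical Naive Bayes model over the decile features separates two
prognostic classes: GPx (good prognosis, called not-Cluster-B) and BPx
(bad prognosis, called Cluster-B).  Conditional decile frequencies are
Laplace-smoothed; posteriors are computed in log space.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RankNBModel",
    "PrognosticCall",
    "decile_transform",
    "fit_rank_nb",
    "predict_rank_nb",
    "predict_samples",
]

CLASSES = ("GPx", "BPx")


def decile_transform(raw_values, n_deciles: int = 10) -> np.ndarray:
    """Map one sample's signature-gene values to relative deciles.

    ``raw_values`` holds one expression value per signature gene, in
    signature order.  Ranks are ascending (rank 1 = lowest value); ties
    are broken stably by signature position, so ranks are always a full
    permutation of 1..N and the ceiling map covers every decile when
    N >= n_deciles.
    """
    values = np.asarray(raw_values, dtype=float)
    if values.ndim != 1:
        raise ValueError("decile_transform expects a single sample (1-D)")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite expression value in sample")
    if n_deciles < 2:
        raise ValueError("n_deciles must be >= 2")
    n = values.size
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    return np.ceil(n_deciles * ranks / n).astype(int)


@dataclass
class RankNBModel:
    """Categorical Naive Bayes over rank-decile features.

    ``cond_freqs[g, c, q-1]`` is the smoothed probability that signature
    gene ``g`` falls in decile ``q`` for class ``c`` (class order GPx,
    BPx).  Each per-gene per-class row sums to 1.
    """

    signature_genes: list[str]
    n_deciles: int
    class_priors: np.ndarray  # (2,) in CLASSES order
    cond_freqs: np.ndarray  # (n_genes, 2, n_deciles)
    smoothing_alpha: float = 1.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "signature_genes": self.signature_genes,
                "n_deciles": self.n_deciles,
                "classes": list(CLASSES),
                "class_priors": self.class_priors.tolist(),
                "cond_freqs": self.cond_freqs.tolist(),
                "smoothing_alpha": self.smoothing_alpha,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RankNBModel":
        obj = json.loads(text)
        return cls(
            signature_genes=list(obj["signature_genes"]),
            n_deciles=int(obj["n_deciles"]),
            class_priors=np.asarray(obj["class_priors"], dtype=float),
            cond_freqs=np.asarray(obj["cond_freqs"], dtype=float),
            smoothing_alpha=float(obj["smoothing_alpha"]),
        )


@dataclass
class PrognosticCall:
    sample_id: str
    q_vector: np.ndarray
    call: str  # GPx | BPx
    posterior: float = field(default=0.0)  # P(BPx | sample)


def fit_rank_nb(
    q_matrix, labels, smoothing_alpha: float = 1.0, n_deciles: int = 10, genes=None
) -> RankNBModel:
    """Fit the categorical NB from per-sample decile vectors.

    Parameters
    ----------
    q_matrix
        samples x genes integer deciles in 1..n_deciles.
    labels
        Per-sample "GPx"/"BPx" class labels.
    smoothing_alpha
        Laplace pseudo-count added to every decile cell:
        cond_freq = (count + alpha) / (n_class + alpha * n_deciles).
    """
    q = np.asarray(q_matrix, dtype=int)
    labels = np.asarray(labels)
    if q.ndim != 2 or q.shape[0] != labels.size:
        raise ValueError("q_matrix must be samples x genes, aligned with labels")
    if q.min() < 1 or q.max() > n_deciles:
        raise ValueError("decile values out of range")
    n_genes = q.shape[1]
    if genes is None:
        genes = [f"g{i}" for i in range(n_genes)]
    genes = list(genes)
    if len(genes) != n_genes:
        raise ValueError("gene list length mismatch with q_matrix")

    priors = np.empty(2)
    freqs = np.empty((n_genes, 2, n_deciles))
    for ci, cls_name in enumerate(CLASSES):
        mask = labels == cls_name
        n_c = int(mask.sum())
        if n_c == 0:
            raise ValueError(f"class {cls_name} absent from training labels")
        priors[ci] = n_c / labels.size
        sub = q[mask]
        for gi in range(n_genes):
            counts = np.bincount(sub[:, gi], minlength=n_deciles + 1)[1:]
            freqs[gi, ci] = (counts + smoothing_alpha) / (n_c + smoothing_alpha * n_deciles)
    return RankNBModel(
        signature_genes=genes,
        n_deciles=n_deciles,
        class_priors=priors,
        cond_freqs=freqs,
        smoothing_alpha=smoothing_alpha,
    )


def predict_rank_nb(model: RankNBModel, raw_values, sample_id: str = "") -> PrognosticCall:
    """Classify one new sample from its raw signature-gene expression.

    ``raw_values`` may be a mapping/Series keyed by gene or an array in
    signature order.  The sample is decile-transformed and scored with
    log prior + sum of log conditional frequencies; the posterior is
    normalized in log space.  An exact 0.5 posterior is called GPx (the
    conservative, good-prognosis default).
    """
    if isinstance(raw_values, (dict, pd.Series)):
        series = pd.Series(raw_values)
        missing = [g for g in model.signature_genes if g not in series.index]
        if missing:
            raise ValueError(f"missing signature gene(s): {', '.join(missing[:5])}")
        values = series.loc[model.signature_genes].to_numpy(dtype=float)
    else:
        values = np.asarray(raw_values, dtype=float)
        if values.size != len(model.signature_genes):
            raise ValueError("value vector length does not match the signature")

    q = decile_transform(values, model.n_deciles)
    gene_idx = np.arange(len(model.signature_genes))
    log_scores = np.log(model.class_priors) + np.array(
        [np.sum(np.log(model.cond_freqs[gene_idx, ci, q - 1])) for ci in range(2)]
    )
    # normalize in log space: P(BPx) = 1 / (1 + exp(score_GPx - score_BPx))
    post_bpx = 1.0 / (1.0 + math.exp(min(log_scores[0] - log_scores[1], 700.0)))
    call = "BPx" if post_bpx > 0.5 else "GPx"
    return PrognosticCall(sample_id=sample_id, q_vector=q, call=call, posterior=post_bpx)


def predict_samples(model: RankNBModel, raw_expr: pd.DataFrame) -> pd.DataFrame:
    """Classify every column (sample) of a raw genes x samples matrix.

    Returns a frame indexed by sample with columns ``call`` and
    ``posterior`` (probability of BPx).
    """
    calls, posts = [], []
    for sample in raw_expr.columns:
        res = predict_rank_nb(model, raw_expr[sample], sample_id=str(sample))
        calls.append(res.call)
        posts.append(res.posterior)
    return pd.DataFrame({"call": calls, "posterior": posts}, index=raw_expr.columns)
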