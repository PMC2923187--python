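"""Relief feature ranking and stepwise forward signature selection.

Relief scores each candidate gene by how well it separates the two prognosis
classes locally: for sampled patients, genes that differ towards the nearest
patients of the *other* class (misses) gain weight and genes that differ
towards the nearest patients of the *same* class (hits) lose weight.  The
default is the multi-neighbor ReliefF variant (k nearest hits/misses under
Manhattan distance on range-normalized values), which is the standard choice
for noisy continuous attributes; classic single-neighbor Relief (k=1) is the
same code path.

The ranked list then feeds a wrapper search: starting from the top-ranked
gene, genes are appended one at a time and kept only if the stratified
cross-validated accuracy of the Gaussian Naive Bayes classifier strictly
improves; the search stops at the first rejection.  Folds are drawn once
from the seed and reused at every step so accuracy differences reflect gene
sets rather than fold noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .core_data import DataError, ExpressionMatrix, PrognosisLabels
from .nb_risk import classify, score_samples, train_nb


@dataclass
class ReliefRanking:
    """Per-gene Relief weights and the induced ranking."""

    weights: pd.Series      # index = gene ids, Relief weight W(A)
    ranked_genes: list[str]  # descending weight, ties in input order
    k: int
    m: int                  # number of sampled instances actually used
    seed: int


def relief_rank(expr: ExpressionMatrix, labels: PrognosisLabels, k: int = 10,
                m: int | None = None, seed: int = 0) -> ReliefRanking:
    """Rank genes by ReliefF weight for separating the two classes.

    For each of ``m`` sampled patients (default: every patient, in order),
    the ``k`` nearest same-class and ``k`` nearest other-class patients are
    found under Manhattan distance on range-normalized expression;
    W(gene) accumulates +diff/(m*k) over misses and -diff/(m*k) over hits,
    with diff(gene, x, y) = |x - y| / range(gene).  A constant gene has
    diff 0 everywhere and therefore weight exactly 0.  Distance ties break
    by sample order; weights lie in [-1, 1].
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = labels.counts()
    if min(counts.values()) < 2:
        raise DataError("Relief needs >= 2 samples in each class")
    ids = labels.sample_ids
    x = expr.subset_samples(ids).data.to_numpy(dtype=float).T  # samples x genes
    y = labels.as_binary()
    n, g = x.shape

    rng_range = x.max(axis=0) - x.min(axis=0)
    nonconst = rng_range > 0
    xn = np.zeros_like(x)
    xn[:, nonconst] = x[:, nonconst] / rng_range[nonconst]  # diff = |xn_i - xn_j|

    if m is None or m >= n:
        sampled = np.arange(n)
    else:
        rng = np.random.Generator(np.random.PCG64(seed))
        sampled = rng.choice(n, size=m, replace=False)
    m_used = len(sampled)

    # full pairwise Manhattan distances on the normalized matrix
    from scipy.spatial.distance import cdist
    dist = cdist(xn, xn, metric="cityblock")

    weights = np.zeros(g)
    order = np.argsort(dist, axis=1, kind="stable")  # ties -> sample order
    for i in sampled:
        same = y == y[i]
        neigh = order[i][order[i] != i]
        hits = neigh[same[neigh]][:k]
        misses = neigh[~same[neigh]][:k]
        if len(hits):
            weights -= np.abs(xn[hits] - xn[i]).sum(axis=0) / (m_used * len(hits))
        if len(misses):
            weights += np.abs(xn[misses] - xn[i]).sum(axis=0) / (m_used * len(misses))

    w = pd.Series(weights, index=expr.probe_ids, name="relief_weight")
    ranked_idx = np.argsort(-w.to_numpy(), kind="stable")
    return ReliefRanking(weights=w,
                         ranked_genes=[expr.probe_ids[i] for i in ranked_idx],
                         k=k, m=m_used, seed=seed)


@dataclass
class SelectionTrace:
    """Accepted genes with the cross-validated accuracy after each addition."""

    steps: list[tuple[str, float]]
    selected: list[str]
    stop_reason: str  # "no_improvement" or "exhausted"
    cv_folds: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["gene", "cv_accuracy"])


def _cv_accuracy(expr: ExpressionMatrix, labels: PrognosisLabels,
                 genes: list[str], folds: list[tuple[np.ndarray, np.ndarray]]
                 ) -> float:
    ids = np.asarray(labels.sample_ids, dtype=object)
    y = labels.labels
    sub = expr.subset_probes(genes)
    correct = total = 0
    for train_idx, test_idx in folds:
        tr_labels = PrognosisLabels(labels=y.iloc[train_idx],
                                    horizon_months=labels.horizon_months)
        model = train_nb(sub.subset_samples(list(ids[train_idx])), tr_labels)
        scores = score_samples(model, sub.subset_samples(list(ids[test_idx])))
        pred = classify(scores)
        correct += int((pred.to_numpy() == y.iloc[test_idx].to_numpy()).sum())
        total += len(test_idx)
    return correct / total


def stepwise_select(expr: ExpressionMatrix, labels: PrognosisLabels,
                    ranking: ReliefRanking, cv_folds: int = 10,
                    seed: int = 0) -> SelectionTrace:
    """Forward selection along the Relief ranking with strict-improvement stop.

    The top-ranked gene is always taken; each further gene is kept iff the
    cross-validated Naive Bayes accuracy strictly increases, and the search
    stops at the first rejected gene.
    """
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    if not ranking.ranked_genes:
        raise ValueError("empty ranking")
    n = len(labels.sample_ids)
    if n < cv_folds:
        raise DataError(f"{n} samples cannot be split into {cv_folds} folds")
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(n), labels.as_binary()))

    selected: list[str] = []
    steps: list[tuple[str, float]] = []
    best = -np.inf
    stop_reason = "exhausted"
    for gene in ranking.ranked_genes:
        acc = _cv_accuracy(expr, labels, selected + [gene], folds)
        if acc > best:
            selected.append(gene)
            steps.append((gene, acc))
            best = acc
        else:
            stop_reason = "no_improvement"
            break
    return SelectionTrace(steps=steps, selected=selected,
                          stop_reason=stop_reason, cv_folds=cv_folds, seed=seed)
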