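"""Cell-line chemoresponse labeling, classification and permutation testing.

A drug's activity profile (log10 GI50 per cell line) is z-normalized over
the lines with data; lines at least +0.5 SD above the panel mean are
*resistant*, at least 0.5 SD below are *sensitive*, the rest *intermediate*.
A signature-restricted classifier (k-nearest-neighbor reference, k = 3,
Euclidean on per-gene z-scored profiles) separates resistant from sensitive
lines under leave-one-out cross-validation; significance is assessed by
comparing the observed overall accuracy with that of random same-size gene
signatures.

Reporting convention: "sensitivity" is the fraction of resistant lines
called correctly (detection of chemoresistance) and "specificity" the
fraction of sensitive lines called correctly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core_data import DataError, ExpressionMatrix
from .diffexp import DIFFERENT_VARIANCE, group_fold_change

RESISTANT = "resistant"
SENSITIVE = "sensitive"
INTERMEDIATE = "intermediate"

#: classifier signature: (train_X, train_y, test_X) -> predicted labels
ClassifierFn = Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]


@dataclass
class DrugResponseTable:
    """Per-line normalized drug activity and response trichotomy."""

    table: pd.DataFrame        # index = line ids; log10_gi50, z, label
    missing_ids: list[str]
    threshold_sd: float

    def ids_for(self, label: str) -> list[str]:
        return list(self.table.index[self.table["label"] == label])

    def counts(self) -> dict[str, int]:
        return {lbl: int((self.table["label"] == lbl).sum())
                for lbl in (RESISTANT, SENSITIVE, INTERMEDIATE)}


def label_response(gi50: pd.Series, threshold_sd: float = 0.5
                   ) -> DrugResponseTable:
    """Trichotomize a log10(GI50) profile at +/- threshold_sd panel SDs.

    The z-normalization uses only lines with data; missing lines are
    excluded (never imputed) and reported.  The boundary is inclusive:
    z exactly +0.5 is resistant ("at least 0.5 SDs above the mean").
    """
    missing = list(gi50.index[gi50.isna()])
    vals = gi50.dropna()
    if len(vals) < 3:
        raise DataError("need >= 3 lines with drug activity data")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise DataError("zero SD in drug activity; cannot normalize")
    z = (vals - vals.mean()) / sd
    label = pd.Series(
        np.select([z >= threshold_sd, z <= -threshold_sd],
                  [RESISTANT, SENSITIVE], default=INTERMEDIATE),
        index=vals.index, dtype=object)
    table = pd.DataFrame({"log10_gi50": vals, "z": z, "label": label})
    return DrugResponseTable(table=table, missing_ids=missing,
                             threshold_sd=threshold_sd)


@dataclass
class ChemoClassReport:
    """LOOCV confusion counts and derived metrics for one drug."""

    resistant_correct: int
    resistant_total: int
    sensitive_correct: int
    sensitive_total: int
    classifier: str = "knn"
    seed: int | None = None
    permutation_p: float | None = None

    @property
    def sensitivity(self) -> float:
        return self.resistant_correct / self.resistant_total

    @property
    def specificity(self) -> float:
        return self.sensitive_correct / self.sensitive_total

    @property
    def overall_accuracy(self) -> float:
        return ((self.resistant_correct + self.sensitive_correct)
                / (self.resistant_total + self.sensitive_total))


def metrics_from_counts(resistant_correct: int, resistant_total: int,
                        sensitive_correct: int, sensitive_total: int
                        ) -> ChemoClassReport:
    """Build a report directly from published-style per-class counts."""
    return ChemoClassReport(resistant_correct, resistant_total,
                            sensitive_correct, sensitive_total)


def _zscore_genes(x: np.ndarray) -> np.ndarray:
    """Row-wise (per-gene) z-score across lines; constant genes map to 0."""
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mu) / sd
    return np.where(np.isfinite(z), z, 0.0)


def _knn_loocv(x: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Vectorized leave-one-out k-NN (Euclidean); x is lines x genes.

    Distance ties break by line order; a tied class vote goes to the class
    of the single nearest neighbor.
    """
    d = cdist(x, x, metric="euclidean")
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    votes = y[order]
    pred = np.empty(x.shape[0], dtype=y.dtype)
    for i in range(x.shape[0]):
        vals, counts = np.unique(votes[i], return_counts=True)
        winners = vals[counts == counts.max()]
        pred[i] = votes[i][0] if len(winners) > 1 else winners[0]
    return pred


def _loocv(x: np.ndarray, y: np.ndarray, classifier: ClassifierFn
           ) -> np.ndarray:
    pred = np.empty(x.shape[0], dtype=y.dtype)
    for i in range(x.shape[0]):
        mask = np.ones(x.shape[0], dtype=bool)
        mask[i] = False
        pred[i] = classifier(x[mask], y[mask], x[i:i + 1])[0]
    return pred


def classify_chemo(expr: ExpressionMatrix, response: DrugResponseTable,
                   classifier: str | ClassifierFn = "knn", k: int = 3,
                   seed: int | None = None) -> ChemoClassReport:
    """Signature-restricted LOOCV chemoresponse classification.

    ``expr`` should already be restricted to the signature genes.
    Intermediate lines are excluded; gene profiles are z-scored across the
    retained lines.  ``classifier`` is the string ``"knn"`` (vectorized
    reference implementation) or any callable with the
    ``(train_X, train_y, test_X) -> labels`` signature.
    """
    res_ids = response.ids_for(RESISTANT)
    sen_ids = response.ids_for(SENSITIVE)
    if len(res_ids) < 2 or len(sen_ids) < 2:
        raise DataError("need >= 2 resistant and >= 2 sensitive lines")
    ids = [s for s in expr.sample_ids if s in set(res_ids) | set(sen_ids)]
    x = _zscore_genes(expr.subset_samples(ids).data.to_numpy(dtype=float)).T
    y = np.array([RESISTANT if s in set(res_ids) else SENSITIVE for s in ids])
    if classifier == "knn":
        pred = _knn_loocv(x, y, k)
        name = f"knn(k={k})"
    elif callable(classifier):
        pred = _loocv(x, y, classifier)
        name = getattr(classifier, "__name__", "custom")
    else:
        raise ValueError(f"unknown classifier {classifier!r}")
    res_mask = y == RESISTANT
    return ChemoClassReport(
        resistant_correct=int((pred[res_mask] == RESISTANT).sum()),
        resistant_total=int(res_mask.sum()),
        sensitive_correct=int((pred[~res_mask] == SENSITIVE).sum()),
        sensitive_total=int((~res_mask).sum()),
        classifier=name, seed=seed)


def permutation_significance(observed_accuracy: float, expr: ExpressionMatrix,
                             response: DrugResponseTable, signature_size: int,
                             n_random: int = 1000,
                             classifier: str | ClassifierFn = "knn",
                             k: int = 3, seed: int = 0,
                             exclude_genes=()) -> float:
    """Empirical p for the observed accuracy against random gene signatures.

    Draws ``n_random`` uniform gene sets of ``signature_size`` from the full
    profiled universe (minus ``exclude_genes``, typically the observed
    signature), reruns the identical LOOCV, and returns
    (1 + #{random >= observed}) / (n_random + 1) — never exactly 0.
    """
    if n_random < 100:
        raise ValueError("n_random < 100 gives an unstable null")
    universe = [g for g in expr.probe_ids if g not in set(exclude_genes)]
    if len(universe) < signature_size:
        raise DataError("gene universe smaller than the signature size")
    rng = np.random.Generator(np.random.PCG64(seed))
    universe = np.asarray(universe, dtype=object)
    n_hits = 0
    for _i in range(n_random):
        genes = rng.choice(universe, size=signature_size, replace=False)
        rep = classify_chemo(expr.subset_probes(list(genes)), response,
                             classifier=classifier, k=k)
        if rep.overall_accuracy >= observed_accuracy:
            n_hits += 1
    return (1 + n_hits) / (n_random + 1)


def resistant_vs_sensitive_de(expr: ExpressionMatrix,
                              response: DrugResponseTable) -> pd.DataFrame:
    """Per-gene fold change and Welch t between resistant and sensitive lines.

    Flags over-expression at FC >= 1.5 and under-expression at FC <= 1/1.5;
    statistical significance at two-sided Welch p <= 0.05.
    """
    from .diffexp import _ttest_arrays

    res_ids = response.ids_for(RESISTANT)
    sen_ids = response.ids_for(SENSITIVE)
    if not res_ids or not sen_ids:
        raise DataError("both resistant and sensitive lines are required")
    fc = group_fold_change(expr, res_ids, sen_ids)
    t, df, p, _zero = _ttest_arrays(expr.data[res_ids].to_numpy(dtype=float),
                                    expr.data[sen_ids].to_numpy(dtype=float),
                                    DIFFERENT_VARIANCE)
    fc["t"] = t
    fc["p"] = p
    fc["significant"] = fc["p"] <= 0.05
    return fc
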