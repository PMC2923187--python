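"""Gene-set enrichment against a two-class phenotype.

Genes are ranked by differential expression between the prognosis classes
(signal-to-noise by default, Welch t as an alternative); a weighted
Kolmogorov-Smirnov running sum yields the enrichment score (ES) per gene
set; phenotype-label permutations provide the normalized enrichment score
(NES = ES / mean same-sign permutation ES) and the standard pooled-NES FDR q.

With walk weight p = 0 the hit increments are uniform and the ES reduces to
the classic two-sample KS statistic between hit and miss rank distributions,
which makes tiny instances hand-checkable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import DataError, ExpressionMatrix, HIGH_RISK, LOW_RISK, PrognosisLabels

SIGNAL_TO_NOISE = "signal_to_noise"
T_STATISTIC = "t_statistic"


def _metric(x1: np.ndarray, x2: np.ndarray, metric: str) -> np.ndarray:
    """Per-gene two-class ranking metric, positive = up in class 1."""
    if metric == SIGNAL_TO_NOISE:
        m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
        s1 = x1.std(axis=1, ddof=1)
        s2 = x2.std(axis=1, ddof=1)
        # GSEA-style variance floor: sd at least 20% of |mean| and > 0
        s1 = np.maximum(s1, np.maximum(0.2 * np.abs(m1), 1e-8))
        s2 = np.maximum(s2, np.maximum(0.2 * np.abs(m2), 1e-8))
        return (m1 - m2) / (s1 + s2)
    if metric == T_STATISTIC:
        from .diffexp import DIFFERENT_VARIANCE, _ttest_arrays
        t, _, _, _ = _ttest_arrays(x1, x2, DIFFERENT_VARIANCE)
        return t
    raise ValueError(f"unknown ranking metric {metric!r}")


def rank_genes(expr: ExpressionMatrix, labels: PrognosisLabels,
               metric: str = SIGNAL_TO_NOISE) -> pd.Series:
    """Genes ordered by descending class-separation metric.

    Ties break deterministically by probe id.  Positive scores mean higher
    expression in the high-risk class.
    """
    g1 = labels.ids_for(HIGH_RISK)
    g2 = labels.ids_for(LOW_RISK)
    if len(g1) < 3 or len(g2) < 3:
        raise DataError("each class needs >= 3 samples for ranking")
    scores = _metric(expr.data[g1].to_numpy(dtype=float),
                     expr.data[g2].to_numpy(dtype=float), metric)
    s = pd.Series(scores, index=expr.probe_ids, name="score")
    order = np.lexsort((np.asarray(s.index), -s.to_numpy()))
    return s.iloc[order]


def enrichment_score(ranked: pd.Series, gene_set, weight_p: float = 1.0
                     ) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score of a gene set along a ranked list.

    Walking the ranking top-down, the running sum rises by |score|^p
    (normalized over in-set genes) at set members and falls by 1/(N - N_hit)
    elsewhere; the ES is the extremum (signed).  The sum telescopes to 0.
    """
    universe = list(ranked.index)
    in_set = np.isin(universe, list(gene_set))
    n = len(universe)
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise DataError("gene set does not intersect the ranked universe")
    if n_hit == n:
        raise DataError("gene set equals the ranked universe")
    w = np.abs(ranked.to_numpy()) ** weight_p
    hit_w = np.where(in_set, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all in-set scores exactly 0: fall back to uniform steps
        hit_w = in_set.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~in_set) / float(n - n_hit)
    running = np.cumsum(steps)
    es = running[np.argmax(np.abs(running))]
    return float(es), running


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from GMT (name, description, members...)."""
    sets = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


@dataclass
class EnrichmentResult:
    """Per-set ES/NES/FDR from a phenotype-permutation GSEA run."""

    table: pd.DataFrame  # index = set name; columns es, nes, fdr_q, size
    metric: str
    weight_p: float
    n_perm: int
    seed: int


def gsea(expr: ExpressionMatrix, labels: PrognosisLabels,
         gene_sets: dict[str, list[str]], n_perm: int = 1000,
         weight_p: float = 1.0, metric: str = SIGNAL_TO_NOISE,
         seed: int = 0) -> EnrichmentResult:
    """Phenotype-permutation GSEA over a collection of gene sets.

    The same permuted label assignments are reused for every set.  NES is the
    observed ES divided by the mean same-sign permutation ES of that set; the
    FDR q-value follows the standard pooled positive/negative NES procedure.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives an unstable permutation null")
    names = sorted(gene_sets)
    ranked = rank_genes(expr, labels, metric)
    es_obs = np.array([enrichment_score(ranked, gene_sets[nm], weight_p)[0]
                       for nm in names])

    ids = labels.sample_ids
    x = expr.subset_samples(ids).data.to_numpy(dtype=float)
    y = labels.as_binary().astype(bool)
    probe_ids = np.asarray(expr.probe_ids)
    rng = np.random.Generator(np.random.PCG64(seed))
    es_perm = np.empty((n_perm, len(names)))
    member_mask = {nm: pd.Index(probe_ids).isin(gene_sets[nm]) for nm in names}
    for b in range(n_perm):
        perm = rng.permutation(len(ids))
        yb = y[perm]
        scores = _metric(x[:, yb], x[:, ~yb], metric)
        order = np.lexsort((probe_ids, -scores))
        ranked_b = pd.Series(scores[order], index=probe_ids[order])
        for j, nm in enumerate(names):
            es_perm[b, j], _ = enrichment_score(ranked_b, gene_sets[nm], weight_p)

    nes_obs = np.empty(len(names))
    nes_perm = np.empty_like(es_perm)
    for j in range(len(names)):
        col = es_perm[:, j]
        pos_mean = col[col > 0].mean() if (col > 0).any() else np.nan
        neg_mean = -col[col < 0].mean() if (col < 0).any() else np.nan
        denom = pos_mean if es_obs[j] >= 0 else neg_mean
        nes_obs[j] = es_obs[j] / denom if np.isfinite(denom) else np.nan
        with np.errstate(invalid="ignore"):
            nes_perm[:, j] = np.where(col >= 0, col / pos_mean, col / neg_mean)

    pool = nes_perm[np.isfinite(nes_perm)]
    fdr = np.empty(len(names))
    for j, nes in enumerate(nes_obs):
        if not np.isfinite(nes):
            fdr[j] = 1.0
            continue
        if nes >= 0:
            num = (pool >= nes).mean() / max((pool >= 0).mean(), 1e-12)
            den = (nes_obs[np.isfinite(nes_obs)] >= nes).mean() / max(
                (nes_obs[np.isfinite(nes_obs)] >= 0).mean(), 1e-12)
        else:
            num = (pool <= nes).mean() / max((pool < 0).mean(), 1e-12)
            den = (nes_obs[np.isfinite(nes_obs)] <= nes).mean() / max(
                (nes_obs[np.isfinite(nes_obs)] < 0).mean(), 1e-12)
        fdr[j] = min(1.0, num / max(den, 1e-12))

    table = pd.DataFrame({
        "es": es_obs, "nes": nes_obs, "fdr_q": fdr,
        "size": [int(member_mask[nm].sum()) for nm in names],
    }, index=pd.Index(names, name="gene_set"))
    return EnrichmentResult(table=table, metric=metric, weight_p=weight_p,
                            n_perm=n_perm, seed=seed)
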