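"""Candidate-gene screening statistics.

Two two-sample t-test variants (Welch different-variance and pooled), the
SAM moderated relative-difference statistic with label-permutation FDR,
intersection filtering of the two screens, group fold change with
over/under-expression flags, and the 2^-ddCt RT-PCR fold-change utility.

Group orientation everywhere: group 1 = high-risk (or resistant), group 2 =
low-risk (or sensitive); positive statistics mean higher expression in the
first group.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import DataError, ExpressionMatrix, HIGH_RISK, LOW_RISK, PrognosisLabels

DIFFERENT_VARIANCE = "different_variance"
POOLED = "pooled"

OVER_FC = 1.5
UNDER_FC = 1.0 / OVER_FC  # 0.667, printed as 0.67


@dataclass
class TTestResult:
    """Per-gene two-sample t statistics."""

    table: pd.DataFrame  # index = probe ids; columns t, df, p, zero_spread
    variant: str

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def significant(self, p_threshold: float) -> list[str]:
        return list(self.table.index[self.table["p"] < p_threshold])


def _group_matrices(expr: ExpressionMatrix, labels: PrognosisLabels
                    ) -> tuple[np.ndarray, np.ndarray]:
    g1 = labels.ids_for(HIGH_RISK)
    g2 = labels.ids_for(LOW_RISK)
    return (expr.data[g1].to_numpy(dtype=float),
            expr.data[g2].to_numpy(dtype=float))


def _ttest_arrays(x1: np.ndarray, x2: np.ndarray, variant: str
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-sample t over rows. Returns (t, df, p, zero_spread)."""
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise DataError("each class needs >= 2 samples for a t-test")
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    zero_spread = (v1 == 0) & (v2 == 0)
    if variant == DIFFERENT_VARIANCE:
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
            t = (m1 - m2) / np.sqrt(se2)
    elif variant == POOLED:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        df = np.full(x1.shape[0], float(n1 + n2 - 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    t = np.where(zero_spread, 0.0, t)
    df = np.where(zero_spread, float(n1 + n2 - 2), df)
    p = np.where(zero_spread, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
    return t, df, p, zero_spread


def t_test(expr: ExpressionMatrix, labels: PrognosisLabels,
           variant: str = DIFFERENT_VARIANCE) -> TTestResult:
    """Per-gene two-sided two-sample t-test, high-risk minus low-risk.

    Welch statistic with Welch-Satterthwaite df (``different_variance``) or
    the pooled-variance statistic with n1+n2-2 df (``pooled``).  Genes with
    zero spread in both classes get t=0, p=1 and a ``zero_spread`` flag.
    """
    x1, x2 = _group_matrices(expr, labels)
    t, df, p, zero = _ttest_arrays(x1, x2, variant)
    table = pd.DataFrame({"t": t, "df": df, "p": p, "zero_spread": zero},
                         index=expr.probe_ids)
    return TTestResult(table=table, variant=variant)


# ---------------------------------------------------------------------------
# SAM


@dataclass
class SamResult:
    """SAM relative-difference statistics and the permutation null.

    ``d`` is the observed moderated statistic per gene; ``d_expected`` (in
    the ``order`` of ascending observed d) is the mean of permutation order
    statistics; ``perm_d`` holds the full permutation null for FDR counting.
    After thresholding (``at_delta`` / ``select_delta``), ``delta``,
    ``significant`` and ``fdr`` are populated.
    """

    d: pd.Series                 # index = probe ids, observed statistic
    d_expected: np.ndarray       # sorted expected order statistics
    order: np.ndarray            # argsort of observed d (ascending)
    perm_d: np.ndarray           # (n_perm, n_genes) permutation statistics
    s0: float
    n_perm: int
    pi0: float = 1.0
    delta: float | None = None
    significant: list[str] | None = None
    fdr: float | None = None

    def _cuts(self, delta: float) -> tuple[float, float]:
        """Asymmetric (cut_low, cut_up) thresholds for a given delta.

        Scanning outward from the origin of the expected-vs-observed plot,
        the first ordered gene whose observed d departs from its expected
        order statistic by >= delta fixes the cut; everything beyond it is
        called significant (monotone by construction).
        """
        d_sorted = self.d.to_numpy()[self.order]
        diff = d_sorted - self.d_expected
        origin = int(np.searchsorted(self.d_expected, 0.0))
        up = diff[origin:] >= delta
        cut_up = d_sorted[origin + int(np.argmax(up))] if up.any() else np.inf
        low = diff[:origin][::-1] <= -delta
        cut_low = d_sorted[origin - 1 - int(np.argmax(low))] if low.any() else -np.inf
        return cut_low, cut_up

    def _fdr_from_cuts(self, cut_low: float, cut_up: float, n_sig: int) -> float:
        false_calls = ((self.perm_d >= cut_up) | (self.perm_d <= cut_low)).sum(axis=1)
        return float(self.pi0 * np.median(false_calls) / n_sig)

    def n_significant(self, delta: float) -> int:
        cut_low, cut_up = self._cuts(delta)
        d = self.d.to_numpy()
        return int(((d >= cut_up) | (d <= cut_low)).sum())

    def estimate_fdr(self, delta: float) -> float:
        """Median false-call count over permutations / observed call count."""
        cut_low, cut_up = self._cuts(delta)
        d = self.d.to_numpy()
        n_sig = int(((d >= cut_up) | (d <= cut_low)).sum())
        if n_sig == 0:
            return 0.0
        return self._fdr_from_cuts(cut_low, cut_up, n_sig)

    def at_delta(self, delta: float) -> "SamResult":
        cut_low, cut_up = self._cuts(delta)
        mask = (self.d >= cut_up) | (self.d <= cut_low)
        return replace(self, delta=delta,
                       significant=list(self.d.index[mask]),
                       fdr=self.estimate_fdr(delta))

    def to_frame(self) -> pd.DataFrame:
        inv = np.empty_like(self.order)
        inv[self.order] = np.arange(len(self.order))
        out = pd.DataFrame({"d": self.d,
                            "d_expected": self.d_expected[inv]},
                           index=self.d.index)
        if self.significant is not None:
            out["significant"] = out.index.isin(self.significant)
        return out


def _relative_difference(x1: np.ndarray, x2: np.ndarray, s0: float
                         ) -> tuple[np.ndarray, np.ndarray]:
    """SAM d_i = (mean1 - mean2) / (s_i + s0); returns (d, s)."""
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss = x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (m1 - m2) / (s + s0)
    return np.where(np.isfinite(d), d, 0.0), s


def _tusher_s0(d_num: np.ndarray, s: np.ndarray) -> float:
    """Percentile search for the exchangeability constant s0.

    Among candidate s0 values at percentiles 0,5,...,100 of the gene-specific
    scatter s, pick the one minimizing the coefficient of variation of the
    median absolute deviation of d across windows of s — the standard SAM
    recipe for making the spread of d independent of s.
    """
    s_pct = np.percentile(s, np.arange(0, 101, 1))
    bins = np.clip(np.searchsorted(s_pct, s, side="right") - 1, 0, 99)
    candidates = np.percentile(s, np.arange(0, 101, 5))
    best_s0, best_cv = 0.0, np.inf
    for s0 in candidates:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(s + s0 > 0, d_num / (s + s0), 0.0)
        mads = []
        for b in range(100):
            db = d[bins == b]
            if db.size:
                mads.append(stats.median_abs_deviation(db, scale="normal"))
        mads = np.asarray(mads)
        if mads.size < 2 or mads.mean() == 0:
            continue
        cv = mads.std(ddof=1) / mads.mean()
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def sam(expr: ExpressionMatrix, labels: PrognosisLabels, n_perm: int = 300,
        s0_mode: str = "auto_percentile", s0_fixed: float = 0.0,
        seed: int = 0, pi0: float = 1.0) -> SamResult:
    """SAM moderated statistics with a label-permutation null.

    The null is built by randomly permuting class labels ``n_perm`` times
    (class sizes preserved); the expected relative difference is the mean of
    the permutation order statistics.  With ``s0_mode='fixed'`` and
    ``s0_fixed=0`` the statistic reduces exactly to the pooled t-test.
    """
    if n_perm < 25:
        raise ValueError("n_perm < 25 gives an unstable permutation null")
    g1 = labels.ids_for(HIGH_RISK)
    g2 = labels.ids_for(LOW_RISK)
    if len(g1) < 2 or len(g2) < 2:
        raise DataError("each class needs >= 2 samples for SAM")
    x = expr.data[g1 + g2].to_numpy(dtype=float)
    n1 = len(g1)

    d_num_obs = x[:, :n1].mean(axis=1) - x[:, n1:].mean(axis=1)
    _, s_obs = _relative_difference(x[:, :n1], x[:, n1:], 0.0)
    if s0_mode == "auto_percentile":
        s0 = _tusher_s0(d_num_obs, s_obs)
    elif s0_mode == "fixed":
        s0 = float(s0_fixed)
    else:
        raise ValueError(f"unknown s0_mode {s0_mode!r}")
    d_obs, _ = _relative_difference(x[:, :n1], x[:, n1:], s0)

    rng = np.random.Generator(np.random.PCG64(seed))
    n_total = x.shape[1]
    perm_d = np.empty((n_perm, x.shape[0]))
    for b in range(n_perm):
        idx = rng.permutation(n_total)
        perm_d[b], _ = _relative_difference(x[:, idx[:n1]], x[:, idx[n1:]], s0)

    d_expected = np.sort(perm_d, axis=1).mean(axis=0)
    order = np.argsort(d_obs, kind="stable")
    return SamResult(d=pd.Series(d_obs, index=expr.probe_ids),
                     d_expected=d_expected, order=order, perm_d=perm_d,
                     s0=s0, n_perm=n_perm, pi0=pi0)


class FdrUnreachableError(ValueError):
    """No delta on the grid achieves the requested FDR."""

    def __init__(self, target: float, minimum: float):
        self.target, self.minimum = target, minimum
        super().__init__(
            f"no delta achieves FDR <= {target}; minimum achievable FDR with "
            f"a non-empty gene set is {minimum:.4f}")


def select_delta(sam_result: SamResult, target_fdr: float) -> SamResult:
    """Smallest delta whose estimated FDR meets the target.

    The grid is the sorted set of observed |d - d_expected| deviations (plus
    0), so the search resolution adapts to the data.  Returns a copy of the
    result with delta, the significant set and the achieved FDR filled in.
    """
    if not 0 < target_fdr < 1:
        raise ValueError("target_fdr must be in (0, 1)")
    d_sorted = sam_result.d.to_numpy()[sam_result.order]
    grid = np.unique(np.concatenate(
        [[0.0], np.abs(d_sorted - sam_result.d_expected)]))
    d = sam_result.d.to_numpy()
    min_fdr = np.inf
    for delta in grid:
        cut_low, cut_up = sam_result._cuts(delta)
        n_sig = int(((d >= cut_up) | (d <= cut_low)).sum())
        if n_sig == 0:
            break
        fdr = sam_result._fdr_from_cuts(cut_low, cut_up, n_sig)
        min_fdr = min(min_fdr, fdr)
        if fdr <= target_fdr:
            return sam_result.at_delta(float(delta))
    raise FdrUnreachableError(target_fdr, min_fdr)


def intersect_candidates(ttest: TTestResult, p_threshold: float,
                         sam_result: SamResult) -> list[str]:
    """Genes passing both screens, in expression (t-test) order."""
    if list(ttest.table.index) != list(sam_result.d.index):
        raise DataError("t-test and SAM results cover different probe universes")
    if sam_result.significant is None:
        raise ValueError("SAM result has no delta applied; call select_delta first")
    sam_set = set(sam_result.significant)
    out = [g for g in ttest.significant(p_threshold) if g in sam_set]
    if not out:
        import logging
        logging.getLogger(__name__).warning(
            "t-test and SAM significant sets are disjoint")
    return out


# ---------------------------------------------------------------------------
# Fold changes


def group_fold_change(expr: ExpressionMatrix, group1_ids, group2_ids
                      ) -> pd.DataFrame:
    """Ratio of group-1 to group-2 mean expression per gene.

    Flags over-expression at FC >= 1.5 and under-expression at FC <= 1/1.5.
    Genes whose group-2 mean is zero get FC = NaN and ``undefined`` = True.
    """
    m1 = expr.data[list(group1_ids)].mean(axis=1)
    m2 = expr.data[list(group2_ids)].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = m1 / m2
    undefined = (m2 == 0)
    fc = fc.mask(undefined)
    return pd.DataFrame({
        "fold_change": fc,
        "over_expressed": fc.ge(OVER_FC).fillna(False),
        "under_expressed": fc.le(UNDER_FC).fillna(False),
        "undefined": undefined,
    })


def ddct_fold_change(ct_target: pd.Series, ct_reference: pd.Series,
                     group: pd.Series, calibrator: str) -> pd.Series:
    """Relative RT-PCR quantification by the 2^-ddCt method.

    dCt = Ct_target - Ct_reference per sample (sample-wise normalization to
    the reference gene); ddCt = mean dCt(group) - mean dCt(calibrator group);
    fold change = 2^-ddCt per group (calibrator group maps to 1).
    """
    missing = ct_reference.reindex(ct_target.index).isna()
    if missing.any():
        raise DataError(
            f"missing reference-gene Ct for sample(s): {list(ct_target.index[missing])}")
    dct = ct_target - ct_reference.reindex(ct_target.index)
    group = group.reindex(ct_target.index)
    if calibrator not in set(group):
        raise ValueError(f"calibrator group {calibrator!r} absent")
    means = dct.groupby(group).mean()
    ddct = means - means[calibrator]
    return (2.0 ** -ddct).rename("fold_change")
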