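"""Gaussian Naive Bayes risk scoring.

The prognostic classifier models each signature gene's expression as a
class-conditional Gaussian.  For a sample with expression values a_1..a_G the
posterior probability of the high-risk class (death within the horizon) is

    P(high | a) ∝ P(high) · Π_i N(a_i; μ_i,high, σ_i,high)

normalized over the two classes.  All likelihood arithmetic happens in the
log domain: intensities and SDs in the hundreds-to-thousands range make raw
density products underflow badly.  The posterior itself is the continuous
"risk score"; the decision rule assigns high-risk strictly above a 0.5
threshold.

``load_published_model`` returns the bundled 12-gene lung adenocarcinoma
model (trained on 229 patients; priors 0.45/0.55) shipped as a checksum-
verified TSV parameter table.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core_data import (ClinicalTable, DataError, ExpressionMatrix, HIGH_RISK,
                        LOW_RISK, PrognosisLabels)

CLASSES = (LOW_RISK, HIGH_RISK)

_PUBLISHED_MODEL_RESOURCE = "published_12gene_model.tsv"
_PUBLISHED_MODEL_SHA256 = (
    "6010e7619279cfab31fd40d26f7008b637009b3c2245f6c0f7aff67b76daaf96")


@dataclass
class NBModel:
    """Class priors plus per-class, per-gene Gaussian parameters."""

    genes: list[str]
    priors: dict[str, float]              # class -> prior
    means: pd.DataFrame                   # index = genes, columns = classes
    sds: pd.DataFrame                     # same shape, floored at sigma_floor
    sigma_floor: pd.Series | float = 0.0  # per-gene floor actually applied
    probe_map: dict[str, str] = field(default_factory=dict)  # gene -> probe id

    def __post_init__(self) -> None:
        if set(self.priors) != set(CLASSES):
            raise DataError(f"priors must cover exactly {CLASSES}")
        if any(p <= 0 for p in self.priors.values()):
            raise DataError("priors must be > 0")
        if abs(sum(self.priors.values()) - 1.0) > 1e-9:
            raise DataError("priors must sum to 1")
        for df, name in ((self.means, "means"), (self.sds, "sds")):
            if list(df.index) != list(self.genes) or set(df.columns) != set(CLASSES):
                raise DataError(f"{name} grid incomplete or misordered")
            if df.isna().any().any():
                raise DataError(f"{name} grid has missing cells")
        if (self.sds.to_numpy() <= 0).any():
            raise DataError("all SDs must be > 0 after flooring")

    def to_tsv(self, path) -> None:
        """Serialize as a parameter table: a priors header line, then one
        row per gene and class with mean and sd (the shape published
        parameter tables print)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#priors\t" + "\t".join(
                f"{c}={float(self.priors[c])!r}" for c in CLASSES) + "\n")
            fh.write("gene\tprobe_id\tclass\tmean\tsd\n")
            for g in self.genes:
                probe = self.probe_map.get(g, "")
                for c in CLASSES:
                    fh.write(f"{g}\t{probe}\t{c}\t{float(self.means.at[g, c])!r}"
                             f"\t{float(self.sds.at[g, c])!r}\n")

    @classmethod
    def from_tsv(cls, path_or_buffer) -> "NBModel":
        if hasattr(path_or_buffer, "read"):
            lines = path_or_buffer.read().splitlines()
        else:
            with open(path_or_buffer, encoding="utf-8") as fh:
                lines = fh.read().splitlines()
        if not lines or not lines[0].startswith("#priors\t"):
            raise DataError("model table must start with a '#priors' line")
        priors = {}
        for tok in lines[0].split("\t")[1:]:
            cls_name, val = tok.split("=")
            priors[cls_name] = float(val)
        from io import StringIO
        body = pd.read_csv(StringIO("\n".join(lines[1:])), sep="\t",
                           dtype={"gene": str, "probe_id": str, "class": str})
        genes = list(dict.fromkeys(body["gene"]))
        means = body.pivot(index="gene", columns="class", values="mean").loc[genes]
        sds = body.pivot(index="gene", columns="class", values="sd").loc[genes]
        probe_map = {r.gene: r.probe_id for r in body.itertuples()
                     if isinstance(r.probe_id, str) and r.probe_id}
        return cls(genes=genes, priors=priors, means=means[list(CLASSES)],
                   sds=sds[list(CLASSES)], probe_map=probe_map)


def train_nb(expr: ExpressionMatrix, labels: PrognosisLabels,
             sigma_floor: float | None = None) -> NBModel:
    """Fit class priors and per-class Gaussian parameters by ML.

    Priors are raw class frequencies (no smoothing); means and SDs are the
    per-class sample statistics (SD with denominator n-1).  Each SD is
    floored at ``sigma_floor`` — by default 1e-6 times the gene's observed
    range (with a tiny absolute fallback for globally constant genes) — so a
    within-class constant gene still yields a proper density.
    """
    ids = labels.sample_ids
    sub = expr.subset_samples(ids)
    x = sub.data.to_numpy(dtype=float)
    y = labels.labels.to_numpy()
    n = len(ids)
    means, sds = {}, {}
    for c in CLASSES:
        mask = y == c
        if mask.sum() < 2:
            raise DataError(f"class {c!r} has fewer than 2 samples")
        means[c] = x[:, mask].mean(axis=1)
        sds[c] = x[:, mask].std(axis=1, ddof=1)
    priors = {c: float((y == c).sum()) / n for c in CLASSES}
    if sigma_floor is None:
        rng = x.max(axis=1) - x.min(axis=1)
        floor = np.maximum(1e-6 * rng, 1e-12)
    else:
        floor = np.full(x.shape[0], float(sigma_floor))
    floor_s = pd.Series(floor, index=sub.probe_ids)
    means_df = pd.DataFrame(means, index=sub.probe_ids)[list(CLASSES)]
    sds_df = pd.DataFrame(
        {c: np.maximum(sds[c], floor) for c in CLASSES},
        index=sub.probe_ids)[list(CLASSES)]
    return NBModel(genes=sub.probe_ids, priors=priors, means=means_df,
                   sds=sds_df, sigma_floor=floor_s)


@dataclass
class RiskScore:
    """Posterior probabilities of the high-risk class per sample."""

    posterior_high: pd.Series  # index = sample ids, values in [0, 1]

    def classify(self, threshold: float = 0.5) -> pd.Series:
        return classify(self, threshold)


def _log_posterior_high(model: NBModel, x: np.ndarray) -> np.ndarray:
    """x: (n_genes, n_samples) in model gene order -> posterior(high)."""
    logp = np.empty((len(CLASSES), x.shape[1]))
    for j, c in enumerate(CLASSES):
        mu = model.means[c].to_numpy()[:, None]
        sd = model.sds[c].to_numpy()[:, None]
        ll = -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((x - mu) / sd) ** 2
        logp[j] = np.log(model.priors[c]) + ll.sum(axis=0)
    log_norm = logsumexp(logp, axis=0)
    return np.exp(logp[CLASSES.index(HIGH_RISK)] - log_norm)


def posterior(model: NBModel, sample: dict[str, float] | pd.Series) -> float:
    """Posterior probability of high-risk for one sample.

    ``sample`` maps every model gene to an expression value; extra genes are
    ignored, missing genes are an error.
    """
    sample = pd.Series(sample)
    missing = [g for g in model.genes if g not in sample.index]
    if missing:
        raise DataError(f"sample lacks value(s) for model gene(s): {missing}")
    x = sample.reindex(model.genes).to_numpy(dtype=float)[:, None]
    return float(_log_posterior_high(model, x)[0])


def score_samples(model: NBModel, expr: ExpressionMatrix) -> RiskScore:
    """Posterior high-risk probability for every sample of a matrix."""
    missing = [g for g in model.genes if g not in expr.data.index]
    if missing:
        raise DataError(f"expression matrix lacks model gene(s): {missing}")
    x = expr.data.loc[model.genes].to_numpy(dtype=float)
    post = _log_posterior_high(model, x)
    return RiskScore(pd.Series(post, index=expr.sample_ids, name="risk_score"))


def classify(score: RiskScore, threshold: float = 0.5) -> pd.Series:
    """Strictly-greater decision rule: posterior > threshold -> high-risk.

    A posterior of exactly the threshold is low-risk ("greater than 0.5, or
    low-risk otherwise").
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return pd.Series(
        np.where(score.posterior_high.to_numpy() > threshold, HIGH_RISK, LOW_RISK),
        index=score.posterior_high.index, dtype=object, name="risk_label")


def _published_model_text() -> str:
    return (resources.files("prognosig") / "data"
            / _PUBLISHED_MODEL_RESOURCE).read_text(encoding="utf-8")


def load_published_model() -> NBModel:
    """Load the bundled published 12-gene prognostic model (Tables 1-2 data)."""
    text = _published_model_text()
    digest = hashlib.sha256(text.encode("utf-8")).hexdigest()
    if _PUBLISHED_MODEL_SHA256 is not None and digest != _PUBLISHED_MODEL_SHA256:
        raise DataError("bundled published model fixture is corrupted "
                        f"(sha256 {digest})")
    from io import StringIO
    return NBModel.from_tsv(StringIO(text))


def calibration_curve(scores: RiskScore, clinical: ClinicalTable,
                      horizon_months: float = 60.0, bin_width: float = 0.05,
                      min_bin_n: int = 5) -> pd.DataFrame:
    """Observed death probability at the horizon per risk-score bin.

    Samples are binned by posterior; each occupied bin gets a Kaplan-Meier
    estimate of 1 - S(horizon) with its Greenwood (log-log) 95% CI.  Bins
    with fewer than ``min_bin_n`` samples are flagged unstable.  Empty bins
    are skipped.
    """
    from lifelines import KaplanMeierFitter

    post = scores.posterior_high
    common = [s for s in post.index if s in set(clinical.sample_ids)]
    if not common:
        raise DataError("scores and clinical table share no samples")
    post = post.loc[common]
    clin = clinical.subset(common)
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    which = np.clip(np.digitize(post.to_numpy(), edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        mask = which == b
        n = int(mask.sum())
        if n == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(clin.time_months.to_numpy()[mask], clin.event.to_numpy()[mask])
        s = float(kmf.predict(horizon_months))
        ci = kmf.confidence_interval_survival_function_
        idx = ci.index.searchsorted(horizon_months, side="right") - 1
        if idx >= 0:
            lo, hi = float(ci.iloc[idx, 0]), float(ci.iloc[idx, 1])
        else:
            lo, hi = 1.0, 1.0
        rows.append({"score_mid": (edges[b] + edges[b + 1]) / 2,
                     "death_prob": 1.0 - s,
                     "ci_low": 1.0 - hi, "ci_high": 1.0 - lo,
                     "n": n, "stable": n >= min_bin_n})
    return pd.DataFrame(rows)
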