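"""Synthetic cohorts and cell-line panels with known ground truth.

The cohort generator emulates the statistical structure the discovery
pipeline assumes: per-gene two-class Gaussian expression (a subset of
"informative" genes shifted between prognosis classes), exponential (or
Weibull) survival with a class-specific hazard ratio, and independent
uniform right-censoring tuned to a requested censoring fraction.  The panel
generator emulates an NCI-60-style screen: a latent per-line response driving
both a signature-gene expression block and the log10(GI50) activity vector.

One root seed is expanded into independent per-component child streams
(class labels, expression, survival, censoring) via ``numpy.random.
SeedSequence.spawn``, so e.g. enlarging the gene panel never perturbs the
survival draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from .core_data import ClinicalTable, ExpressionMatrix, HIGH_RISK, LOW_RISK


@dataclass
class CohortSpec:
    """Parameters of a simulated expression + survival cohort.

    effect_size is the between-class mean shift of informative genes in
    within-class SD units; hazard_ratio_highrisk multiplies the baseline
    hazard for the high-risk class; baseline_median_months sets the low-risk
    median survival.  weibull_shape=1 gives exponential survival.
    """

    n_samples: int = 300
    n_genes: int = 2000
    n_informative: int = 20
    effect_size: float = 1.0
    base_mean: float = 300.0
    base_sd: float = 60.0
    censor_rate: float = 0.2
    hazard_ratio_highrisk: float = 3.0
    baseline_median_months: float = 90.0
    weibull_shape: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if not 0 <= self.n_informative <= self.n_genes:
            raise ValueError("need 0 <= n_informative <= n_genes")
        if self.base_mean <= 0 or self.base_sd <= 0:
            raise ValueError("base_mean and base_sd must be > 0")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.hazard_ratio_highrisk <= 0:
            raise ValueError("hazard_ratio_highrisk must be > 0")
        if self.baseline_median_months <= 0 or self.weibull_shape <= 0:
            raise ValueError("survival parameters must be > 0")


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort."""

    informative_genes: list[str]
    true_class: pd.Series  # sample id -> {low_risk, high_risk}

    def write(self, path) -> None:
        out = self.true_class.rename("true_class").to_frame()
        out.index.name = "sample_id"
        out["informative_genes"] = ""
        out.iloc[0, out.columns.get_loc("informative_genes")] = ",".join(
            self.informative_genes)
        out.to_csv(path, sep="\t")


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(n)]


def _weibull_survival_times(rng, n, scale_lambda, shape, hazard_mult):
    # S(t) = exp(-hr * (lambda*t)^shape); inverse-transform sampling.
    u = rng.uniform(size=n)
    return (-np.log(u) / hazard_mult) ** (1.0 / shape) / scale_lambda


def _censor_horizon(scale_lambda, shape, hazard_mults, censor_rate):
    """Upper bound c of Uniform(0, c) censoring achieving the target rate.

    P(censored) = mean_i (1/c) * int_0^c S_i(u) du, solved by bisection.
    """
    if censor_rate == 0:
        return np.inf

    def surv(u, hr):
        return np.exp(-hr * (scale_lambda * u) ** shape)

    def expected_rate(c):
        rates = [integrate.quad(surv, 0, c, args=(hr,))[0] / c
                 for hr in hazard_mults]
        return float(np.mean(rates))

    # expected_rate decreases from 1 (c -> 0) towards 0; bracket then solve.
    hi = 1.0 / scale_lambda
    while expected_rate(hi) > censor_rate:
        hi *= 2
        if hi > 1e9 / scale_lambda:  # pragma: no cover - unreachable rates
            break
    return optimize.brentq(lambda c: expected_rate(c) - censor_rate, 1e-9 / scale_lambda, hi)


def simulate_cohort(spec: CohortSpec
                    ) -> tuple[ExpressionMatrix, ClinicalTable, CohortTruth]:
    """Draw a cohort with class-linked expression and survival.

    Informative genes are Normal(base_mean +/- effect_size*base_sd/2, base_sd)
    per class; all other genes are class-independent Normal(base_mean,
    base_sd).  Negative draws are truncated at 0 (kept, not resampled, so the
    draw count is deterministic).  Survival is Weibull (exponential by
    default) with the high-risk hazard multiplied by hazard_ratio_highrisk;
    censoring is independent Uniform(0, c) with c solved to achieve the
    requested censoring fraction.
    """
    spec.validate()
    rng_class, rng_expr, rng_surv, rng_cens = _child_rngs(spec.seed, 4)

    n, g = spec.n_samples, spec.n_genes
    sample_ids = [f"S{i:04d}" for i in range(n)]
    gene_ids = [f"G{i:05d}" for i in range(g)]
    informative = gene_ids[: spec.n_informative]

    is_high = rng_class.uniform(size=n) < 0.5
    true_class = pd.Series(np.where(is_high, HIGH_RISK, LOW_RISK),
                           index=sample_ids, dtype=object)

    values = rng_expr.normal(spec.base_mean, spec.base_sd, size=(g, n))
    shift = spec.effect_size * spec.base_sd / 2.0
    # high-risk class shifted up, low-risk shifted down, for informative genes
    values[: spec.n_informative, :] += np.where(is_high, shift, -shift)
    np.maximum(values, 0.0, out=values)
    expr = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))

    scale_lambda = np.log(2.0) ** (1.0 / spec.weibull_shape) / spec.baseline_median_months
    hazard_mult = np.where(is_high, spec.hazard_ratio_highrisk, 1.0)
    t_event = _weibull_survival_times(rng_surv, n, scale_lambda,
                                      spec.weibull_shape, hazard_mult)
    c = _censor_horizon(scale_lambda, spec.weibull_shape,
                        [1.0, spec.hazard_ratio_highrisk], spec.censor_rate)
    if np.isinf(c):
        time, event = t_event, np.ones(n, dtype=int)
    else:
        t_cens = rng_cens.uniform(0.0, c, size=n)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)

    clinical = ClinicalTable(pd.DataFrame(
        {"time_months": time, "event": event}, index=sample_ids))
    return expr, clinical, CohortTruth(informative, true_class)


@dataclass
class PanelSpec:
    """Parameters of a simulated cell-line drug-screen panel.

    response_effect is the shift of log10(GI50) per SD of the latent
    response that also drives the signature-gene expression block.
    """

    n_lines: int = 60
    n_genes: int = 1000
    n_signature: int = 12
    response_effect: float = 1.5
    base_mean: float = 300.0
    base_sd: float = 60.0
    gi50_center: float = -5.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_lines < 3:
            raise ValueError("n_lines must be >= 3")
        if not 0 <= self.n_signature <= self.n_genes:
            raise ValueError("need 0 <= n_signature <= n_genes")
        if self.base_mean <= 0 or self.base_sd <= 0:
            raise ValueError("base_mean and base_sd must be > 0")


@dataclass
class PanelTruth:
    """Ground truth of a simulated panel."""

    signature_genes: list[str]
    latent_response: pd.Series  # line id -> latent response (SD units)
    true_label: pd.Series       # thresholded latent at +/- 0.5

    def write(self, path) -> None:
        out = pd.DataFrame({"latent_response": self.latent_response,
                            "true_label": self.true_label})
        out.index.name = "line_id"
        out.to_csv(path, sep="\t")


def simulate_panel(spec: PanelSpec
                   ) -> tuple[ExpressionMatrix, pd.Series, PanelTruth]:
    """Draw a cell-line panel with expression-linked drug activity.

    A latent standard-normal response per line is added (in SD units) to each
    signature gene and scaled by response_effect into the log10(GI50) vector,
    so high-GI50 (resistant) lines over-express the signature block.
    """
    spec.validate()
    rng_latent, rng_expr, rng_act = _child_rngs(spec.seed, 3)

    line_ids = [f"CL{i:03d}" for i in range(spec.n_lines)]
    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    signature = gene_ids[: spec.n_signature]

    latent = rng_latent.normal(size=spec.n_lines)
    values = rng_expr.normal(spec.base_mean, spec.base_sd,
                             size=(spec.n_genes, spec.n_lines))
    values[: spec.n_signature, :] += spec.base_sd * latent
    np.maximum(values, 0.0, out=values)
    expr = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=line_ids))

    gi50 = pd.Series(
        spec.gi50_center + spec.response_effect * latent + rng_act.normal(size=spec.n_lines),
        index=line_ids, name="log10_gi50")

    true_label = pd.Series(
        np.select([latent >= 0.5, latent <= -0.5],
                  ["resistant", "sensitive"], default="intermediate"),
        index=line_ids, dtype=object)
    return expr, gi50, PanelTruth(signature, pd.Series(latent, index=line_ids),
                                  true_label)
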