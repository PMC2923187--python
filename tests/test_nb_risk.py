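import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from prognosig import nb_risk as nb
from prognosig import core_data as cd
from prognosig.core_data import (ClinicalTable, ExpressionMatrix, HIGH_RISK,
                                 LOW_RISK, PrognosisLabels)
from prognosig.synthetic_data import CohortSpec, simulate_cohort

from conftest import balanced_labels, random_expr


def brute_posterior(priors, means, sds, x):
    """Direct Bayes-formula evaluation with raw density products."""
    num = {}
    for c in (LOW_RISK, HIGH_RISK):
        num[c] = priors[c] * np.prod(stats.norm.pdf(x, means[c], sds[c]))
    return num[HIGH_RISK] / (num[LOW_RISK] + num[HIGH_RISK])


def make_model(priors, means, sds, genes=None):
    genes = genes or [f"g{i}" for i in range(len(means[LOW_RISK]))]
    return nb.NBModel(
        genes=genes,
        priors=priors,
        means=pd.DataFrame(means, index=genes)[[LOW_RISK, HIGH_RISK]],
        sds=pd.DataFrame(sds, index=genes)[[LOW_RISK, HIGH_RISK]],
    )


class TestTrain:
    def test_priors_from_class_counts(self):
        # 104 low-risk vs 125 high-risk -> 0.45 / 0.55 at two decimals
        rng = np.random.default_rng(1)
        n = 229
        ids = [f"s{i}" for i in range(n)]
        labels = PrognosisLabels(labels=pd.Series(
            [LOW_RISK] * 104 + [HIGH_RISK] * 125, index=ids, dtype=object))
        expr = ExpressionMatrix(pd.DataFrame(
            np.abs(rng.normal(100, 20, size=(3, n))),
            index=["a", "b", "c"], columns=ids))
        model = nb.train_nb(expr, labels)
        assert round(model.priors[LOW_RISK], 2) == 0.45
        assert round(model.priors[HIGH_RISK], 2) == 0.55
        assert model.priors[LOW_RISK] == pytest.approx(104 / 229)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(2)
        n = 500
        mu = {LOW_RISK: 80.0, HIGH_RISK: 120.0}
        sigma = 15.0
        cols, vals, labs = [], [], []
        for c in (LOW_RISK, HIGH_RISK):
            for i in range(n):
                cols.append(f"{c}{i}")
                labs.append(c)
                vals.append(abs(rng.normal(mu[c], sigma)))
        expr = ExpressionMatrix(pd.DataFrame([vals], index=["g"], columns=cols))
        labels = PrognosisLabels(labels=pd.Series(labs, index=cols, dtype=object))
        model = nb.train_nb(expr, labels)
        se = sigma / np.sqrt(n)
        for c in (LOW_RISK, HIGH_RISK):
            assert abs(model.means.at["g", c] - mu[c]) < 3 * se
            assert abs(model.sds.at["g", c] - sigma) / sigma < 0.05

    def test_constant_gene_floored(self):
        ids = [f"s{i}" for i in range(8)]
        x = pd.DataFrame([[5.0] * 4 + [9.0, 10, 11, 12]], index=["g"], columns=ids)
        labels = PrognosisLabels(labels=pd.Series(
            [HIGH_RISK] * 4 + [LOW_RISK] * 4, index=ids, dtype=object))
        model = nb.train_nb(ExpressionMatrix(x), labels)
        assert model.sds.at["g", HIGH_RISK] > 0
        # still scores without warnings/NaN
        assert 0 <= nb.posterior(model, {"g": 5.0}) <= 1

    def test_missing_class_errors(self):
        ids = ["a", "b", "c"]
        expr = ExpressionMatrix(pd.DataFrame([[1.0, 2, 3]], index=["g"],
                                             columns=ids))
        labels = PrognosisLabels(labels=pd.Series(
            [HIGH_RISK] * 3, index=ids, dtype=object))
        with pytest.raises(Exception):
            nb.train_nb(expr, labels)


class TestPosterior:
    def test_symmetric_model_midpoint(self):
        model = make_model(
            priors={LOW_RISK: 0.5, HIGH_RISK: 0.5},
            means={LOW_RISK: [90.0], HIGH_RISK: [110.0]},
            sds={LOW_RISK: [10.0], HIGH_RISK: [10.0]})
        assert nb.posterior(model, {"g0": 100.0}) == pytest.approx(0.5, abs=1e-12)

    def test_matches_bruteforce_fuzzed(self):
        # sample points within a few SDs of a class mean so the raw density
        # products of the brute-force oracle stay representable
        rng = np.random.default_rng(5)
        for _ in range(300):
            k = rng.integers(1, 4)
            p_high = rng.uniform(0.1, 0.9)
            priors = {LOW_RISK: 1 - p_high, HIGH_RISK: p_high}
            means = {c: rng.uniform(10, 200, k) for c in (LOW_RISK, HIGH_RISK)}
            sds = {c: rng.uniform(5, 50, k) for c in (LOW_RISK, HIGH_RISK)}
            model = make_model(priors, means, sds)
            anchor = means[LOW_RISK] if rng.uniform() < 0.5 else means[HIGH_RISK]
            x = anchor + sds[LOW_RISK] * rng.uniform(-5, 5, k)
            want = brute_posterior(priors, means, sds, x)
            got = nb.posterior(model, dict(zip(model.genes, x)))
            assert got == pytest.approx(want, rel=1e-10)

    def test_gene_order_invariance(self):
        model = make_model(
            priors={LOW_RISK: 0.4, HIGH_RISK: 0.6},
            means={LOW_RISK: [10.0, 50.0], HIGH_RISK: [20.0, 40.0]},
            sds={LOW_RISK: [5.0, 8.0], HIGH_RISK: [4.0, 9.0]})
        sample = {"g1": 45.0, "g0": 12.0}
        assert nb.posterior(model, sample) == nb.posterior(
            model, dict(reversed(list(sample.items()))))

    def test_missing_gene_listed(self):
        model = make_model(
            priors={LOW_RISK: 0.5, HIGH_RISK: 0.5},
            means={LOW_RISK: [10.0, 20.0], HIGH_RISK: [11.0, 21.0]},
            sds={LOW_RISK: [1.0, 1.0], HIGH_RISK: [1.0, 1.0]})
        with pytest.raises(Exception, match="g1"):
            nb.posterior(model, {"g0": 10.0})

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_normalization_property(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 5))
        p_high = float(rng.uniform(0.05, 0.95))
        model = make_model(
            priors={LOW_RISK: 1 - p_high, HIGH_RISK: p_high},
            means={c: rng.uniform(10, 2500, k) for c in (LOW_RISK, HIGH_RISK)},
            sds={c: rng.uniform(1, 600, k) for c in (LOW_RISK, HIGH_RISK)})
        x = rng.uniform(0, 3000, k)
        post_high = nb.posterior(model, dict(zip(model.genes, x)))
        # complement computed by swapping class roles
        flipped = make_model(
            priors={LOW_RISK: p_high, HIGH_RISK: 1 - p_high},
            means={LOW_RISK: model.means[HIGH_RISK].to_numpy(),
                   HIGH_RISK: model.means[LOW_RISK].to_numpy()},
            sds={LOW_RISK: model.sds[HIGH_RISK].to_numpy(),
                 HIGH_RISK: model.sds[LOW_RISK].to_numpy()})
        post_low = nb.posterior(flipped, dict(zip(model.genes, x)))
        assert post_high + post_low == pytest.approx(1.0, abs=1e-9)


class TestClassify:
    @pytest.mark.parametrize("p,expected", [
        (0.5, LOW_RISK), (0.51, HIGH_RISK), (0.0, LOW_RISK), (1.0, HIGH_RISK)])
    def test_strict_threshold(self, p, expected):
        score = nb.RiskScore(pd.Series([p], index=["s"]))
        assert nb.classify(score)["s"] == expected

    def test_custom_threshold(self):
        score = nb.RiskScore(pd.Series([0.4], index=["s"]))
        assert nb.classify(score, threshold=0.3)["s"] == HIGH_RISK
        assert nb.classify(score, threshold=0.4)["s"] == LOW_RISK


class TestPublishedModel:
    def test_contents(self):
        m = nb.load_published_model()
        assert len(m.genes) == 12
        assert m.probe_map["ATP6V0D1"] == "212041_at"
        assert m.means.at["PKLR", LOW_RISK] == pytest.approx(14.3474)
        assert m.sds.at["PKLR", LOW_RISK] == pytest.approx(6.872)
        assert sum(m.priors.values()) == pytest.approx(1.0)

    def test_low_risk_means_score_low(self):
        m = nb.load_published_model()
        post = nb.posterior(m, m.means[LOW_RISK])
        assert post < 0.5
        # brute-force oracle agrees (12 genes is fine in linear domain here)
        want = brute_posterior(
            m.priors,
            {c: m.means[c].to_numpy() for c in (LOW_RISK, HIGH_RISK)},
            {c: m.sds[c].to_numpy() for c in (LOW_RISK, HIGH_RISK)},
            m.means[LOW_RISK].to_numpy())
        assert post == pytest.approx(want, rel=1e-10)

    def test_tsv_roundtrip(self, tmp_path):
        m = nb.load_published_model()
        out = tmp_path / "model.tsv"
        m.to_tsv(out)
        again = nb.NBModel.from_tsv(out)
        assert again.genes == m.genes
        assert again.priors == m.priors
        pd.testing.assert_frame_equal(
            again.means[m.means.columns], m.means, check_names=False)
        assert again.probe_map == m.probe_map

    def test_checksum_guard(self, monkeypatch):
        monkeypatch.setattr(nb, "_PUBLISHED_MODEL_SHA256", "0" * 64)
        with pytest.raises(Exception, match="corrupt"):
            nb.load_published_model()


class TestEndToEnd:
    def test_trained_model_stratifies_heldout_cohort(self):
        from prognosig import survival_eval as sv
        ok = 0
        n_seeds = 8
        for seed in range(n_seeds):
            expr, clin, truth = simulate_cohort(CohortSpec(
                n_samples=300, n_genes=50, n_informative=20,
                effect_size=1.0, seed=seed))
            labels = cd.dichotomize(clin, 60)
            model = nb.train_nb(expr.subset_probes(truth.informative_genes),
                                labels)
            expr2, clin2, _ = simulate_cohort(CohortSpec(
                n_samples=300, n_genes=50, n_informative=20,
                effect_size=1.0, seed=10_000 + seed))
            pred = nb.classify(nb.score_samples(model, expr2))
            t = clin2.time_months.to_numpy()
            e = clin2.event.to_numpy()
            hi = (pred == HIGH_RISK).to_numpy()
            _, _, p = sv.logrank([(t[hi], e[hi]), (t[~hi], e[~hi])])
            ok += p < 0.01
        assert ok == n_seeds


class TestCalibrationCurve:
    def _clin(self, times, events):
        ids = [f"s{i}" for i in range(len(times))]
        return ids, ClinicalTable(pd.DataFrame(
            {"time_months": times, "event": events}, index=ids))

    def test_all_deaths_one_bin(self):
        ids, clin = self._clin([10, 20, 30, 40], [1, 1, 1, 1])
        scores = nb.RiskScore(pd.Series([0.9, 0.91, 0.92, 0.93], index=ids))
        curve = nb.calibration_curve(scores, clin, horizon_months=60)
        assert len(curve) == 1
        assert curve.iloc[0]["death_prob"] == pytest.approx(1.0)

    def test_no_events_zero_death(self):
        ids, clin = self._clin([100, 110, 120, 130], [0, 0, 0, 0])
        scores = nb.RiskScore(pd.Series([0.11, 0.12, 0.61, 0.63], index=ids))
        curve = nb.calibration_curve(scores, clin, horizon_months=60)
        assert (curve["death_prob"] == 0).all()
        assert len(curve) == 2  # two occupied bins, empty ones skipped

    def test_monotone_on_score_linked_hazard(self):
        rng = np.random.default_rng(33)
        n = 2000
        score = rng.uniform(0, 1, n)
        lam = 0.005 * np.exp(2.5 * score)
        t = rng.exponential(1 / lam)
        cens = rng.uniform(0, 300, n)
        ids = [f"s{i}" for i in range(n)]
        clin = ClinicalTable(pd.DataFrame(
            {"time_months": np.minimum(t, cens),
             "event": (t <= cens).astype(int)}, index=ids))
        scores = nb.RiskScore(pd.Series(score, index=ids))
        curve = nb.calibration_curve(scores, clin, horizon_months=60,
                                     bin_width=0.1)
        stable = curve[curve["stable"]]
        rho = stats.spearmanr(stable["score_mid"], stable["death_prob"]).statistic
        assert rho > 0.8
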