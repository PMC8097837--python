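"""Beta-binomial regression, FDR adjustment, and aggregation."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_hyp
from scipy.special import expit

from genecag import (
    CAGPartition,
    GeneCatalog,
    aggregate_by_annotation,
    bh_adjust,
    build_count_table,
    build_design_matrix,
    fit_beta_binomial,
    fit_errors_in_response,
    significant_cags,
)
from genecag.stats import _bb_negloglik_and_grad, fit_all_cags


def bh_bruteforce(p):
    """Independent step-up implementation: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = min(running, 1.0)
    return q


def simulate_bb(n, beta0, beta1, phi, rng, m_low=5000, m_high=15000):
    x = np.r_[np.zeros(n // 2), np.ones(n - n // 2)]
    mu = expit(beta0 + beta1 * x)
    if phi > 0:
        r = (1 - phi) / phi
        p = rng.beta(mu * r, (1 - mu) * r)
    else:
        p = mu
    M = rng.integers(m_low, m_high, n)
    W = rng.binomial(M, p)
    X = pd.DataFrame({"Intercept": 1.0, "x": x})
    return W, M, X


class TestBetaBinomialFit:
    def test_binomial_limit_intercept_only(self):
        # phi -> 0: the MLE of the mean must match the pooled proportion
        rng = np.random.default_rng(0)
        W, M, _ = simulate_bb(60, -2.0, 0.0, 0.0, rng)
        X = pd.DataFrame({"Intercept": np.ones(60)})
        fit = fit_beta_binomial(W, M, X)
        assert expit(fit.beta[0]) == pytest.approx(W.sum() / M.sum(), abs=1e-4)

    def test_agrees_with_logistic_oracle_without_overdispersion(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        W, M, X = simulate_bb(100, -2.0, 0.7, 0.0, rng)
        fit = fit_beta_binomial(W, M, X)
        glm = sm.GLM(np.column_stack([W, M - W]), X.to_numpy(), family=sm.families.Binomial()).fit()
        assert np.allclose(fit.beta, glm.params, atol=1e-3)

    def test_effect_recovery(self):
        rng = np.random.default_rng(3)
        ests = []
        for _ in range(200):
            W, M, X = simulate_bb(200, -3.0, 1.0, 0.02, rng)
            ests.append(fit_beta_binomial(W, M, X).beta[1])
        mean_est = float(np.mean(ests))
        assert mean_est == pytest.approx(1.0, abs=0.1)
        # each single estimate should be within a few SEs of truth
        W, M, X = simulate_bb(200, -3.0, 1.0, 0.02, rng)
        f = fit_beta_binomial(W, M, X)
        assert abs(f.beta[1] - 1.0) < 3 * f.se[1]

    def test_loglik_improves_over_null_start(self):
        rng = np.random.default_rng(5)
        W, M, X = simulate_bb(50, -2.5, 0.8, 0.02, rng)
        fit = fit_beta_binomial(W, M, X)
        null_params = np.array([0.0, 0.0, np.log(0.01 / 0.99)])
        null_nll, _ = _bb_negloglik_and_grad(null_params, W.astype(float), M.astype(float), X.to_numpy())
        assert fit.loglik >= -null_nll
        # gradient ~ 0 at the optimum
        from scipy.special import logit as slogit

        _, grad = _bb_negloglik_and_grad(
            np.concatenate([fit.beta, [slogit(fit.phi)]]), W.astype(float), M.astype(float), X.to_numpy()
        )
        assert np.abs(grad).max() < 1e-2

    def test_separation_flagged_not_fitted(self):
        X = pd.DataFrame({"Intercept": np.ones(10)})
        fit = fit_beta_binomial(np.zeros(10), np.full(10, 100), X)
        assert not fit.converged
        assert fit.message == "separation"


class TestCountTable:
    def test_counts_per_cag(self, alignment_row):
        part = CAGPartition({"c1": ["gA", "gB"], "c2": ["gC"]})
        assignments = pd.DataFrame(
            [
                {"specimen": "s1", "read_id": f"r{i}", "gene_id": g, "aligned_bases": 150}
                for i, g in enumerate(["gA"] * 6 + ["gB"] * 3 + ["gC"] * 1)
            ]
        )
        counts = build_count_table(assignments, part)
        assert counts.W.loc["s1", "c1"] == 9
        assert counts.W.loc["s1", "c2"] == 1
        assert counts.M.loc["s1"] == 10

    def test_unassigned_gene_rejected(self):
        part = CAGPartition({"c1": ["gA"]})
        assignments = pd.DataFrame(
            [{"specimen": "s1", "read_id": "r0", "gene_id": "gX", "aligned_bases": 100}]
        )
        with pytest.raises(KeyError, match="gX"):
            build_count_table(assignments, part)

    def test_matches_planted_allocation(self, small_experiment):
        exp = small_experiment
        truth_part = CAGPartition(
            {c: [g for g, cc in exp.truth.gene_to_cag.items() if cc == c] for c in exp.truth.cag_ids}
        )
        # count directly from the planted per-read sources
        src = exp.truth.read_source.copy()
        src["aligned_bases"] = 150
        counts = build_count_table(src, truth_part)
        expected = (
            src.assign(cag=src["gene_id"].map(exp.truth.gene_to_cag))
            .groupby(["specimen", "cag"])
            .size()
            .unstack(fill_value=0)
        )
        assert (counts.W.to_numpy() == expected[counts.W.columns].to_numpy()).all()


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_all_equal(self):
        q = bh_adjust(np.full(5, 0.2))
        assert np.allclose(q, 0.2)

    def test_known_vector(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st_hyp.lists(st_hyp.floats(0, 1), min_size=1, max_size=50))
    def test_matches_bruteforce(self, p):
        q = bh_adjust(np.array(p))
        assert np.allclose(q, bh_bruteforce(p))
        assert (q >= np.array(p) - 1e-12).all()


class TestErrorsInResponse:
    def test_single_observation(self):
        b0, se0, s2, _ = fit_errors_in_response(np.array([0.7]), np.array([0.3]))
        assert (b0, se0, s2) == (0.7, 0.3, 0.0)

    def test_equal_variance_zero_heterogeneity_closed_form(self):
        # with sigma2 = 0 and equal known variances v, the intercept is the
        # sample mean with SE sqrt(v/k)
        y = np.array([0.5, 0.6, 0.7, 0.8, 0.9])
        v = 2.0  # huge vs the spread, so ML puts sigma2 at 0
        b0, se0, s2, clamped = fit_errors_in_response(y, np.full(5, np.sqrt(v)))
        assert s2 == 0.0 and clamped
        assert b0 == pytest.approx(y.mean())
        assert se0 == pytest.approx(np.sqrt(v / 5))

    def test_matches_metafor_ml(self, tmp_path):
        # independent random-effects meta-analysis oracle (metafor, ML)
        rng = np.random.default_rng(8)
        y = rng.normal(0.5, 0.4, size=12)
        se = rng.uniform(0.1, 0.3, size=12)
        b0, se0, s2, _ = fit_errors_in_response(y, se)
        script = tmp_path / "rma.R"
        script.write_text(
            "suppressMessages(library(metafor))\n"
            f"y <- c({','.join(map(str, y))})\n"
            f"se <- c({','.join(map(str, se))})\n"
            'r <- rma(yi=y, sei=se, method="ML")\n'
            "cat(coef(r), r$se, r$tau2)\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        ).stdout.split()
        rb0, rse0, rtau2 = map(float, out)
        assert b0 == pytest.approx(rb0, abs=1e-4)
        assert se0 == pytest.approx(rse0, abs=1e-4)
        assert s2 == pytest.approx(rtau2, abs=1e-4)

    def test_parameter_recovery_over_labels(self):
        rng = np.random.default_rng(5)
        estimates = []
        for _ in range(50):
            se = rng.uniform(0.1, 0.3, size=20)
            y = 0.8 + rng.normal(0, np.sqrt(0.1), 20) + rng.normal(0, se)
            estimates.append(fit_errors_in_response(y, se)[0])
        assert np.mean(estimates) == pytest.approx(0.8, abs=0.05)


class TestAggregation:
    def _setup(self):
        catalog = GeneCatalog(
            pd.DataFrame(
                {
                    "gene_id": ["g1", "g2", "g3", "g4"],
                    "length_aa": [100] * 4,
                    "taxon": ["taxA", "taxA", "taxB", None],
                    "function": [None] * 4,
                }
            )
        )
        part = CAGPartition({"c1": ["g1"], "c2": ["g2", "g3"], "c3": ["g4"]})
        fits = pd.DataFrame(
            {
                "estimate": [1.0, 2.0, 3.0],
                "se": [0.5, 0.5, 0.5],
                "converged": [True, True, True],
            },
            index=pd.Index(["c1", "c2", "c3"], name="cag_id"),
        )
        return catalog, part, fits

    def test_multi_label_cag_contributes_to_each(self):
        catalog, part, fits = self._setup()
        agg = aggregate_by_annotation(fits, part, catalog, "taxon")
        # taxA: c1 + c2; taxB: c2 only; unannotated c3 contributes nowhere
        assert agg.loc["taxA", "n_cags"] == 2
        assert agg.loc["taxB", "n_cags"] == 1
        assert agg.loc["taxB", "beta0_hat"] == pytest.approx(2.0)
        assert agg.loc["taxB", "se0"] == pytest.approx(0.5)

    def test_single_cag_label_passthrough(self):
        catalog, part, fits = self._setup()
        agg = aggregate_by_annotation(fits, part, catalog, "taxon")
        assert agg.loc["taxB", "sigma2_hat"] == 0.0


class TestSignificantCags:
    def _fits(self):
        return pd.DataFrame(
            {
                "estimate": [2.0, -1.5, 0.3, -0.2],
                "q": [0.001, 0.005, 0.2, np.nan],
            },
            index=pd.Index(["c1", "c2", "c3", "c4"], name="cag_id"),
        )

    def test_split_by_sign(self):
        pos, neg = significant_cags(self._fits(), 0.01)
        assert pos == ["c1"] and neg == ["c2"]

    def test_zero_threshold_empty(self):
        pos, neg = significant_cags(self._fits(), 0.0)
        assert pos == [] and neg == []


class TestDesignMatrix:
    def test_formula_over_manifest_columns(self):
        cov = pd.DataFrame(
            {"outcome": ["responder", "progressor", "responder", "progressor"],
             "cohort": ["a", "a", "b", "b"]},
            index=pd.Index([f"s{i}" for i in range(4)], name="specimen"),
        )
        X = build_design_matrix(cov, "outcome + cohort")
        assert "Intercept" in X.columns
        assert X.shape == (4, 3)

    def test_rank_deficiency_rejected(self):
        cov = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]},
            index=pd.Index(["s1", "s2", "s3"], name="specimen"),
        )
        with pytest.raises(ValueError, match="rank"):
            build_design_matrix(cov, "a + b")
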