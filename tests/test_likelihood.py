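"""LK / CLK likelihoods, intercept profiling, and the estimator facade."""

import numpy as np
import pytest
from sklearn.base import clone

import presback as pb
from presback.likelihood import FitFamily, _design_full_rank
from presback.simulate import PBDataset


def _tiny():
    """P = {0}, B = {0, 1}: small enough to check by hand."""
    return PBDataset(P=np.array([[0.0]]), B=np.array([[0.0], [1.0]]))


class TestFitFamily:
    def test_design_and_params(self):
        fam = FitFamily("logistic", 3, 1)
        T = fam.design(np.array([[2.0]]))
        assert np.allclose(T, [[2.0, 4.0, 8.0]])
        assert fam.n_params == 4

    def test_per_covariate_degrees(self):
        fam = FitFamily("logistic", (1, 2), 2)
        T = fam.design(np.array([[2.0, 3.0]]))
        assert np.allclose(T, [[2.0, 3.0, 9.0]])
        assert fam.n_params == 4

    def test_links(self):
        g = np.array([0.0])
        assert FitFamily("logistic").p_of_g(g)[0] == pytest.approx(0.5)
        assert FitFamily("exponential").p_of_g(g)[0] == pytest.approx(1.0)
        assert FitFamily("cloglog").p_of_g(g)[0] == pytest.approx(1 - np.exp(-1))

    def test_validation(self):
        with pytest.raises(ValueError):
            FitFamily("probit")
        with pytest.raises(ValueError):
            FitFamily("logistic", 0)


class TestLKLoglik:
    def test_hand_computed_value(self):
        """sum_P ln p - n1 ln(mean_B p) with the linear logistic at
        beta=(-0.606, 3.64): checked against a manual evaluation."""
        fam = FitFamily("logistic", 1, 1)
        L = pb.lk_loglik([-0.606, 3.64], fam, _tiny())
        p0 = 1 / (1 + np.exp(-0.606))
        p1 = 1 / (1 + np.exp(-0.606 + 3.64))
        expected = np.log(p0) - 1 * np.log((p0 + p1) / 2)
        assert L == pytest.approx(expected, abs=1e-12)
        assert L == pytest.approx(0.6245914579859025, abs=1e-12)

    def test_exponential_scale_invariance(self, small_linear_data):
        """Multiplying an exponential family by k shifts the intercept
        by ln k and must leave the relative log-likelihood unchanged."""
        fam = FitFamily("exponential", 1, 1)
        beta = np.array([-1.2, -0.7])
        L1 = pb.lk_loglik(beta, fam, small_linear_data)
        L2 = pb.lk_loglik(beta + np.array([np.log(2), 0.0]), fam,
                          small_linear_data)
        assert L2 == pytest.approx(L1, abs=1e-9)

    def test_degenerate_probability_is_minus_inf(self):
        fam = FitFamily("exponential", 1, 1)
        assert pb.lk_loglik([-1e4, 0.0], fam, _tiny()) == -np.inf


class TestProfileIntercept:
    @pytest.mark.parametrize("link", ["logistic", "exponential", "cloglog"])
    @pytest.mark.parametrize("pi0", [0.05, 0.3, 0.9])
    def test_constraint_satisfied_exactly(self, small_linear_data, link, pi0):
        fam = FitFamily(link, 1, 1)
        beta_rest = np.array([0.8])
        b0 = pb.profile_intercept(beta_rest, fam, small_linear_data.B, pi0)
        TB = fam.design(small_linear_data.B)
        mean = fam.p_of_g(b0 + TB @ beta_rest).mean()
        assert mean == pytest.approx(pi0, abs=1e-10)

    def test_monotone_in_pi0(self, small_linear_data):
        fam = FitFamily("logistic", 1, 1)
        b = [pb.profile_intercept([0.5], fam, small_linear_data.B, p)
             for p in (0.1, 0.3, 0.6)]
        # logistic is decreasing in g: larger pi0 needs smaller intercept
        assert b[0] > b[1] > b[2]

    def test_exponential_closed_form(self, small_linear_data):
        fam = FitFamily("exponential", 1, 1)
        beta_rest = np.array([-0.4])
        b0 = pb.profile_intercept(beta_rest, fam, small_linear_data.B, 0.2)
        h = fam.design(small_linear_data.B) @ beta_rest
        assert np.exp(b0 + h).mean() == pytest.approx(0.2, rel=1e-12)

    def test_invalid_pi0(self, small_linear_data):
        fam = FitFamily("logistic", 1, 1)
        with pytest.raises(ValueError):
            pb.profile_intercept([0.0], fam, small_linear_data.B, 0.0)
        with pytest.raises(ValueError):
            pb.profile_intercept([0.0], fam, small_linear_data.B, 1.0)


class TestFitLK:
    def test_recovers_shape_up_to_scale(self, small_linear_data, cat):
        """LK cannot identify the scale, but the fitted curve should be
        proportional in shape: slope sign and ranking match the truth."""
        fam = FitFamily("logistic", 1, 1)
        res = pb.fit_lk(small_linear_data, fam, n_starts=5, seed=0)
        assert res.converged
        grid = np.linspace(-1, 1, 9)[:, None]
        pf = res.predict(grid)
        assert np.all(np.diff(pf) < 0)  # decreasing, like the truth

    def test_deterministic(self, small_linear_data):
        fam = FitFamily("logistic", 1, 1)
        r1 = pb.fit_lk(small_linear_data, fam, seed=4)
        r2 = pb.fit_lk(small_linear_data, fam, seed=4)
        assert np.array_equal(r1.beta_hat, r2.beta_hat)

    def test_rank_deficient_design_flagged(self):
        X = np.full((200, 1), 0.7)  # constant covariate
        d = PBDataset(P=X[:50], B=X[50:])
        fam = FitFamily("logistic", 1, 1)
        assert not _design_full_rank(fam, d)
        res = pb.fit_lk(d, fam)
        assert not res.converged
        assert any("rank" in str(x.get("error", "")) for x in res.diagnostics)

    def test_diagnostics_one_row_per_start(self, small_linear_data):
        res = pb.fit_lk(small_linear_data, FitFamily("logistic", 1, 1),
                        n_starts=3, seed=1)
        assert len(res.diagnostics) == 3
        assert res.n_starts_used == 3

    def test_exponential_fit_keeps_probabilities_valid(self, cat):
        d = pb.simulate_pb(cat.model("cat2_exponential"), 1000, 10_000, seed=8)
        fam = FitFamily("exponential", 3, 1)
        res = pb.fit_lk(d, fam, seed=0)
        pf = res.predict(np.vstack([d.P, d.B]))
        assert pf.max() <= 1.0 + 1e-6


class TestFitCLK:
    def test_constraint_holds_and_truth_recovered(self, small_linear_data, cat):
        m = cat.model("cat1_linear")
        pi0 = pb.true_prevalence(m)
        fam = FitFamily("logistic", 1, 1)
        res = pb.fit_clk(small_linear_data, fam, pi0, seed=0)
        assert res.converged
        assert res.constraint_residual <= 1e-8
        assert res.pi_constraint == pi0
        assert pb.rmse_curve(res, m) < 0.03

    def test_constrained_no_better_than_unconstrained(self, small_linear_data):
        fam = FitFamily("logistic", 1, 1)
        lk = pb.fit_lk(small_linear_data, fam, seed=0)
        clk = pb.fit_clk(small_linear_data, fam, 0.3, seed=0)
        assert clk.loglik <= lk.loglik + 1e-6

    def test_exponential_constraint(self, cat):
        m = cat.model("cat2_exponential")
        d = pb.simulate_pb(m, 1000, 10_000, seed=21)
        pi0 = pb.true_prevalence(m)
        res = pb.fit_clk(d, FitFamily("exponential", 3, 1), pi0, seed=0)
        assert res.converged
        assert res.constraint_residual <= 1e-8
        assert pb.rmse_curve(res, m) < 0.1

    def test_invalid_pi0(self, small_linear_data):
        with pytest.raises(ValueError):
            pb.fit_clk(small_linear_data, FitFamily("logistic", 1, 1), 1.5)

    def test_deterministic(self, small_linear_data):
        fam = FitFamily("logistic", 1, 1)
        r1 = pb.fit_clk(small_linear_data, fam, 0.4, seed=2)
        r2 = pb.fit_clk(small_linear_data, fam, 0.4, seed=2)
        assert np.array_equal(r1.beta_hat, r2.beta_hat)


class TestRefinedCLK:
    def test_oracle_pipeline_end_to_end(self, cat):
        """With oracle scores the estimated prevalence must sit near the
        latent p2/n0 and the constrained fit must track the truth."""
        m = cat.model("cat1_linear")
        d = pb.simulate_pb(m, 2000, 20_000, seed=31)
        cfg = pb.ClassifierConfig(kind="oracle", oracle_model=m,
                                  oracle_c=d.implied_c)
        rep = pb.fit_refined_clk(d, FitFamily("logistic", 1, 1),
                                 pb.LocalKnowledge(), cfg, seed=0)
        assert rep.prevalence.pi_hat == pytest.approx(d.p2 / d.n0, rel=0.10)
        assert rep.fit.converged
        assert pb.rmse_curve(rep.fit, m) < 0.06
        assert rep.provenance["pi0"] == pytest.approx(rep.prevalence.pi_hat)

    def test_neural_pipeline_runs(self, small_linear_data, cat):
        rep = pb.fit_refined_clk(small_linear_data, FitFamily("logistic", 1, 1),
                                 seed=0)
        assert rep.fit.converged
        assert 0 < rep.prevalence.pi_hat <= 1
        assert rep.scores.scores.shape[0] == 11_000


class TestSklearnFacade:
    def test_lk_estimator_roundtrip(self, small_linear_data):
        d = small_linear_data
        X, s = d.pooled()
        est = pb.LKEstimator(link="logistic", degree=1, random_state=0)
        assert clone(est).get_params() == est.get_params()
        est.fit(X, s)
        assert est.converged_
        assert est.coef_.shape == (2,)
        p = est.predict(np.array([[0.0]]))
        assert 0 < p[0] < 1
        direct = pb.fit_lk(d, FitFamily("logistic", 1, 1), seed=0)
        assert np.allclose(est.coef_, direct.beta_hat)

    def test_clk_estimator(self, small_linear_data, cat):
        X, s = small_linear_data.pooled()
        pi0 = pb.true_prevalence(cat.model("cat1_linear"))
        est = pb.CLKEstimator(pi0=pi0).fit(X, s)
        assert est.converged_
        assert est.constraint_residual_ <= 1e-8
        est2 = clone(est).set_params(pi0=0.2).fit(X, s)
        assert est2.result_.pi_constraint == 0.2

    def test_refined_estimator_fitted_attributes(self, small_linear_data):
        X, s = small_linear_data.pooled()
        est = pb.RefinedCLKEstimator(random_state=0).fit(X, s)
        for attr in ("coef_", "loglik_", "converged_", "c_hat_", "pi_hat_",
                     "constraint_residual_", "result_", "report_"):
            assert hasattr(est, attr)
        assert 0 < est.c_hat_ < 1 and 0 < est.pi_hat_ <= 1

    def test_input_validation(self):
        est = pb.LKEstimator()
        with pytest.raises(ValueError):
            est.fit(np.zeros((4, 1)), np.array([0, 1, 2, 1]))
        with pytest.raises(ValueError):
            est.fit(np.zeros((4, 1)), np.array([0, 1, 1]))
        with pytest.raises(RuntimeError):
            pb.LKEstimator().predict(np.zeros((1, 1)))
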