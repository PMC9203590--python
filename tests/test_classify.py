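"""Membership classifier Pr(s=1|x): oracle algebra and trained models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import presback as pb
from presback.classify import SMembershipClassifier
from presback.rspf import RSPFModel


def _const_model(p):
    return RSPFModel("exponential", (np.log(p), 0.0), ((1,),), domain=((-1.0, 1.0),))


class TestOracleScores:
    def test_certain_presence_scores_c(self):
        # p(x)=1 everywhere => Pr(s=1|x) = c exactly
        s = pb.oracle_scores(_const_model(1.0), 0.37, np.zeros((5, 1)))
        assert np.allclose(s, 0.37)

    def test_half_half_is_one_third(self):
        s = pb.oracle_scores(_const_model(0.5), 0.5, np.zeros((1, 1)))
        assert s[0] == pytest.approx(1 / 3, abs=1e-12)

    def test_clipping(self):
        s = pb.oracle_scores(_const_model(1e-8), 0.5, np.zeros((1, 1)))
        assert s[0] == 1e-6

    def test_invalid_c(self):
        with pytest.raises(ValueError):
            pb.oracle_scores(_const_model(0.5), 1.0, np.zeros((1, 1)))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(c=st.floats(0.05, 0.95))
    def test_monotone_in_presence_probability(self, cat, c):
        """Pr(s=1|x) must preserve the ranking of p(x)."""
        m = cat.model("cat1_linear")
        xs = np.linspace(-1, 1, 21)[:, None]
        p = m.probability(xs)
        s = pb.oracle_scores(m, c, xs)
        assert np.array_equal(np.argsort(p), np.argsort(s))


class TestTrainedClassifier:
    def test_scores_aligned_and_bounded(self, small_linear_data):
        cfg = pb.ClassifierConfig(kind="logistic_main_effects", seed=0)
        scorer = pb.fit_s_classifier(small_linear_data, cfg)
        sc = pb.score_pb(scorer, small_linear_data)
        d = small_linear_data
        assert sc.scores.shape == (d.n1 + d.n0,)
        assert sc.background_scores.shape == (d.n0,)
        assert np.all((sc.scores >= 1e-6) & (sc.scores <= 1 - 1e-6))
        # presence rows must on average outscore background rows
        assert sc.scores[:d.n1].mean() > sc.background_scores.mean()

    def test_neural_net_decile_tracks_implied_c(self, cat):
        """On the linear logistic species the top-decile mean score
        should land near the implied labelling frequency."""
        d = pb.simulate_pb(cat.model("cat1_linear"), 2000, 20_000, seed=77)
        scorer = pb.fit_s_classifier(d, pb.ClassifierConfig(seed=0))
        sc = pb.score_pb(scorer, d)
        top = pb.select_top_sites(sc, 10.0)
        c_hat = pb.estimate_c(sc, top, "mean")
        # top-decile sites have p(x) near the in-domain max (~0.97), so
        # their mean membership score sits close to but below c
        assert abs(c_hat - d.implied_c) < 0.05

    def test_neural_net_calibration(self, cat):
        """Binned predicted vs empirical membership frequencies agree."""
        d = pb.simulate_pb(cat.model("cat1_linear"), 2000, 20_000, seed=42)
        scorer = pb.fit_s_classifier(d, pb.ClassifierConfig(seed=0))
        X, s = d.pooled()
        pred = scorer.predict_s(X)
        for lo in np.arange(0.0, 1.0, 0.2):
            m = (pred >= lo) & (pred < lo + 0.2)
            if m.sum() < 200:
                continue
            assert abs(pred[m].mean() - s[m].mean()) < 0.05

    def test_no_rebalancing_duplication_shifts_scores(self, cat):
        """Training is calibrated to the n1:n0 design: duplicating the
        presence rows must *raise* the fitted scores (a rebalancing
        classifier would be invariant)."""
        rng = np.random.default_rng(5)
        X0 = rng.uniform(-1, 1, size=(2000, 1))
        X1 = rng.uniform(-1, 1, size=(500, 1))
        X = np.vstack([X1, X0])
        s = np.r_[np.ones(500), np.zeros(2000)]
        base = SMembershipClassifier(kind="logistic_main_effects").fit(X, s)
        Xd = np.vstack([X1, X1, X1, X0])
        sd = np.r_[np.ones(1500), np.zeros(2000)]
        dup = SMembershipClassifier(kind="logistic_main_effects").fit(Xd, sd)
        grid = np.linspace(-1, 1, 11)[:, None]
        assert dup.predict_s(grid).mean() > base.predict_s(grid).mean() + 0.1

    def test_too_few_rows_rejected(self):
        X = np.zeros((12, 1))
        s = np.r_[np.ones(3), np.zeros(9)]
        with pytest.raises(ValueError):
            SMembershipClassifier().fit(X, s)

    def test_dimension_mismatch(self, small_linear_data):
        cfg = pb.ClassifierConfig(kind="logistic_main_effects")
        scorer = pb.fit_s_classifier(small_linear_data, cfg)
        with pytest.raises(ValueError):
            scorer.predict_s(np.zeros((3, 2)))

    def test_empty_matrix(self, small_linear_data):
        cfg = pb.ClassifierConfig(kind="logistic_main_effects")
        scorer = pb.fit_s_classifier(small_linear_data, cfg)
        assert pb.score(scorer, np.empty((0, 1))).shape == (0,)

    def test_unfitted_raises(self):
        from sklearn.exceptions import NotFittedError
        with pytest.raises(NotFittedError):
            SMembershipClassifier().predict_s(np.zeros((1, 1)))

    def test_deterministic_given_seed(self, small_linear_data):
        cfg = pb.ClassifierConfig(seed=3)
        s1 = pb.score_pb(pb.fit_s_classifier(small_linear_data, cfg),
                         small_linear_data).scores
        s2 = pb.score_pb(pb.fit_s_classifier(small_linear_data, cfg),
                         small_linear_data).scores
        assert np.array_equal(s1, s2)


class TestOracleKind:
    def test_oracle_config_round_trip(self, cat, small_linear_data):
        d = small_linear_data
        cfg = pb.ClassifierConfig(kind="oracle",
                                  oracle_model=cat.model("cat1_linear"),
                                  oracle_c=d.implied_c)
        scorer = pb.fit_s_classifier(d, cfg)
        sc = pb.score_pb(scorer, d)
        direct = pb.oracle_scores(cat.model("cat1_linear"), d.implied_c,
                                  np.vstack([d.P, d.B]))
        assert np.array_equal(sc.scores, direct)

    def test_oracle_requires_model_and_c(self, small_linear_data):
        with pytest.raises(ValueError):
            pb.fit_s_classifier(small_linear_data,
                                pb.ClassifierConfig(kind="oracle"))


class TestSerialisation:
    @pytest.mark.parametrize("kind", ["neural_net", "logistic_main_effects"])
    def test_json_round_trip_identical_scores(self, small_linear_data, kind):
        cfg = pb.ClassifierConfig(kind=kind, seed=1)
        scorer = pb.fit_s_classifier(small_linear_data, cfg)
        back = SMembershipClassifier.from_json(scorer.to_json())
        grid = np.linspace(-1, 1, 23)[:, None]
        assert np.allclose(scorer.predict_s(grid), back.predict_s(grid),
                           atol=1e-12)


class TestConfigValidation:
    def test_bad_clip(self):
        with pytest.raises(ValueError):
            pb.ClassifierConfig(clip_eps=0.5)

    def test_bad_hidden_units(self):
        with pytest.raises(ValueError):
            pb.ClassifierConfig(hidden_units=0)

    def test_unknown_kind(self, small_linear_data):
        with pytest.raises(ValueError):
            pb.fit_s_classifier(small_linear_data,
                                pb.ClassifierConfig(kind="forest"))
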