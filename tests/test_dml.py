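"""Cross-fitted double machine learning: residuals, theta, bootstrap, subgroups."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gapdml import dml
from gapdml.instruments import OUTCOME_COLUMN
from gapdml.synthetic import SurveyConfig, generate_survey, linear_structural_spec


class TestCrossfitResiduals:
    def test_perfect_nuisance_limit(self):
        rng = np.random.default_rng(0)
        W = rng.standard_normal((400, 3))
        t = W @ np.array([0.5, -0.2, 0.1])          # exactly linear in W
        y = W @ np.array([1.0, 2.0, -1.0])
        rs = dml.crossfit_residuals(y, t + rng.standard_normal(400), W,
                                    learner="linear", n_folds=4, seed=0)
        assert np.max(np.abs(rs.e_y)) < 1e-8        # outcome fully explained

    def test_residuals_are_out_of_fold(self):
        rng = np.random.default_rng(1)
        W = rng.standard_normal((200, 2))
        y = W[:, 0] + rng.standard_normal(200)
        t = W[:, 1] + rng.standard_normal(200)
        rs = dml.crossfit_residuals(y, t, W, learner="linear", n_folds=5, seed=3)
        assert sorted(np.unique(rs.fold_assignment)) == [0, 1, 2, 3, 4]
        assert abs(rs.e_y.mean()) < 0.2 and abs(rs.e_t.mean()) < 0.2

    def test_treatment_in_w_rejected(self):
        rng = np.random.default_rng(2)
        W = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
        with pytest.raises(ValueError, match="treatment also appears"):
            dml.crossfit_residuals(rng.normal(size=50), W["a"].to_numpy(), W,
                                   learner="linear")

    def test_constant_treatment_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="constant"):
            dml.crossfit_residuals(rng.normal(size=50), np.ones(50),
                                   rng.normal(size=(50, 2)), learner="linear")


class TestThetaHat:
    def test_exact_linear_relation(self):
        e_t = np.array([1.0, -2.0, 3.0])
        assert dml.theta_hat(2 * e_t, e_t) == pytest.approx(2.0)

    def test_orthogonal_residuals_give_zero(self):
        e_t = np.array([1.0, -1.0, 1.0, -1.0])
        e_y = np.array([1.0, 1.0, -1.0, -1.0])
        assert dml.theta_hat(e_y, e_t) == pytest.approx(0.0)

    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        e_t = rng.standard_normal(50)
        e_y = rng.standard_normal(50)
        lstsq = np.linalg.lstsq(e_t[:, None], e_y, rcond=None)[0][0]
        assert abs(dml.theta_hat(e_y, e_t) - lstsq) < 1e-10

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            dml.theta_hat(np.array([1.0, 2.0]), np.zeros(2))


class TestKfoldTheta:
    def _rs(self, e_y, e_t, folds):
        folds = np.asarray(folds)
        return dml.ResidualSet(e_y=np.asarray(e_y, float), e_t=np.asarray(e_t, float),
                               fold_assignment=folds, nuisance_scores={},
                               n_folds=int(folds.max()) + 1)

    def test_constructed_fold_thetas_average(self):
        e_t = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        e_y = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])  # theta_k = 1, 2, 3
        per_fold, mean, _ = dml.kfold_theta(self._rs(e_y, e_t, [0, 0, 1, 1, 2, 2]))
        assert per_fold == pytest.approx([1.0, 2.0, 3.0])
        assert mean == pytest.approx(2.0)

    def test_single_fold_reduces_to_theta_hat(self):
        rng = np.random.default_rng(4)
        e_t = rng.standard_normal(30)
        e_y = 0.7 * e_t + 0.1 * rng.standard_normal(30)
        _, mean, pooled = dml.kfold_theta(self._rs(e_y, e_t, np.zeros(30, int)))
        assert mean == pooled == pytest.approx(dml.theta_hat(e_y, e_t))

    def test_homogeneous_folds_agree_with_pooled(self):
        e_t = np.tile([1.0, -1.0], 10)
        e_y = 1.5 * e_t
        per_fold, mean, pooled = dml.kfold_theta(
            self._rs(e_y, e_t, np.repeat([0, 1], 10)))
        assert mean == pytest.approx(pooled) == pytest.approx(1.5)

    def test_degenerate_fold_skipped_with_warning(self):
        e_t = np.array([1.0, -1.0, 0.0, 0.0])
        e_y = np.array([2.0, -2.0, 1.0, 1.0])
        with pytest.warns(UserWarning, match="degenerate"):
            per_fold, mean, _ = dml.kfold_theta(self._rs(e_y, e_t, [0, 0, 1, 1]))
        assert per_fold == pytest.approx([2.0])


class TestBootstrap:
    def test_noiseless_relation_collapses_interval(self):
        rng = np.random.default_rng(5)
        e_t = rng.standard_normal(200)
        se, ci, used = dml.bootstrap_inference(0.5 * e_t, e_t, B=500, seed=0)
        assert se < 1e-12
        assert ci[0] == pytest.approx(ci[1], abs=1e-10) == pytest.approx(0.5)
        assert used == 500

    def test_bootstrap_floor_enforced(self):
        with pytest.raises(ValueError, match="100"):
            dml.bootstrap_inference(np.ones(10), np.ones(10), B=50)

    def test_se_stable_when_doubling_replicates(self):
        rng = np.random.default_rng(6)
        e_t = rng.standard_normal(500)
        e_y = 0.3 * e_t + rng.standard_normal(500)
        se1, _, _ = dml.bootstrap_inference(e_y, e_t, B=1000, seed=1)
        se2, _, _ = dml.bootstrap_inference(e_y, e_t, B=2000, seed=1)
        assert se1 == pytest.approx(se2, rel=0.15)


class TestDmlAte:
    CFG = dml.DMLConfig(learner="linear", n_folds=5, bootstrap_b=300, seed=2)

    def test_pooled_estimate_is_orthogonal(self, encoded_linear):
        W = encoded_linear.drop(columns=["BAR", OUTCOME_COLUMN])
        rs = dml.crossfit_residuals(encoded_linear[OUTCOME_COLUMN],
                                    encoded_linear["BAR"], W,
                                    learner="linear", n_folds=5, seed=0)
        theta = dml.theta_hat(rs.e_y, rs.e_t)
        resid = rs.e_y - theta * rs.e_t
        assert abs(np.dot(rs.e_t, resid)) < 1e-8

    def test_recovers_known_effect_under_confounding(self, encoded_linear, linear_survey):
        truth = linear_survey.true_effects.coeff_map
        r = dml.dml_ate(encoded_linear, "BAR", config=self.CFG)
        assert r.theta == pytest.approx(truth["BAR"], abs=0.05)
        assert r.theta == pytest.approx(np.mean(r.theta_per_fold))
        assert r.ci95[0] < r.theta < r.ci95[1]
        assert r.ci95 == pytest.approx((r.theta - 1.96 * r.se, r.theta + 1.96 * r.se))

    def test_null_treatment_interval_covers_zero(self, encoded_linear):
        # AT carries no effect in the linear structural design
        r = dml.dml_ate(encoded_linear, "AT", config=self.CFG)
        assert r.ci95[0] <= 0.0 <= r.ci95[1]

    def test_orthogonalization_beats_naive_regression(self):
        # heavy linear confounding: naive slope absorbs the confounder path
        theta_true, wins = 0.3, 0
        for rep in range(20):
            rng = np.random.default_rng(500 + rep)
            W = rng.standard_normal((800, 3))
            t = 0.8 * W[:, 0] + 0.6 * rng.standard_normal(800)
            y = theta_true * t + 1.2 * W[:, 0] - 0.5 * W[:, 1] + 0.4 * rng.standard_normal(800)
            naive = np.dot(t, y) / np.dot(t, t)
            rs = dml.crossfit_residuals(y, t, W, learner="linear", n_folds=5, seed=rep)
            est = dml.theta_hat(rs.e_y, rs.e_t)
            wins += abs(est - theta_true) < abs(naive - theta_true)
        assert wins >= 18

    def test_missing_columns_rejected(self, encoded_linear):
        with pytest.raises(ValueError, match="treatment column"):
            dml.dml_ate(encoded_linear, "GHOST", config=self.CFG)


class TestSubgroups:
    CFG = dml.DMLConfig(learner="linear", n_folds=5, bootstrap_b=200, seed=3)

    def test_undersized_group_refused(self):
        ds = generate_survey(300, seed=5,
                             config=SurveyConfig(structural=linear_structural_spec()))
        from conftest import encode_with_outcome

        data = encode_with_outcome(ds)
        with pytest.raises(ValueError, match="below the minimum"):
            dml.subgroup_ates(data, "SE", ["UI"], config=self.CFG, min_size=250)

    def test_homogeneous_effect_matches_pooled(self, encoded_linear):
        pooled = dml.dml_ate(encoded_linear, "BAR", config=self.CFG).theta
        res = dml.subgroup_ates(encoded_linear, "SE", ["BAR"], config=self.CFG,
                                min_size=250)
        lo = res.results["lower"][0].theta
        hi = res.results["higher"][0].theta
        assert lo == pytest.approx(pooled, abs=0.06)
        assert hi == pytest.approx(pooled, abs=0.06)
        assert sum(res.group_sizes.values()) == len(encoded_linear)

    def test_block_table_shape(self, encoded_linear):
        res = dml.subgroup_ates(encoded_linear, "BAR", ["UI", "SS"],
                                config=self.CFG, min_size=250)
        frame = res.to_frame()
        assert set(frame["group"]) == {"lower", "higher"}
        assert len(frame) == 4
        assert set(res.outcome_r2) == {"lower", "higher"}
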