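"""Psychometric validation statistics and feature encoding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gapdml import measurement as m
from gapdml.instruments import DEFAULT_LOADINGS

# Constructs whose published AVE/CR are self-consistent with their printed
# loadings under the standard formulas.
PRINTED = [
    ("BEN", "ave", 0.778), ("BEN", "cr", 0.875),
    ("AT", "ave", 0.742),
    ("SE", "ave", 0.787), ("SE", "cr", 0.936),
    ("SEV", "ave", 0.613), ("SEV", "cr", 0.825),
    ("EE", "ave", 0.832),
    ("FC", "cr", 0.878),
    ("PN", "cr", 0.937),
    ("SS", "ave", 0.679), ("SS", "cr", 0.894),
]


@pytest.mark.parametrize("construct,stat,expected", PRINTED)
def test_validity_statistics_reproduce_instrument_calibration(construct, stat, expected):
    lam = DEFAULT_LOADINGS[construct]
    value = m.ave(lam) if stat == "ave" else m.composite_reliability(lam)
    assert m.round_half_up(value, 3) == expected


def test_ave_cr_identity_and_guards():
    assert m.ave((1.0, 1.0)) == 1.0
    assert m.composite_reliability((1.0,)) == 1.0
    for fn in (m.ave, m.composite_reliability):
        with pytest.raises(ValueError):
            fn(())
        with pytest.raises(ValueError):
            fn((0.5, 1.2))


class TestCronbachAlpha:
    def test_identical_items_give_unit_alpha(self):
        x = np.random.default_rng(0).normal(size=100)
        items = np.column_stack([x, x, x])
        assert m.cronbach_alpha(items) == pytest.approx(1.0)

    def test_independent_items_drive_alpha_to_zero(self):
        items = np.random.default_rng(1).normal(size=(20000, 2))
        assert abs(m.cronbach_alpha(items)) < 0.05

    def test_parallel_items_match_spearman_brown(self):
        # k parallel items with intercorrelation r: alpha ~ kr / (1 + (k-1)r)
        rng = np.random.default_rng(2)
        k, r, n = 4, 0.5, 40000
        f = rng.normal(size=n)
        items = np.column_stack([np.sqrt(r) * f + np.sqrt(1 - r) * rng.normal(size=n)
                                 for _ in range(k)])
        expected = k * r / (1 + (k - 1) * r)
        assert m.cronbach_alpha(items) == pytest.approx(expected, abs=0.02)

    def test_agrees_with_independent_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        f = rng.normal(size=300)
        items = pd.DataFrame({f"i{j}": 0.7 * f + rng.normal(size=300) for j in range(4)})
        ours = m.cronbach_alpha(items.to_numpy())
        theirs = pingouin.cronbach_alpha(items)[0]
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_guards(self):
        with pytest.raises(ValueError):
            m.cronbach_alpha(np.ones((100, 1)))
        with pytest.raises(ValueError, match="zero variance"):
            m.cronbach_alpha(np.ones((100, 3)))


@given(st.permutations(list(range(4))))
def test_item_order_invariance(perm):
    rng = np.random.default_rng(7)
    f = rng.normal(size=200)
    items = np.column_stack([0.8 * f + rng.normal(size=200) for _ in range(4)])
    lam = (0.6, 0.7, 0.8, 0.9)
    assert m.cronbach_alpha(items[:, perm]) == pytest.approx(m.cronbach_alpha(items))
    lam_p = tuple(lam[i] for i in perm)
    assert m.ave(lam_p) == pytest.approx(m.ave(lam))
    assert m.composite_reliability(lam_p) == pytest.approx(m.composite_reliability(lam))


class TestKMO:
    def test_identity_matrix_defined_as_zero(self):
        assert m.kmo(np.eye(4)) == 0.0

    def test_equicorrelated_three_variables_frozen_value(self):
        # off-diagonal r = 0.5 everywhere: partial r = 1/3 for every pair,
        # KMO = 6*0.25 / (6*0.25 + 6/9)
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        expected = 1.5 / (1.5 + 6.0 / 9.0)
        assert m.kmo(R) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_partial_correlation_oracle(self):
        # independent oracle: partial correlations via regression residuals
        # on a large MVN sample drawn from R
        rng = np.random.default_rng(5)
        R = np.array([
            [1.0, 0.5, 0.3, 0.2],
            [0.5, 1.0, 0.4, 0.1],
            [0.3, 0.4, 1.0, 0.25],
            [0.2, 0.1, 0.25, 1.0],
        ])
        X = rng.multivariate_normal(np.zeros(4), R, size=400000)
        Re = np.corrcoef(X.T)
        p = 4
        partial = np.zeros((p, p))
        for i in range(p):
            for j in range(i + 1, p):
                others = [k for k in range(p) if k not in (i, j)]
                Z = X[:, others]
                ri = X[:, i] - Z @ np.linalg.lstsq(Z, X[:, i], rcond=None)[0]
                rj = X[:, j] - Z @ np.linalg.lstsq(Z, X[:, j], rcond=None)[0]
                partial[i, j] = partial[j, i] = np.corrcoef(ri, rj)[0, 1]
        off = ~np.eye(p, dtype=bool)
        oracle = np.sum(Re[off] ** 2) / (np.sum(Re[off] ** 2) + np.sum(partial[off] ** 2))
        assert m.kmo(Re) == pytest.approx(oracle, abs=0.01)

    def test_singular_matrix_rejected_with_condition_diagnostic(self):
        R = np.ones((3, 3))
        with pytest.raises(ValueError, match="condition number"):
            m.kmo(R)


class TestBartlett:
    def test_identity_gives_zero_chi2_unit_p(self):
        chi2, df, p = m.bartlett_sphericity(np.eye(5), n=100)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert df == 10
        assert p == pytest.approx(1.0)

    def test_strong_correlation_is_overwhelmingly_significant(self):
        R = np.full((6, 6), 0.5)
        np.fill_diagonal(R, 1.0)
        _, _, p = m.bartlett_sphericity(R, n=1334)
        assert p < 0.001

    def test_guards(self):
        with pytest.raises(ValueError, match="more observations"):
            m.bartlett_sphericity(np.eye(5), n=4)
        bad = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="determinant"):
            m.bartlett_sphericity(bad, n=50)


class TestEncodeFeatures:
    @pytest.fixture()
    def raw(self):
        rng = np.random.default_rng(11)
        return pd.DataFrame({
            "score": rng.normal(5, 2, 300),
            "level": rng.choice([1, 2, 3, 4], 300),
        })

    def test_zscore_and_one_hot(self, raw):
        enc = m.encode_features(raw, {"score": "continuous", "level": "categorical"})
        assert enc.frame["score"].mean() == pytest.approx(0.0, abs=1e-12)
        assert enc.frame["score"].std(ddof=0) == pytest.approx(1.0)
        dummies = enc.frame[[c for c in enc.frame.columns if c.startswith("level=")]]
        assert dummies.shape[1] == 4
        assert np.allclose(dummies.sum(axis=1), 1.0)
        assert enc.model_matrix().filter(like="level=").shape[1] == 3

    def test_constant_column_rejected(self, raw):
        raw = raw.assign(flat=1.0)
        with pytest.raises(ValueError, match="constant"):
            m.encode_features(raw, {"score": "continuous", "level": "categorical",
                                    "flat": "continuous"})

    def test_idempotent_on_already_encoded_continuous(self, raw):
        schema = {"score": "continuous", "level": "continuous"}
        once = m.encode_features(raw, schema).frame
        twice = m.encode_features(once, schema).frame
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_correlation_screen_warns_on_near_duplicates(self, raw):
        raw = raw.assign(echo=raw["score"] * 2 + 0.001)
        schema = {"score": "continuous", "level": "categorical", "echo": "continuous"}
        with pytest.warns(UserWarning, match="exceed"):
            enc = m.encode_features(raw, schema)
        assert enc.corr_warnings and enc.max_abs_corr > 0.99

    def test_unlabelled_column_rejected(self, raw):
        with pytest.raises(ValueError, match="does not label"):
            m.encode_features(raw, {"score": "continuous"})
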