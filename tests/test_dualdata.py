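"""Dual-data masking, permutation, losses and the exact risk oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splitsig import (
    Dataset,
    DiscreteJoint,
    FeatureSet,
    LossSpec,
    make_dual,
    parse_region,
    per_sample_loss,
    permute_features,
    read_delimited,
    risk_difference_oracle,
    write_delimited,
)
from splitsig.dualdata import (
    DegeneratePermutationError,
    InvalidFeatureSetError,
    conditional_pmfs,
)


class TestMakeDual:
    @pytest.mark.parametrize(
        "row, idx, M, expected",
        [
            ((1.5, -2.0, 3.0), (0,), 0.0, (0.0, -2.0, 3.0)),
            ((1.0, 1.0, 1.0), (0, 1, 2), 7.0, (7.0, 7.0, 7.0)),
            ((1.5, -2.0, 3.0), (), 0.0, (1.5, -2.0, 3.0)),  # empty set = identity
        ],
    )
    def test_masking(self, row, idx, M, expected):
        data = Dataset(np.array([row]), np.array([0.0]))
        out = make_dual(data, FeatureSet(idx, M))
        assert tuple(out.features[0]) == expected
        assert out.outcome[0] == 0.0

    def test_input_not_modified(self, rng):
        X = rng.standard_normal((10, 4))
        data = Dataset(X.copy(), np.zeros(10))
        make_dual(data, FeatureSet((1, 2), 5.0))
        np.testing.assert_array_equal(data.features, X)

    def test_out_of_range_rejected(self):
        data = Dataset(np.ones((3, 2)), np.zeros(3))
        with pytest.raises(InvalidFeatureSetError):
            make_dual(data, FeatureSet((5,)))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_idempotent(self, seed):
        r = np.random.default_rng(seed)
        data = Dataset(r.standard_normal((8, 5)), r.standard_normal(8))
        fs = FeatureSet(tuple(r.choice(5, size=r.integers(1, 5), replace=False)),
                        float(r.standard_normal()))
        once = make_dual(data, fs)
        twice = make_dual(once, fs)
        np.testing.assert_array_equal(once.features, twice.features)


class TestPermuteFeatures:
    def test_joint_permutation_shares_pi(self, rng):
        # hypothesized columns move together; others and outcome do not
        X = np.column_stack([np.arange(6.0), np.arange(6.0) * 10, np.arange(6.0) * 100])
        data = Dataset(X, np.arange(6.0))
        out = permute_features(data, FeatureSet((0, 1)), rng)
        np.testing.assert_array_equal(out.features[:, 0] * 10, out.features[:, 1])
        np.testing.assert_array_equal(out.features[:, 2], X[:, 2])
        np.testing.assert_array_equal(out.outcome, data.outcome)
        assert sorted(out.features[:, 0]) == sorted(X[:, 0])

    def test_single_row_rejected(self, rng):
        with pytest.raises(DegeneratePermutationError):
            permute_features(Dataset(np.ones((1, 2)), np.zeros(1)), FeatureSet((0,)), rng)

    def test_permutations_uniform(self):
        # all 6 permutations of 3 rows appear with frequency 1/6 +- 0.02
        data = Dataset(np.array([[0.0], [1.0], [2.0]]), np.zeros(3))
        fs = FeatureSet((0,))
        rng = np.random.default_rng(123)
        counts = {p: 0 for p in itertools.permutations((0.0, 1.0, 2.0))}
        draws = 10_000
        for _ in range(draws):
            out = permute_features(data, fs, rng)
            counts[tuple(out.features[:, 0])] += 1
        for c in counts.values():
            assert abs(c / draws - 1 / 6) < 0.02


class TestPerSampleLoss:
    def test_squared(self):
        out = per_sample_loss([2.0], [5.0], LossSpec("squared"))
        assert out[0] == pytest.approx(9.0)

    def test_cross_entropy(self):
        out = per_sample_loss([[0.5, 0.5]], [0], LossSpec("cross_entropy"))
        assert out[0] == pytest.approx(-np.log(0.5))

    def test_cross_entropy_floor(self):
        out = per_sample_loss([[1.0, 0.0]], [1], LossSpec("cross_entropy"))
        assert out[0] == pytest.approx(-np.log(1e-12))

    def test_cross_entropy_rejects_nonprobabilities(self):
        with pytest.raises(ValueError):
            per_sample_loss([[0.9, 0.3]], [0], LossSpec("cross_entropy"))

    def test_zero_one(self):
        out = per_sample_loss([1, 0, 1], [1, 1, 0], LossSpec("zero_one"))
        np.testing.assert_array_equal(out, [0.0, 1.0, 1.0])


def _bernoulli_pair_joint():
    """X1, X2 iid Bernoulli(1/2), Y = X1; support enumerated."""
    pts = list(itertools.product([0, 1], [0, 1]))
    x1 = np.array([[a] for a, _ in pts], dtype=float)
    x2 = np.array([[b] for _, b in pts], dtype=float)
    y = np.array([a for a, _ in pts])
    p = np.full(4, 0.25)
    return x1, x2, y, p


def _random_joint(rng, factorized):
    """Random joint over x_s in {0,1}, (x_c, y) in {0,1,2} x {0,1}.

    With ``factorized`` the pmf is p(x_s) * p(x_c, y), which makes
    Y independent of X_S given X_Sc by construction.
    """
    pts = list(itertools.product([0, 1], [0, 1, 2], [0, 1]))
    if factorized:
        ps = rng.dirichlet(np.ones(2))
        pcy = rng.dirichlet(np.ones(6)).reshape(3, 2)
        p = np.array([ps[s] * pcy[c, y] for s, c, y in pts])
    else:
        p = rng.dirichlet(np.ones(len(pts)))
    x_s = np.array([[s] for s, _, _ in pts], dtype=float)
    x_c = np.array([[c] for _, c, _ in pts], dtype=float)
    y = np.array([y for _, _, y in pts])
    return DiscreteJoint(x_s, x_c, y, p / p.sum())


class TestRiskOracle:
    def test_conditionally_independent_feature_is_null(self):
        x1, x2, y, p = _bernoulli_pair_joint()
        joint = DiscreteJoint(x_s=x2, x_c=x1, y=y, probs=p)  # S = {X2}
        assert risk_difference_oracle(joint, LossSpec("squared")) == pytest.approx(0.0, abs=1e-12)

    def test_masking_the_driver_costs_its_variance(self):
        x1, x2, y, p = _bernoulli_pair_joint()
        joint = DiscreteJoint(x_s=x1, x_c=x2, y=y, probs=p)  # S = {X1} = Y
        # R(f*) = 0, masked Bayes risk = Var(Y) = 1/4
        assert risk_difference_oracle(joint, LossSpec("squared")) == pytest.approx(-0.25)

    def test_unsupported_loss_rejected(self):
        x1, x2, y, p = _bernoulli_pair_joint()
        joint = DiscreteJoint(x1, x2, y, p)
        with pytest.raises(ValueError):
            risk_difference_oracle(joint, LossSpec("zero_one"))

    @pytest.mark.parametrize("loss", ["squared", "cross_entropy"])
    def test_masking_never_improves_bayes_risk(self, loss):
        rng = np.random.default_rng(7)
        for _ in range(100):
            joint = _random_joint(rng, factorized=False)
            assert risk_difference_oracle(joint, LossSpec(loss)) <= 1e-10

    @pytest.mark.parametrize("loss", ["squared", "cross_entropy"])
    def test_conditional_independence_implies_invariance(self, loss):
        rng = np.random.default_rng(11)
        for _ in range(200):
            joint = _random_joint(rng, factorized=True)
            assert abs(risk_difference_oracle(joint, LossSpec(loss))) < 1e-10

    def test_cross_entropy_invariance_implies_conditional_independence(self):
        # equivalence direction: zero risk gap forces the conditional pmfs
        # with and without the hypothesized features to agree everywhere
        rng = np.random.default_rng(13)
        for _ in range(50):
            joint = _random_joint(rng, factorized=True)
            assert abs(risk_difference_oracle(joint, LossSpec("cross_entropy"))) < 1e-10
            pairs = conditional_pmfs(joint)
            np.testing.assert_allclose(pairs[:, 0], pairs[:, 1], atol=1e-8)

    def test_dependent_joint_has_disagreeing_conditionals(self):
        x1, x2, y, p = _bernoulli_pair_joint()
        joint = DiscreteJoint(x_s=x1, x_c=x2, y=y, probs=p)
        assert risk_difference_oracle(joint, LossSpec("cross_entropy")) < -1e-3
        pairs = conditional_pmfs(joint)
        assert np.max(np.abs(pairs[:, 0] - pairs[:, 1])) > 0.1


class TestExternalInterfaces:
    def test_delimited_roundtrip(self, tmp_path, rng):
        data = Dataset(rng.standard_normal((20, 3)), rng.standard_normal(20),
                       ("a", "b", "c"))
        path = tmp_path / "data.csv"
        write_delimited(data, path, outcome="y")
        back = read_delimited(path, outcome="y")
        np.testing.assert_allclose(back.features, data.features)
        np.testing.assert_allclose(back.outcome, data.outcome)
        assert back.column_names == ("a", "b", "c")

    def test_region_spec(self):
        assert parse_region("rows 2:4, cols 0:3", 5, 5) == (10, 11, 12, 15, 16, 17)

    def test_region_out_of_range(self):
        with pytest.raises(ValueError):
            parse_region("rows 2:9, cols 0:3", 5, 5)

    def test_missing_values_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b,y\n1,2,3\n4,,6\n")
        with pytest.raises(ValueError):
            read_delimited(path, outcome="y")
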