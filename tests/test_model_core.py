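"""Unit and property tests for tabulation, shrinkage and the Bayes rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

import vacalib as vl
from vacalib.model_core import ValidationError


class TestTabulation:
    def test_prediction_counts_direct(self, space2):
        pc = vl.tabulate_predictions(["a", "a", "b"], space2)
        assert pc.v.tolist() == [2, 1] and pc.N == 3
        np.testing.assert_allclose(pc.naive_q, [2 / 3, 1 / 3])

    def test_degenerate_single_class(self):
        space = vl.LabelSpace(["a", "b", "c"])
        pc = vl.tabulate_predictions(["a"] * 17, space)
        assert pc.v.tolist() == [17, 0, 0]

    def test_uniform_draws_within_binomial_bounds(self, rng):
        space = vl.LabelSpace(["w", "x", "y", "z"])
        labels = np.asarray(space.classes)[rng.integers(0, 4, size=1000)]
        pc = vl.tabulate_predictions(labels.tolist(), space)
        assert pc.N == 1000
        lo, hi = binom.ppf([0.0005, 0.9995], 1000, 0.25)
        assert ((pc.v >= lo) & (pc.v <= hi)).all()

    def test_unknown_label_rejected_with_value(self, space2):
        with pytest.raises(ValidationError, match="'zzz'"):
            vl.tabulate_predictions(["a", "zzz"], space2)
        with pytest.raises(ValidationError):
            vl.tabulate_predictions([], space2)

    def test_transfer_counts(self, space2):
        T = vl.tabulate_transfer(["a", "a", "b"], ["a", "b", "b"], space2)
        assert T.T.tolist() == [[1, 1], [0, 1]]
        assert T.n_i.tolist() == [2, 1] and T.n == 3

    def test_transfer_empty_and_perfect(self, space2):
        assert vl.tabulate_transfer([], [], space2).n == 0
        labels = ["a", "b", "b"]
        T = vl.tabulate_transfer(labels, labels, space2)
        assert T.T.tolist() == [[1, 0], [0, 2]]

    def test_transfer_length_mismatch(self, space2):
        with pytest.raises(ValidationError, match="mismatch"):
            vl.tabulate_transfer(["a"], ["a", "b"], space2)


class TestConfusionEstimators:
    def test_mom_row_normalization(self, space2):
        T = vl.TransferCounts(T=[[1, 1], [0, 1]], space=space2)
        np.testing.assert_allclose(vl.mom_confusion(T), [[0.5, 0.5], [0, 1]])
        T2 = vl.TransferCounts(T=[[65, 35], [0, 100]], space=space2)
        np.testing.assert_allclose(vl.mom_confusion(T2), [[0.65, 0.35], [0, 1]])

    def test_mom_rejects_empty_row(self, space2):
        T = vl.TransferCounts(T=[[2, 1], [0, 0]], space=space2)
        with pytest.raises(ValidationError, match="shrink_confusion"):
            vl.mom_confusion(T)

    def test_shrink_no_data_is_identity(self, space2):
        T = vl.TransferCounts(T=np.zeros((2, 2), int), space=space2)
        for g in (0.1, 1.0, 100.0):
            np.testing.assert_array_equal(vl.shrink_confusion(T, g), np.eye(2))

    def test_shrink_small_gamma_recovers_mom(self, space2):
        T = vl.TransferCounts(T=[[3, 1], [2, 2]], space=space2)
        np.testing.assert_allclose(
            vl.shrink_confusion(T, 1e-12), vl.mom_confusion(T), atol=1e-12
        )

    def test_shrink_hand_blend(self, space2):
        # row (10, 10), gamma 20 -> lambda = 0.5, blend of (0.5, 0.5) and e_1
        T = vl.TransferCounts(T=[[10, 10], [0, 20]], space=space2)
        M = vl.shrink_confusion(T, [20.0, 1.0])
        np.testing.assert_allclose(M[0], [0.75, 0.25])

    def test_shrink_rejects_nonpositive_gamma(self, space2):
        T = vl.TransferCounts(T=[[1, 0], [0, 1]], space=space2)
        with pytest.raises(ValidationError):
            vl.shrink_confusion(T, 0.0)

    @given(
        t=st.lists(
            st.lists(st.integers(0, 50), min_size=3, max_size=3),
            min_size=3,
            max_size=3,
        ),
        gamma=st.floats(0.01, 100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_shrink_rows_always_stochastic(self, t, gamma):
        space = vl.LabelSpace(["a", "b", "c"])
        T = vl.TransferCounts(T=np.array(t), space=space)
        M = vl.shrink_confusion(T, gamma)
        assert (M >= 0).all()
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)


class TestComposeAndBayes:
    def test_identity_channel(self):
        p = np.array([0.2, 0.3, 0.5])
        np.testing.assert_allclose(vl.compose_q(np.eye(3), p), p)

    def test_m2_uniform_product(self):
        M2 = vl.builtin_confusion("M2")
        q = vl.compose_q(M2, np.full(4, 0.25))
        np.testing.assert_allclose(q, [0.4125, 0.0875, 0.125, 0.375])

    def test_point_mass_gives_first_row(self):
        M2 = vl.builtin_confusion("M2")
        np.testing.assert_allclose(vl.compose_q(M2, [1, 0, 0, 0]), M2[0])

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            vl.compose_q(np.eye(3), np.array([0.5, 0.5]))

    def test_individual_posterior_identity(self):
        out = vl.individual_posterior(np.eye(3), np.array([0.2, 0.3, 0.5]), 1)
        np.testing.assert_allclose(out, [0, 1, 0])

    def test_individual_posterior_m2_uniform(self):
        M2 = vl.builtin_confusion("M2")
        out = vl.individual_posterior(M2, np.full(4, 0.25), 0)
        np.testing.assert_allclose(out, np.array([1, 0.65, 0, 0]) / 1.65)

    def test_individual_posterior_rows_normalize(self, rng):
        M3 = vl.builtin_confusion("M3")
        p = rng.dirichlet(np.ones(4))
        for j in range(4):
            assert vl.individual_posterior(M3, p, j).sum() == pytest.approx(1.0)

    def test_zero_column_rejected(self):
        M = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValidationError):
            vl.individual_posterior(M, np.array([0.5, 0.5]), 1)


class TestGammaConditional:
    HYPER = vl.Hyperparams(epsilon=1e-3, alpha=1.0, beta=1.0)

    def test_finite_at_one(self):
        val = vl.log_gamma_conditional(1.0, np.full(4, 0.25), 0, self.HYPER)
        assert math.isfinite(val)

    def test_ratio_matches_direct_evaluation(self):
        # independent evaluation of the printed density with math.lgamma
        m_row = np.array([0.7, 0.1, 0.2])
        C, e, a, b = 3, self.HYPER.epsilon, self.HYPER.alpha, self.HYPER.beta

        def direct(g):
            val = (
                math.lgamma(C * g * e + g)
                - (C - 1) * math.lgamma(g * e)
                - math.lgamma(g * e + g)
            )
            val += (a - 1) * math.log(g) - b * g
            for j, m in enumerate(m_row):
                val += (g * e + (g if j == 0 else 0.0)) * math.log(m)
            return val

        for g1, g2 in [(0.5, 2.0), (1.0, 10.0), (0.01, 0.5)]:
            got = vl.log_gamma_conditional(
                g1, m_row, 0, self.HYPER
            ) - vl.log_gamma_conditional(g2, m_row, 0, self.HYPER)
            assert got == pytest.approx(direct(g1) - direct(g2), abs=1e-10)

    def test_small_gamma_limit_rate(self):
        # as gamma -> 0+ the Gamma-function ratio behaves like
        # gamma^(C-1) eps^(C-1) (1+eps)/(1+C eps): the log-density stays finite
        # at every gamma > 0 but decreases at rate (C-1) log gamma
        m_row = np.full(4, 0.25)
        vals = [
            vl.log_gamma_conditional(g, m_row, 0, self.HYPER)
            for g in (1e-4, 1e-6, 1e-8)
        ]
        assert all(math.isfinite(v) for v in vals)
        C = 4
        expected_drop = (C - 1) * math.log(1e-6 / 1e-8)
        assert vals[1] - vals[2] == pytest.approx(expected_drop, rel=1e-3)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValidationError):
            vl.log_gamma_conditional(0.0, np.full(3, 1 / 3), 0, self.HYPER)
        with pytest.raises(ValidationError):
            vl.log_gamma_conditional(1.0, np.array([0.0, 0.5, 0.5]), 0, self.HYPER)


class TestValidation:
    def test_label_space_invariants(self):
        with pytest.raises(ValidationError):
            vl.LabelSpace(["a"])
        with pytest.raises(ValidationError):
            vl.LabelSpace(["a", "a"])

    def test_hyperparams_guards(self):
        with pytest.raises(ValidationError):
            vl.Hyperparams(epsilon=0.0)
        with pytest.raises(ValidationError):
            vl.Hyperparams(alpha=-1.0)
        with pytest.warns(UserWarning, match="improper"):
            vl.Hyperparams(delta=0.0)

    def test_sampler_control_guards(self):
        with pytest.raises(ValidationError):
            vl.SamplerControl(n_iter=10, n_burnin=10)
        with pytest.raises(ValidationError):
            vl.SamplerControl(mh_step=0.0)
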