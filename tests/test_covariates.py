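"""Covariate-dependent calibration: design building, softmax, PG block."""

import numpy as np
import pandas as pd
import pytest

import vacalib as vl
from vacalib._polya_gamma import pg_mean, pg_var, random_polyagamma
from vacalib.covariates import CoefficientPrior, build_design, marginal_csmf, softmax_csmf

from conftest import mc_se


@pytest.fixture
def records4(space4, rng):
    names = np.asarray(space4.classes)
    n = 240
    return pd.DataFrame(
        {
            "predicted": names[rng.integers(0, 4, size=n)],
            "region": rng.choice(["N", "S", "E", "W"], size=n),
            "age": rng.choice(["0-1", "1-4", "5+"], size=n),
            "bmi": rng.normal(16, 2, size=n),
        }
    )


class TestBuildDesign:
    def test_fully_crossed_categorical(self, records4, space4):
        d = build_design(
            records4, [("region", "categorical"), ("age", "categorical")], space4
        )
        assert d.H == 12  # 4 regions x 3 age groups
        assert d.V.sum() == len(records4)
        assert d.n_h.tolist() == d.V.sum(axis=1).tolist()

    def test_intercept_only_collapses_to_v(self, records4, space4):
        d = build_design(records4, [], space4)
        assert d.H == 1 and d.X.shape == (1, 1)
        v = vl.tabulate_predictions(records4["predicted"].tolist(), space4)
        np.testing.assert_array_equal(d.V[0], v.v)

    def test_continuous_gives_pattern_per_record(self, records4, space4):
        d = build_design(records4, [("bmi", "continuous")], space4)
        assert d.H == len(records4)

    def test_missing_values_rejected(self, records4, space4):
        records4.loc[0, "region"] = np.nan
        with pytest.raises(vl.ValidationError, match="missing"):
            build_design(records4, [("region", "categorical")], space4)


class TestSoftmax:
    def test_zero_coefficients_uniform(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        p = softmax_csmf(np.zeros((2, 2)), X)
        np.testing.assert_allclose(p, 1 / 3)

    def test_intercept_closed_form(self):
        beta = np.array([[np.log(2.0)]])  # C = 2, intercept only
        p = softmax_csmf(beta, np.ones((3, 1)))
        np.testing.assert_allclose(p, [[2 / 3, 1 / 3]] * 3)

    def test_reference_coding_not_shift_invariant(self):
        X = np.ones((1, 1))
        beta = np.array([[0.5, -0.3]])
        shifted = beta + 1.0  # reference class stays pinned at zero
        assert not np.allclose(softmax_csmf(beta, X), softmax_csmf(shifted, X))

    def test_rows_on_simplex(self, rng):
        X = np.column_stack([np.ones(10), rng.normal(size=10)])
        p = softmax_csmf(rng.normal(size=(2, 3)), X)
        np.testing.assert_allclose(p.sum(axis=1), 1.0)
        assert (p > 0).all()


class TestMarginalCsmf:
    def test_single_pattern_identity(self):
        p = np.array([[0.3, 0.7]])
        np.testing.assert_allclose(marginal_csmf(p, np.array([5.0])), p[0])

    def test_equal_weight_average(self):
        p = np.array([[1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_allclose(marginal_csmf(p, np.array([1.0, 1.0])), [0.5, 0.5])

    def test_weighted_mean(self):
        p = np.array([[0.8, 0.2], [0.4, 0.6]])
        np.testing.assert_allclose(marginal_csmf(p, np.array([3.0, 1.0])), [0.7, 0.3])

    def test_zero_total_weight_rejected(self):
        with pytest.raises(vl.ValidationError):
            marginal_csmf(np.array([[0.5, 0.5]]), np.array([0.0]))


class TestPolyaGamma:
    @pytest.mark.parametrize("b,c", [(1, 0.0), (1, 2.0), (10, -1.5), (200, 3.0)])
    def test_moments_match_closed_form(self, b, c, rng):
        x = random_polyagamma(rng, np.full(4000, b), np.full(4000, c))
        m, v = pg_mean(b, c), pg_var(b, c)
        assert x.mean() == pytest.approx(m, rel=0.05)
        assert x.var() == pytest.approx(v, rel=0.15)

    def test_zero_count_is_point_mass(self, rng):
        assert (random_polyagamma(rng, np.zeros(5), np.ones(5)) == 0).all()


class TestGibbsCovariate:
    def test_intercept_only_collapses_to_marginal_model(self, space2):
        rng = np.random.default_rng(31)
        names = np.asarray(space2.classes)
        p_true = np.array([0.65, 0.35])
        M = np.array([[0.8, 0.2], [0.3, 0.7]])
        g = rng.choice(2, p=p_true, size=2000)
        a = np.array([rng.choice(2, p=M[i]) for i in g])
        gl = rng.choice(2, p=[0.5, 0.5], size=300)
        al = np.array([rng.choice(2, p=M[i]) for i in gl])
        T = vl.tabulate_transfer(names[gl], names[al], space2)
        design = build_design(pd.DataFrame({"predicted": names[a]}), [], space2)
        ctl = vl.SamplerControl(n_chains=2, n_iter=2000, n_burnin=1000, seed=6)
        post = vl.gibbs_covariate(design, T, control=ctl)
        single = vl.gibbs_single(
            vl.tabulate_predictions(names[a].tolist(), space2), T, control=ctl
        )
        marg = post.marginal_csmf_draws()
        tol = max(3 * float(np.hypot(mc_se(marg).max(), mc_se(single.p).max())), 0.015)
        assert np.abs(marg.mean(axis=(0, 1)) - single.p_mean).max() < tol

    def test_sign_recovery_across_groups(self, space2):
        # two binary-covariate groups with opposite class balance; with a
        # near-perfect classifier the fitted p_h must separate them correctly
        rng = np.random.default_rng(8)
        names = np.asarray(space2.classes)
        n_per = 400
        g1 = rng.choice(2, p=[0.8, 0.2], size=n_per)
        g2 = rng.choice(2, p=[0.3, 0.7], size=n_per)
        df = pd.DataFrame(
            {
                "predicted": names[np.concatenate([g1, g2])],  # identity channel
                "grp": ["x"] * n_per + ["y"] * n_per,
            }
        )
        design = build_design(df, [("grp", "categorical")], space2)
        T = vl.TransferCounts(T=np.diag([500, 500]), space=space2)  # pins M ~ I
        ctl = vl.SamplerControl(n_chains=1, n_iter=1200, n_burnin=600, seed=9)
        post = vl.gibbs_covariate(design, T, control=ctl)
        p_h = post.pattern_csmf_draws().mean(axis=(0, 1))
        # pattern with grp indicator 0 is group x (reference level), 1 is group y
        x_row = int(np.flatnonzero(design.X[:, 1] == 0)[0])
        y_row = int(np.flatnonzero(design.X[:, 1] == 1)[0])
        assert p_h[x_row, 0] > 0.6 and p_h[y_row, 0] < 0.5

    def test_pattern_draws_on_simplex(self, records4, space4):
        design = build_design(records4, [("region", "categorical")], space4)
        T = vl.TransferCounts(T=np.diag([10] * 4), space=space4)
        ctl = vl.SamplerControl(n_chains=1, n_iter=120, n_burnin=60, seed=1)
        post = vl.gibbs_covariate(design, T, control=ctl)
        p_h = post.pattern_csmf_draws()
        np.testing.assert_allclose(p_h.sum(axis=-1), 1.0, atol=1e-9)
        np.testing.assert_allclose(
            post.marginal_csmf_draws().sum(axis=-1), 1.0, atol=1e-9
        )

    def test_tight_prior_dominates(self, space2, rng):
        # W0 -> 0 around zero forces beta -> 0, hence uniform p_h
        names = np.asarray(space2.classes)
        a = names[rng.integers(0, 2, size=300)]
        design = build_design(pd.DataFrame({"predicted": a}), [], space2)
        T = vl.TransferCounts(T=np.diag([20, 20]), space=space2)
        prior = CoefficientPrior(m0=np.zeros((1, 1)), W0=1e-8 * np.eye(1)[None])
        ctl = vl.SamplerControl(n_chains=1, n_iter=400, n_burnin=200, seed=12)
        post = vl.gibbs_covariate(design, T, prior=prior, control=ctl)
        np.testing.assert_allclose(post.marginal_csmf_mean, 0.5, atol=0.01)
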