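"""Core model: quadratic form B, Q_a, its moments and the moment estimator."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import hetvar
from hetvar import (
    MetaDataset,
    RandomEffectsMeta,
    WeightScheme,
    build_quadratic_core,
    compute_qa,
    qa_moments,
    tau2_moment_estimate,
    variance_coefficients,
)
from hetvar.exceptions import SingularDesignError
from hetvar.simulation import brockwell_gordon_variances

from conftest import random_meta_dataset, run_metafor


class TestBuildB:
    def test_two_study_equal_weights_by_hand(self):
        core = build_quadratic_core(np.ones((2, 1)), np.ones(2), np.ones(2))
        np.testing.assert_allclose(core.B, [[0.5, -0.5], [-0.5, 0.5]], atol=1e-14)
        assert core.trB == pytest.approx(1.0)

    def test_meta_analysis_shortcut_matrix(self, rng):
        # intercept-only B equals A - a a' / a_+
        a = rng.uniform(0.5, 5.0, 7)
        core = build_quadratic_core(np.ones((7, 1)), a, rng.uniform(0.1, 1, 7))
        shortcut = np.diag(a) - np.outer(a, a) / a.sum()
        np.testing.assert_allclose(core.B, shortcut, rtol=1e-12, atol=1e-14)

    def test_dersimonian_laird_denominator(self, rng):
        # with a_i = w_i = 1/sigma2_i, tr(B) is the classical DL denominator
        sigma2 = rng.uniform(0.05, 0.8, 10)
        w = 1.0 / sigma2
        core = build_quadratic_core(np.ones((10, 1)), w, sigma2)
        assert core.trB == pytest.approx(w.sum() - (w**2).sum() / w.sum(), rel=1e-12)

    @given(st.integers(0, 500), st.integers(1, 3), st.integers(4, 9))
    def test_projection_annihilates_design(self, seed, p, n):
        rng = np.random.default_rng(seed)
        _, sigma2, X = random_meta_dataset(rng, n=n, p=p)
        a = rng.uniform(0.2, 5.0, n)
        core = build_quadratic_core(X, a, sigma2)
        assert np.allclose(core.B, core.B.T)
        assert np.linalg.norm(core.B @ X) <= 1e-10 * np.linalg.norm(core.B) * np.linalg.norm(X)

    def test_rank_deficient_design_raises(self):
        X = np.column_stack([np.ones(5), np.ones(5)])
        with pytest.raises(SingularDesignError):
            build_quadratic_core(X, np.ones(5), np.ones(5))

    def test_nonpositive_weight_raises(self):
        with pytest.raises(ValueError):
            build_quadratic_core(np.ones((3, 1)), np.array([1.0, 0.0, 1.0]), np.ones(3))


class TestComputeQa:
    def test_antisymmetric_pair(self):
        data = MetaDataset(y=[1.0, -1.0], sigma2=[1.0, 1.0])
        q, beta, _ = compute_qa(data, WeightScheme([1.0, 1.0]))
        assert q == pytest.approx(2.0)
        assert beta[0] == pytest.approx(0.0)

    def test_homogeneous_data_gives_zero(self, rng):
        data = MetaDataset(y=np.full(6, 0.7), sigma2=rng.uniform(0.1, 1, 6))
        q, _, _ = compute_qa(data, WeightScheme(rng.uniform(0.5, 2, 6)))
        assert q == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_quadratic_form_equals_residual_sum(self, seed):
        # y'By against a brute-force weighted least squares refit
        rng = np.random.default_rng(seed)
        y, sigma2, X = random_meta_dataset(rng, n=6, p=2)
        a = rng.uniform(0.2, 4.0, 6)
        data = MetaDataset(y=y, sigma2=sigma2, X=X)
        q, _, _ = compute_qa(data, WeightScheme(a))
        core = build_quadratic_core(X, a, sigma2)
        assert q == pytest.approx(y @ core.B @ y, rel=1e-10)
        # independent WLS: normal equations solved directly
        beta = np.linalg.solve(X.T @ np.diag(a) @ X, X.T @ (a * y))
        assert q == pytest.approx(np.sum(a * (y - X @ beta) ** 2), rel=1e-10)


class TestMoments:
    def test_two_study_chisquare_case(self):
        core = build_quadratic_core(np.ones((2, 1)), np.ones(2), np.ones(2))
        mean, var = qa_moments(core, 0.0)
        assert (mean, var) == (pytest.approx(1.0), pytest.approx(2.0))

    def test_variance_constant_term(self, rng):
        _, sigma2, X = random_meta_dataset(rng, n=7, p=2)
        core = build_quadratic_core(X, rng.uniform(0.5, 3, 7), sigma2)
        _, var0 = qa_moments(core, 0.0)
        assert var0 == pytest.approx(2.0 * core.trBDBD, rel=1e-12)

    def test_moments_match_monte_carlo(self, rng):
        # Q = Z' B Z with Z ~ N(0, Sigma): simulate and compare both moments
        tau2 = 0.3
        _, sigma2, X = random_meta_dataset(rng, n=6, p=1)
        a = rng.uniform(0.5, 3, 6)
        core = build_quadratic_core(X, a, sigma2)
        mean, var = qa_moments(core, tau2)
        R = 200_000
        Z = rng.standard_normal((R, 6)) * np.sqrt(sigma2 + tau2)
        Q = np.einsum("ri,ij,rj->r", Z, core.B, Z)
        assert abs(Q.mean() - mean) < 3 * Q.std() / np.sqrt(R)
        m2 = Q.var()
        se_var = np.sqrt((np.mean((Q - Q.mean()) ** 4) - m2**2) / R)
        assert abs(m2 - var) < 3 * se_var


class TestVarianceCoefficients:
    def test_two_study_equal_variance_case(self):
        core = build_quadratic_core(np.ones((2, 1)), np.ones(2), np.ones(2))
        c = variance_coefficients(core)
        assert (c.C0, c.C1, c.C2) == (pytest.approx(2.0), pytest.approx(4.0), pytest.approx(2.0))
        assert c.disc == 0.0

    def test_common_variance_discriminant_vanishes(self, rng):
        # Delta = s I makes C1^2 = 4 C0 C2 exactly
        s = 0.37
        X = np.column_stack([np.ones(6), rng.standard_normal(6)])
        core = build_quadratic_core(X, rng.uniform(0.5, 2, 6), np.full(6, s))
        c = variance_coefficients(core)
        assert c.disc == 0.0
        assert c.C1**2 == pytest.approx(4 * c.C0 * c.C2, rel=1e-9)

    def test_brockwell_gordon_discriminant_strictly_negative(self):
        sigma2 = brockwell_gordon_variances(5)
        core = build_quadratic_core(np.ones((5, 1)), 1 / sigma2, sigma2)
        c = variance_coefficients(core)
        assert c.disc < -1e-4 * 4 * c.C0 * c.C2

    @given(st.integers(0, 300))
    def test_discriminant_never_positive(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        _, sigma2, X = random_meta_dataset(rng, n=n, p=1)
        core = build_quadratic_core(X, rng.uniform(0.1, 10, n), sigma2)
        assert variance_coefficients(core).disc <= 0.0


class TestTauEstimate:
    def test_estimating_equation_root(self, rng):
        _, sigma2, X = random_meta_dataset(rng, n=5)
        core = build_quadratic_core(X, 1 / sigma2, sigma2)
        est = tau2_moment_estimate(core.trBD, core)
        assert est.tau2_untruncated == pytest.approx(0.0, abs=1e-12)
        assert est.tau2 == 0.0

    def test_two_study_example(self):
        core = build_quadratic_core(np.ones((2, 1)), np.ones(2), np.ones(2))
        assert tau2_moment_estimate(2.0, core).tau2 == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_textbook_dersimonian_laird(self, seed):
        rng = np.random.default_rng(seed)
        y, sigma2, _ = random_meta_dataset(rng, n=9, tau2=0.2)
        res = RandomEffectsMeta(y, sigma2).fit()
        # textbook formula, coded independently
        w = 1 / sigma2
        q = np.sum(w * (y - np.sum(w * y) / w.sum()) ** 2)
        dl = max((q - (len(y) - 1)) / (w.sum() - (w**2).sum() / w.sum()), 0.0)
        assert res.tau2 == pytest.approx(dl, rel=1e-12, abs=1e-15)

    def test_matches_metafor_dl(self):
        y = [0.3, -0.2, 0.6, 0.1, -0.4]
        v = [0.04, 0.09, 0.05, 0.12, 0.07]
        oracle = run_metafor(y, v, method="DL")
        res = RandomEffectsMeta(y, v).fit()
        assert res.tau2 == pytest.approx(oracle["tau2"], rel=1e-6)

    def test_moment_estimator_is_unbiased(self, rng):
        # mean of the untruncated estimate over 100k model draws ~ tau2
        tau2 = 0.15
        sigma2 = brockwell_gordon_variances(8)
        core = build_quadratic_core(np.ones((8, 1)), 1 / sigma2, sigma2)
        R = 100_000
        Y = rng.standard_normal((R, 8)) * np.sqrt(sigma2 + tau2)
        q = np.einsum("ri,ij,rj->r", Y, core.B, Y)
        t = (q - core.trBD) / core.trB
        assert abs(t.mean() - tau2) < 3 * t.std() / np.sqrt(R)


class TestModelFrontEnd:
    def test_from_dataframe_and_summary(self):
        import pandas as pd

        df = pd.DataFrame(
            {"estimate": [0.1, 0.5, -0.2, 0.3], "se": [0.2, 0.3, 0.25, 0.4],
             "dose": [1.0, 2.0, 1.5, 3.0]}
        )
        m = RandomEffectsMeta.from_dataframe(df, covariates=["dose"])
        assert m.data.p == 2
        res = m.fit()
        text = res.summary(methods=("vst",))
        assert "meta-regression" in text and "tau2" in text

    def test_input_validation(self):
        with pytest.raises(ValueError):
            MetaDataset(y=[1.0, 2.0], sigma2=[1.0, -1.0])
        with pytest.raises(ValueError):
            MetaDataset(y=[1.0], sigma2=[1.0])  # n <= p
        with pytest.raises(ValueError):
            RandomEffectsMeta([1, 2, 3], [1, 1, 1], weights="nonsense")
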