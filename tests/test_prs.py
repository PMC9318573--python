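"""PRS weight construction and the truncated-R^(-1/2) LD adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from twasprs import (GwasSummary, adjust_genotypes, build_weights,
                     compute_prs, ld_inverse_sqrt, sample_correlation,
                     t_from_pvalue)
from twasprs.data import GenotypeMatrix


class TestTFromPvalue:
    @pytest.mark.parametrize("p, sign, expected, tol", [
        (1.0, +1, 0.0, 1e-12),
        (0.3173, -1, -1.0, 5e-4),        # Phi(1) - Phi(-1) ~ 0.6827
        (0.05, +1, 1.95996, 1e-5),
    ])
    def test_known_quantiles(self, p, sign, expected, tol):
        assert t_from_pvalue(p, sign) == pytest.approx(expected, abs=tol)

    def test_matches_numeric_quantile_oracle(self):
        # independent oracle: bisection on 2(1 - Phi(t)) = p
        from scipy.optimize import brentq
        for p in (0.3173, 0.05, 0.5, 1e-4):
            t_oracle = brentq(lambda t: 2 * stats.norm.sf(t) - p, 0, 40)
            assert t_from_pvalue(p, +1) == pytest.approx(t_oracle, abs=1e-9)

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.0001, 2.0])
    def test_domain_errors(self, p):
        with pytest.raises(ValueError):
            t_from_pvalue(p, +1)

    @given(t=st.floats(-8, 8), negate=st.booleans())
    @settings(max_examples=100, deadline=None)
    def test_roundtrip_through_pvalue(self, t, negate):
        t = -t if negate else t
        p = min(2 * stats.norm.sf(abs(t)), 1.0)
        sign = 1.0 if t >= 0 else -1.0
        assert t_from_pvalue(p, sign) == pytest.approx(t, abs=1e-8)


class TestBuildWeights:
    def test_scheme_q_signed_square(self):
        s = GwasSummary(["a", "b", "c"], beta_hat=[0.1, -0.05, 0.0],
                        t_stat=[2.0, -1.0, 0.0])
        assert build_weights(s, "Q").w == pytest.approx([4.0, -1.0, 0.0])

    def test_scheme_b_is_identity_on_beta(self):
        s = GwasSummary(["a", "b"], beta_hat=[0.3, -0.1], t_stat=[1.0, -0.5])
        assert build_weights(s, "B").w == pytest.approx([0.3, -0.1])

    def test_scheme_t_from_pvalues_only(self):
        s = GwasSummary(["a", "b"], beta_hat=[0.2, -0.2],
                        p_value=[0.05, 0.5])
        assert build_weights(s, "T").w == pytest.approx([1.95996, -0.67449],
                                                        abs=1e-5)

    def test_missing_statistic_names_snp(self):
        s = GwasSummary(["rsA", "rsB"], beta_hat=[0.1, 0.2],
                        t_stat=[1.0, np.nan])
        with pytest.raises(ValueError, match="rsB"):
            build_weights(s, "T")

    def test_t_and_q_share_rank_order_of_magnitude(self, rng):
        t = rng.normal(size=30)
        s = GwasSummary([f"s{i}" for i in range(30)], beta_hat=t, t_stat=t)
        wt = np.abs(build_weights(s, "T").w)
        wq = np.abs(build_weights(s, "Q").w)
        assert (np.argsort(wt) == np.argsort(wq)).all()

    def test_q_sign_pattern_matches_t(self, rng):
        t = rng.normal(size=20)
        s = GwasSummary([f"s{i}" for i in range(20)], beta_hat=t, t_stat=t)
        assert (np.sign(build_weights(s, "Q").w)
                == np.sign(build_weights(s, "T").w)).all()


class TestGwasSummaryInvariants:
    def test_rejects_pvalues_outside_unit_interval(self):
        with pytest.raises(ValueError):
            GwasSummary(["a"], beta_hat=[0.1], p_value=[0.0])

    def test_rejects_sign_mismatch(self):
        with pytest.raises(ValueError, match="sign"):
            GwasSummary(["a"], beta_hat=[0.5], t_stat=[-2.0])

    def test_rejects_inconsistent_p_and_t(self):
        with pytest.raises(ValueError, match="inconsistent"):
            GwasSummary(["a"], beta_hat=[0.5], t_stat=[2.0], p_value=[0.5])


class TestSampleCorrelation:
    def test_duplicated_columns_fully_correlated(self, rng):
        x = rng.integers(0, 3, size=200).astype(float)
        r = sample_correlation(np.column_stack([x, x]))
        assert r[0, 1] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 3, size=(10000, 6)).astype(float)
        r = sample_correlation(x)
        off = r[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.05          # 1.96 / sqrt(n) bound

    def test_single_snp_gene(self, rng):
        x = rng.integers(0, 3, size=(50, 1)).astype(float)
        assert sample_correlation(x) == pytest.approx(np.array([[1.0]]))

    def test_zero_variance_column_names_snp(self):
        g = GenotypeMatrix(np.array([[1.0, 0.0], [1.0, 2.0]]),
                           ["mono", "poly"], ["i1", "i2"])
        with pytest.raises(ValueError, match="mono"):
            sample_correlation(g)


class TestLdInverseSqrt:
    def test_identity_matrix(self):
        t = ld_inverse_sqrt(np.eye(3))
        assert t.retained == 3
        assert t.inv_sqrt == pytest.approx(np.eye(3), abs=1e-12)

    def test_2x2_closed_form(self):
        rho = 0.5
        r = np.array([[1.0, rho], [rho, 1.0]])
        a = 0.5 * (1 / np.sqrt(1 + rho) + 1 / np.sqrt(1 - rho))
        b = 0.5 * (1 / np.sqrt(1 + rho) - 1 / np.sqrt(1 - rho))
        expected = np.array([[a, b], [b, a]])
        t = ld_inverse_sqrt(r)
        assert t.retained == 2
        assert t.inv_sqrt == pytest.approx(expected, abs=1e-12)

    def test_small_trailing_eigenvalue_truncated(self):
        # spectrum (1.999, 0.001): trailing share 5e-4 < 0.1% -> L = 1
        e = np.array([[1.0, 1.0], [1.0, -1.0]]) / np.sqrt(2)
        lam = np.array([1.999, 0.001])
        r = (e * lam) @ e.T
        t = ld_inverse_sqrt(r)
        # direct cumulative-sum oracle
        cum = np.cumsum(sorted(lam, reverse=True))
        l_oracle = int(np.argmax(cum / cum[-1] >= 0.999)) + 1
        assert t.retained == l_oracle == 1
        expected = np.outer(e[:, 0], e[:, 0]) / np.sqrt(lam[0])
        assert t.inv_sqrt == pytest.approx(expected, abs=1e-12)

    def test_full_retention_inverts_r(self, small_geno):
        r = sample_correlation(small_geno)
        t = ld_inverse_sqrt(r, cum_threshold=1.0)
        assert t.retained == r.shape[0]
        assert t.inv_sqrt @ r @ t.inv_sqrt == pytest.approx(np.eye(r.shape[0]),
                                                            abs=1e-8)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            ld_inverse_sqrt(np.array([[1.0, 0.5], [0.2, 1.0]]))

    def test_negative_eigenvalue_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ld_inverse_sqrt(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestAdjustGenotypes:
    def test_identity_transform_returns_standardized(self, rng):
        x = rng.integers(0, 3, size=(100, 4)).astype(float)
        t = ld_inverse_sqrt(np.eye(4))
        z = (x - x.mean(0)) / x.std(0)
        assert adjust_genotypes(x, t) == pytest.approx(z)

    def test_whitening_makes_columns_uncorrelated(self, small_geno):
        r = sample_correlation(small_geno)
        t = ld_inverse_sqrt(r, cum_threshold=1.0)
        adj = adjust_genotypes(small_geno, t)
        cov = adj.T @ adj / adj.shape[0]
        assert cov == pytest.approx(np.eye(adj.shape[1]), abs=1e-6)

    def test_duplicate_snps_truncated_and_downweighted(self):
        # rho -> 1 pair: the zero eigenpair is truncated, leaving the two
        # adjusted columns identical and each with less variance than an
        # uncorrelated SNP (which full whitening would bring to variance 1)
        rng = np.random.default_rng(3)
        base = rng.integers(0, 3, size=2000).astype(float)
        indep = rng.integers(0, 3, size=2000).astype(float)
        x = np.column_stack([base, base, indep])
        t = ld_inverse_sqrt(sample_correlation(x))
        assert t.retained < 3
        adj = adjust_genotypes(x, t)
        assert adj[:, 0] == pytest.approx(adj[:, 1], abs=1e-10)
        assert adj[:, 0].var() < adj[:, 2].var()

    def test_dimension_mismatch(self, rng):
        t = ld_inverse_sqrt(np.eye(3))
        with pytest.raises(ValueError):
            adjust_genotypes(rng.random((10, 4)), t)


class TestComputePrs:
    def test_zero_weights_zero_scores(self, rng):
        assert compute_prs(rng.random((7, 3)), np.zeros(3)) == pytest.approx(0)

    def test_unit_weight_selects_column(self, rng):
        adj = rng.random((9, 4))
        w = np.array([0.0, 0.0, 1.0, 0.0])
        assert compute_prs(adj, w) == pytest.approx(adj[:, 2])

    def test_matches_double_loop_oracle(self, rng):
        adj = rng.normal(size=(5, 4))
        w = rng.normal(size=4)
        oracle = [sum(w[m] * adj[i, m] for m in range(4)) for i in range(5)]
        assert compute_prs(adj, w) == pytest.approx(oracle)

    @given(scale=st.floats(-5, 5, allow_nan=False))
    @settings(max_examples=30, deadline=None)
    def test_linearity_in_weights(self, scale):
        rng = np.random.default_rng(0)
        adj = rng.normal(size=(6, 3))
        w = rng.normal(size=3)
        assert compute_prs(adj, scale * w) == pytest.approx(
            scale * compute_prs(adj, w), abs=1e-9)

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            compute_prs(rng.random((5, 3)), np.ones(4))


def test_adjusted_prs_reduces_to_standardized_prs_without_ld(rng):
    """With R = I the LD-adjusted PRS equals the plain standardized PRS."""
    x = rng.integers(0, 3, size=(80, 5)).astype(float)
    w = rng.normal(size=5)
    t = ld_inverse_sqrt(np.eye(5))
    z = (x - x.mean(0)) / x.std(0)
    assert compute_prs(adjust_genotypes(x, t), w) == pytest.approx(z @ w)


def test_pipeline_is_deterministic(small_geno):
    r1 = sample_correlation(small_geno)
    r2 = sample_correlation(small_geno)
    assert (r1 == r2).all()
    t1, t2 = ld_inverse_sqrt(r1), ld_inverse_sqrt(r2)
    assert (t1.inv_sqrt == t2.inv_sqrt).all()
    a1 = adjust_genotypes(small_geno, t1)
    a2 = adjust_genotypes(small_geno, t2)
    assert (a1 == a2).all()
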