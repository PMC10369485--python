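"""Clumping, scoring, PRS-PCA, ancestry PCs, standardization, residualization."""

import numpy as np
import pandas as pd
import pytest

from triopgs import prs
from triopgs.cohort import MISSING


def brute_force_clump(pvals, pos, G, r2_thr, window):
    """Independent greedy oracle: plain loops, np.corrcoef pair by pair."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: (pvals[i], str(i)))
    removed, retained = set(), []
    for i in order:
        if i in removed:
            continue
        retained.append(i)
        for j in range(n):
            if j == i or j in removed or j in retained:
                continue
            if abs(pos[j] - pos[i]) > window:
                continue
            gi, gj = G[:, i], G[:, j]
            if gi.std() == 0 or gj.std() == 0:
                r2 = 0.0
            else:
                r2 = np.corrcoef(gi, gj)[0, 1] ** 2
            if r2 > r2_thr:
                removed.add(j)
    return sorted(retained)


def _aligned(pvals, pos, ids=None):
    n = len(pvals)
    return pd.DataFrame(
        {
            "id": ids or [f"v{i}" for i in range(n)],
            "chrom": "1",
            "pos": pos,
            "beta": np.ones(n),
            "p": pvals,
        }
    )


class TestClump:
    def test_single_clump_keeps_most_significant(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 3, 200)
        G = np.column_stack([base, base, base]).astype(float)
        out = prs.clump(_aligned([0.001, 0.01, 0.05], [100, 200, 300]), G,
                        r2_threshold=0.1, window_kb=1.0)
        assert out == [0]

    def test_uncorrelated_variants_all_retained(self):
        rng = np.random.default_rng(1)
        G = rng.integers(0, 3, size=(500, 4)).astype(float)
        out = prs.clump(_aligned([0.04, 0.01, 0.03, 0.02], [1, 2, 3, 4]), G,
                        r2_threshold=0.5, window_kb=1.0)
        assert out == [0, 1, 2, 3]

    def test_chain_structure(self):
        """A-B correlated, B-C correlated, A-C not; p(A)<p(B)<p(C) -> {A, C}."""
        rng = np.random.default_rng(2)
        n = 4000
        a = rng.integers(0, 2, n)
        c = rng.integers(0, 2, n)
        b = np.where(rng.random(n) < 0.5, a, c)  # r2(a,b),r2(b,c) ~ 0.25
        G = np.column_stack([a, b, c]).astype(float)
        out = prs.clump(_aligned([0.001, 0.01, 0.05], [100, 200, 300]), G,
                        r2_threshold=0.15, window_kb=1.0)
        assert out == [0, 2]

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(3)
        for rep in range(10):
            n = 60
            pos = np.sort(rng.choice(100_000, size=n, replace=False))
            blocks = np.repeat(np.arange(10), 6)
            latent = rng.normal(size=(80, 10))
            G = (latent[:, blocks] + 0.8 * rng.normal(size=(80, n)) > 0).astype(float)
            pvals = rng.uniform(0, 1, n)
            aligned = _aligned(pvals, pos)
            mine = prs.clump(aligned, G, r2_threshold=0.2, window_kb=20.0)
            oracle = brute_force_clump(pvals, pos, G, 0.2, 20_000.0)
            assert mine == oracle

    def test_retained_set_r2_sparse(self):
        rng = np.random.default_rng(4)
        n = 100
        pos = np.arange(n) * 500
        blocks = np.repeat(np.arange(10), 10)
        latent = rng.normal(size=(200, 10))
        G = (latent[:, blocks] + 0.6 * rng.normal(size=(200, n)) > 0.2).astype(float)
        pvals = rng.uniform(0, 1, n)
        kept = prs.clump(_aligned(pvals, pos), G, r2_threshold=0.2, window_kb=5.0)
        Gz = (G - G.mean(0)) / G.std(0)
        for i in kept:
            for j in kept:
                if i < j and abs(pos[i] - pos[j]) <= 5000:
                    r2 = (Gz[:, i] @ Gz[:, j] / len(G)) ** 2
                    assert r2 <= 0.2 + 1e-12


class TestScoreAtThresholds:
    def test_single_variant_score(self):
        aligned = _aligned([0.01], [100])
        aligned["beta"] = [0.5]
        out = prs.score_at_thresholds(np.array([[2]]), aligned, [0.05])
        assert out.iloc[0, 0] == pytest.approx(1.0)

    def test_missing_dosage_imputed_2af_beta(self):
        aligned = _aligned([0.01], [100])
        aligned["beta"] = [0.5]
        out = prs.score_at_thresholds(
            np.array([[MISSING]]), aligned, [0.05], control_af=np.array([0.25])
        )
        assert out.iloc[0, 0] == pytest.approx(2 * 0.25 * 0.5)

    def test_threshold_one_sums_all_retained(self):
        rng = np.random.default_rng(5)
        aligned = _aligned(rng.uniform(0, 1, 30), np.arange(30))
        aligned["beta"] = rng.normal(size=30)
        G = rng.integers(0, 3, size=(10, 30)).astype(float)
        out = prs.score_at_thresholds(G, aligned, [1.0])
        expected = G @ aligned["beta"].to_numpy()
        np.testing.assert_allclose(out.iloc[:, 0], expected)

    def test_empty_threshold_warns_zero_column(self):
        aligned = _aligned([0.5], [100])
        with pytest.warns(UserWarning, match="no retained variants"):
            out = prs.score_at_thresholds(np.array([[1.0]]), aligned, [1e-8])
        assert out.iloc[0, 0] == 0.0


class TestPrsPca:
    def test_identical_columns_give_standardized_column(self):
        rng = np.random.default_rng(6)
        col = rng.normal(size=50)
        mat = pd.DataFrame({f"p_{i}": col for i in range(7)})
        res = prs.prs_pca(mat)
        z = (col - col.mean()) / col.std(ddof=1)
        np.testing.assert_allclose(res.scores / np.sqrt(7), z, atol=1e-10)
        assert res.explained_variance_ratio == pytest.approx(1.0)

    def test_negation_symmetry(self):
        rng = np.random.default_rng(7)
        mat = pd.DataFrame(rng.normal(size=(40, 5)) + rng.normal(size=(40, 1)))
        a = prs.prs_pca(mat).scores
        b = prs.prs_pca(-mat).scores
        np.testing.assert_allclose(a.to_numpy(), -b.to_numpy(), atol=1e-10)

    def test_matches_dense_eigendecomposition(self):
        """PC1 agrees with a brute-force eigendecomposition of the
        correlation matrix of the threshold scores."""
        rng = np.random.default_rng(8)
        mat = pd.DataFrame(
            rng.normal(size=(100, 7)) + 0.5 * rng.normal(size=(100, 1))
        )
        res = prs.prs_pca(mat)
        X = mat.to_numpy()
        Xz = (X - X.mean(0)) / X.std(0, ddof=1)
        C = Xz.T @ Xz / (len(X) - 1)
        vals, vecs = np.linalg.eigh(C)
        v1 = vecs[:, -1]
        oracle = Xz @ v1
        if np.corrcoef(oracle, Xz.mean(1))[0, 1] < 0:
            oracle = -oracle
        r = np.corrcoef(res.scores, oracle)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_column_dropped(self):
        rng = np.random.default_rng(9)
        mat = pd.DataFrame({"a": rng.normal(size=30), "b": np.zeros(30)})
        with pytest.warns(UserWarning, match="zero-variance"):
            res = prs.prs_pca(mat)
        assert res.dropped_columns == ["b"]
        with pytest.raises(ValueError):
            prs.prs_pca(pd.DataFrame({"a": np.zeros(30)}))


class TestAncestryPcs:
    def test_two_subpopulations_separated(self):
        rng = np.random.default_rng(10)
        n, m = 120, 300
        af1 = rng.uniform(0.1, 0.5, m)
        af2 = np.clip(af1 + rng.normal(0, 0.12, m), 0.02, 0.98)
        g1 = rng.binomial(2, af1, size=(n // 2, m))
        g2 = rng.binomial(2, af2, size=(n // 2, m))
        G = np.vstack([g1, g2])
        pcs = prs.ancestry_pcs(G, np.arange(n), n_components=5)
        label = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        r = abs(np.corrcoef(pcs["PC1"], label)[0, 1])
        assert r > 0.9

    def test_homogeneous_population_no_separation(self):
        rng = np.random.default_rng(11)
        G = rng.binomial(2, 0.3, size=(100, 200))
        pcs = prs.ancestry_pcs(G, np.arange(100), n_components=3)
        label = rng.integers(0, 2, 100)
        for c in pcs.columns:
            assert abs(np.corrcoef(pcs[c], label)[0, 1]) < 0.35

    def test_duplicated_sample_identical_coordinates(self):
        rng = np.random.default_rng(12)
        G = rng.binomial(2, 0.3, size=(50, 100))
        G = np.vstack([G, G[:1]])
        pcs = prs.ancestry_pcs(G, np.arange(50), n_components=4)
        np.testing.assert_allclose(pcs.iloc[0], pcs.iloc[-1], atol=1e-10)

    def test_few_founders_reduces_components(self):
        rng = np.random.default_rng(13)
        G = rng.binomial(2, 0.3, size=(8, 50))
        with pytest.warns(UserWarning, match="few founders"):
            pcs = prs.ancestry_pcs(G, np.arange(8), n_components=10)
        assert pcs.shape[1] == 7


class TestStandardize:
    def test_control_subset_mean0_sd1(self):
        rng = np.random.default_rng(14)
        s = pd.Series(rng.normal(2, 3, 100), index=[f"s{i}" for i in range(100)])
        ctrl = [f"s{i}" for i in range(50)]
        out = prs.standardize(s, ctrl)
        assert out.loc[ctrl].mean() == pytest.approx(0.0, abs=1e-9)
        assert out.loc[ctrl].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_case_at_control_mean_is_zero(self):
        s = pd.Series([1.0, 3.0, 2.0], index=["c1", "c2", "x"])
        out = prs.standardize(s, ["c1", "c2"])
        assert out["x"] == pytest.approx(0.0)

    def test_affine_equivariance_and_rank_preservation(self):
        rng = np.random.default_rng(15)
        s = pd.Series(rng.normal(size=60), index=[f"s{i}" for i in range(60)])
        ctrl = list(s.index[:30])
        a = prs.standardize(s, ctrl)
        b = prs.standardize(3.0 * s + 7.0, ctrl)
        np.testing.assert_allclose(a, b, atol=1e-9)
        assert (a.rank() == s.rank()).all()

    def test_zero_control_sd_errors(self):
        s = pd.Series([1.0, 1.0, 5.0], index=["c1", "c2", "x"])
        with pytest.raises(ValueError, match="zero control SD"):
            prs.standardize(s, ["c1", "c2"])


class TestResidualize:
    def test_orthogonal_covariates_center_only(self):
        rng = np.random.default_rng(16)
        y = pd.Series(rng.normal(size=200))
        x = rng.normal(size=200)
        x = x - x.mean()
        yc = y - y.mean()
        x = x - (x @ yc) / (yc @ yc) * yc  # orthogonalize to the score
        out = prs.residualize(y, pd.DataFrame({"x": x}))
        np.testing.assert_allclose(out, y - y.mean(), atol=1e-9)

    def test_exactly_linear_score_residuals_zero(self):
        x = np.linspace(-2, 2, 50)
        y = pd.Series(3.0 * x + 1.0)
        out = prs.residualize(y, pd.DataFrame({"PC1": x}))
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(80, 4))
        y = pd.Series(rng.normal(size=80))
        out = prs.residualize(y, pd.DataFrame(X))
        Xi = np.column_stack([np.ones(80), X])
        beta = np.linalg.solve(Xi.T @ Xi, Xi.T @ y.to_numpy())
        np.testing.assert_allclose(out, y.to_numpy() - Xi @ beta, atol=1e-8)

    def test_collinear_covariates_warn(self):
        rng = np.random.default_rng(18)
        x = rng.normal(size=50)
        y = pd.Series(rng.normal(size=50))
        with pytest.warns(UserWarning, match="rank-deficient"):
            out = prs.residualize(y, pd.DataFrame({"a": x, "b": 2 * x}))
        ref = prs.residualize(y, pd.DataFrame({"a": x}))
        np.testing.assert_allclose(out, ref, atol=1e-8)
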