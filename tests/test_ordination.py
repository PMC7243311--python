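"""PCA, top contributors, envfit-style trait fitting, RDA fraction, Procrustes."""

import numpy as np
import pandas as pd
import pytest

from phyllomatch import (
    fit_traits,
    pca,
    procrustes,
    top_contributors,
    variance_explained_by_traits,
)


def make_matrix(seed=0, n=10, p=6):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.random((n, p)),
        index=[f"s{i}" for i in range(n)],
        columns=[f"f{j}" for j in range(p)],
    )


class TestPCA:
    def test_rank_one_data_single_axis(self):
        v = np.array([1.0, 3.0, 2.0, 5.0])
        m = pd.DataFrame({"a": v, "b": 2 * v})
        ordn = pca(m)
        assert ordn.pct_variance[0] == pytest.approx(100.0, abs=1e-8)

    def test_trace_conserved_and_invariants(self):
        m = make_matrix()
        ordn = pca(m)
        # scaled data has unit column variances: eigenvalue sum = n columns
        assert ordn.eigenvalues.sum() == pytest.approx(m.shape[1], abs=1e-8)
        assert (np.diff(ordn.eigenvalues) <= 1e-12).all()
        assert np.allclose(ordn.contributions.sum(axis=0), 100.0, atol=1e-8)
        G = ordn.scores.to_numpy().T @ ordn.scores.to_numpy()
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_matches_eigendecomposition_oracle(self):
        m = make_matrix(seed=5)
        ordn = pca(m)
        # independent oracle: dense eigendecomposition of the correlation matrix
        R = np.corrcoef(m.to_numpy(), rowvar=False)
        evals = np.sort(np.linalg.eigvalsh(R))[::-1]
        n_axes = len(ordn.eigenvalues)
        np.testing.assert_allclose(ordn.eigenvalues, evals[:n_axes], atol=1e-8)
        # scores reproduce the standardized data (full rank)
        X = m.to_numpy()
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        recon = ordn.scores.to_numpy() @ ordn.loadings.to_numpy().T
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_zero_variance_column_rejected(self):
        m = make_matrix()
        m["const"] = 1.0
        with pytest.raises(ValueError, match="const"):
            pca(m)


class TestTopContributors:
    def test_axis_concentration_ranks_first(self):
        v = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        rng = np.random.default_rng(2)
        m = pd.DataFrame({"sig": v * 10, "n1": rng.random(5), "n2": rng.random(5)})
        ordn = pca(m, scale_unit=False)
        assert top_contributors(ordn, k=1, axes=(1,)).index[0] == "sig"

    def test_full_ranking_is_permutation(self):
        m = make_matrix()
        ordn = pca(m)
        ranked = top_contributors(ordn, k=m.shape[1])
        assert sorted(ranked.index) == sorted(m.columns)

    def test_matches_loading_square_formula(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        m = pd.DataFrame({"a": 0.9 * v, "b": 0.3 * v, "c": 0.1 * v})
        ordn = pca(m, scale_unit=False)
        load = ordn.loadings["PC1"].to_numpy()
        manual = 100 * load**2 / (load**2).sum()
        ranked = top_contributors(ordn, k=3, axes=(1,))
        assert list(ranked.index) == ["a", "b", "c"]
        np.testing.assert_allclose(
            ranked["contribution"].to_numpy(), np.sort(manual)[::-1], atol=1e-10
        )

    def test_k_exceeding_warns(self):
        ordn = pca(make_matrix())
        with pytest.warns(UserWarning, match="returning all"):
            out = top_contributors(ordn, k=99)
        assert len(out) == 6


class TestFitTraits:
    def test_self_fit_axis1(self):
        ordn = pca(make_matrix(seed=1))
        traits = pd.DataFrame({"t": ordn.scores["PC1"]})
        (fit,) = fit_traits(ordn, traits, n_perm=99, seed=0)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(np.abs(fit.direction), [1.0, 0.0], atol=1e-8)

    def test_r_squared_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        ordn = pca(make_matrix(seed=3, n=12))
        y = rng.random(12)
        traits = pd.DataFrame({"t": y}, index=ordn.scores.index)
        (fit,) = fit_traits(ordn, traits, n_perm=9, seed=0)
        S = ordn.scores[["PC1", "PC2"]].to_numpy()
        X = np.column_stack([np.ones(12), S])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2_oracle = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert fit.r_squared == pytest.approx(r2_oracle, abs=1e-10)

    def test_r_squared_affine_invariant(self):
        ordn = pca(make_matrix(seed=4))
        rng = np.random.default_rng(0)
        y = rng.random(10)
        t1 = pd.DataFrame({"t": y}, index=ordn.scores.index)
        t2 = pd.DataFrame({"t": 5.0 * y - 3.0}, index=ordn.scores.index)
        (f1,) = fit_traits(ordn, t1, n_perm=9, seed=0)
        (f2,) = fit_traits(ordn, t2, n_perm=9, seed=0)
        assert f1.r_squared == pytest.approx(f2.r_squared, abs=1e-12)

    def test_constant_trait_skipped_others_fitted(self):
        ordn = pca(make_matrix(seed=1))
        rng = np.random.default_rng(1)
        traits = pd.DataFrame(
            {"const": np.ones(10), "ok": rng.random(10)}, index=ordn.scores.index
        )
        with pytest.warns(UserWarning, match="const"):
            fits = fit_traits(ordn, traits, n_perm=9, seed=0)
        assert [f.trait_id for f in fits] == ["ok"]

    def test_p_value_lower_bound_and_determinism(self):
        ordn = pca(make_matrix(seed=2))
        rng = np.random.default_rng(9)
        traits = pd.DataFrame({"t": rng.random(10)}, index=ordn.scores.index)
        (f1,) = fit_traits(ordn, traits, n_perm=99, seed=5)
        (f2,) = fit_traits(ordn, traits, n_perm=99, seed=5)
        assert f1.p_value == f2.p_value >= 1 / 100


class TestVarianceExplained:
    def test_full_span_gives_one(self):
        m = make_matrix(seed=6, n=12, p=4)
        ordn = pca(m)
        traits = ordn.scores.copy()  # spans the response completely
        tv = variance_explained_by_traits(m, traits)
        assert tv.raw == pytest.approx(1.0, abs=1e-10)

    def test_zero_traits_gives_zero(self):
        m = make_matrix(seed=6, n=12, p=4)
        tv = variance_explained_by_traits(m, pd.DataFrame(index=m.index))
        assert tv.raw == 0.0

    def test_matches_weighted_per_column_regression_oracle(self):
        rng = np.random.default_rng(11)
        m = make_matrix(seed=8, n=12, p=5)
        traits = pd.DataFrame(
            {"t1": rng.random(12), "t2": rng.random(12)}, index=m.index
        )
        tv = variance_explained_by_traits(m, traits, scale_unit=True)
        # oracle: per-column OLS R^2 weighted by column variance of the
        # standardized response (all equal after scaling -> plain mean)
        Y = m.to_numpy()
        Y = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        X = np.column_stack([np.ones(12), traits.to_numpy()])
        r2s, weights = [], []
        for j in range(Y.shape[1]):
            beta, *_ = np.linalg.lstsq(X, Y[:, j], rcond=None)
            resid = Y[:, j] - X @ beta
            sst = Y[:, j] @ Y[:, j]
            r2s.append(1 - resid @ resid / sst)
            weights.append(sst)
        oracle = np.average(r2s, weights=weights)
        assert tv.raw == pytest.approx(oracle, abs=1e-10)

    def test_collinear_traits_dropped_with_warning(self):
        rng = np.random.default_rng(12)
        m = make_matrix(seed=9, n=12, p=4)
        t1 = rng.random(12)
        traits = pd.DataFrame({"t1": t1, "t2": 2 * t1}, index=m.index)
        with pytest.warns(UserWarning, match="collinear"):
            tv = variance_explained_by_traits(m, traits)
        assert len(tv.traits_used) == 1

    def test_too_few_samples_error(self):
        m = make_matrix(seed=9, n=4, p=3)
        rng = np.random.default_rng(0)
        traits = pd.DataFrame(rng.random((4, 3)), index=m.index, columns=list("xyz"))
        with pytest.raises(ValueError, match="trait subset"):
            variance_explained_by_traits(m, traits)


def brute_force_m2(A, B, n_theta=3600):
    """Grid + refinement oracle: minimize ||s * B0 R - A0||^2 over rotation
    (incl. reflection) and scale, both configurations centered/unit-norm."""
    A0 = A - A.mean(0)
    B0 = B - B.mean(0)
    A0 /= np.linalg.norm(A0)
    B0 /= np.linalg.norm(B0)

    def loss_at(theta, reflect):
        c, s = np.cos(theta), np.sin(theta)
        R = np.array([[c, -s], [s, c]])
        if reflect:
            R = R @ np.diag([1.0, -1.0])
        tr = np.trace(R.T @ B0.T @ A0)
        scale = max(tr, 0.0)  # optimal scale for given rotation
        return 1.0 + scale**2 - 2 * scale * tr

    best = np.inf
    for reflect in (False, True):
        thetas = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
        losses = [loss_at(t, reflect) for t in thetas]
        i = int(np.argmin(losses))
        # local refinement
        lo, hi = thetas[i] - 2 * np.pi / n_theta, thetas[i] + 2 * np.pi / n_theta
        for _ in range(40):
            mid = np.linspace(lo, hi, 9)
            vals = [loss_at(t, reflect) for t in mid]
            j = int(np.argmin(vals))
            lo, hi = mid[max(j - 1, 0)], mid[min(j + 1, 8)]
        best = min(best, min(vals))
    return best


class TestProcrustes:
    def test_similarity_invariance(self):
        rng = np.random.default_rng(0)
        A = rng.random((7, 2))
        th = np.pi / 6
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        B = 3.0 * A @ R + np.array([5.0, -2.0])
        res = procrustes(A, B)
        assert res.correlation == pytest.approx(1.0, abs=1e-10)
        assert res.m_squared == pytest.approx(0.0, abs=1e-10)

    def test_identity(self):
        A = np.random.default_rng(1).random((5, 2))
        assert procrustes(A, A).m_squared == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        A = rng.random((6, 2))
        B = rng.random((6, 2))
        res = procrustes(A, B)
        assert res.m_squared == pytest.approx(brute_force_m2(A, B), abs=1e-6)
        assert res.correlation == pytest.approx(np.sqrt(1 - res.m_squared), abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        A, B = rng.random((8, 2)), rng.random((8, 2))
        assert procrustes(A, B).correlation == pytest.approx(
            procrustes(B, A).correlation, abs=1e-12
        )

    def test_row_set_alignment_and_errors(self):
        rng = np.random.default_rng(4)
        A = pd.DataFrame(rng.random((4, 2)), index=list("abcd"))
        B = A.loc[list("dcba")] * 2.0
        assert procrustes(A, B).correlation == pytest.approx(1.0, abs=1e-10)
        with pytest.raises(ValueError, match="row sets"):
            procrustes(A, A.rename(index={"a": "zz"}))
        with pytest.raises(ValueError, match=">= 2 rows"):
            procrustes(np.ones((1, 2)), np.ones((1, 2)))
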