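"""Shape models: designs, OLS fits, RRPP inference, allometry, PCA and
variance summaries."""

import numpy as np
import pandas as pd
import pytest

from ontotraj import (
    build_design,
    fit_shape_model,
    marginal_means,
    rrpp_test,
    allometry_regression_score,
    shape_pca,
    group_variance_summary,
)


def make_meta(species, ages, n_per_cell):
    rows = [
        {"species": s, "age": a}
        for s in species
        for a in ages
        for _ in range(n_per_cell)
    ]
    return pd.DataFrame(rows)


class TestDesign:
    def test_indicator_coding(self):
        meta = make_meta(["a", "b"], [1, 2], 3)
        design = build_design(meta)
        assert design.X.shape == (12, 4)
        assert np.all(design.X.sum(axis=1) == 1)
        assert design.cells == [("a", 1), ("a", 2), ("b", 1), ("b", 2)]
        assert np.allclose(design.L, np.eye(4))

    def test_identity_L_yields_cell_means(self, rng):
        meta = make_meta(["a", "b"], [1, 2], 3)
        design = build_design(meta)
        Y = rng.normal(size=(12, 5))
        fit = fit_shape_model(Y, design)
        zhat = marginal_means(fit)
        for j, (s, a) in enumerate(design.cells):
            sel = (meta.species == s) & (meta.age == a)
            assert np.allclose(zhat[j], Y[sel.to_numpy()].mean(axis=0), atol=1e-10)

    def test_empty_cell_named(self):
        meta = make_meta(["a", "b"], [1, 2], 2).iloc[:-2]
        with pytest.raises(ValueError, match="b:2"):
            build_design(meta)


class TestFit:
    def test_exact_interpolation(self, rng):
        meta = make_meta(["a", "b"], [1, 2], 3)
        design = build_design(meta)
        B0 = rng.normal(size=(4, 6))
        Y = design.X @ B0
        fit = fit_shape_model(Y, design)
        assert np.abs(fit.beta - B0).max() < 1e-10
        assert np.abs(fit.Se).max() < 1e-20

    def test_matches_normal_equations_oracle(self, rng):
        meta = make_meta(["a", "b"], [1, 2], 3)
        design = build_design(meta)
        Y = rng.normal(size=(12, 6))
        fit = fit_shape_model(Y, design)
        beta_oracle = np.linalg.pinv(design.X.T @ design.X) @ design.X.T @ Y
        assert np.abs(fit.beta - beta_oracle).max() < 1e-10
        resid = Y - design.X @ beta_oracle
        assert np.abs(fit.Se - resid.T @ resid / (12 - 4)).max() < 1e-12

    def test_reconstruction_identity(self, rng):
        meta = make_meta(["a"], [1, 2, 3], 4)
        design = build_design(meta)
        Y = rng.normal(size=(12, 5))
        fit = fit_shape_model(Y, design)
        assert np.abs(fit.X @ fit.beta + fit.residuals - Y).max() < 1e-12


class TestRRPP:
    def test_zero_noise_effect_gives_minimal_p(self, rng):
        n = 12
        g = np.repeat([0, 1], n // 2)
        Xf = np.column_stack([(g == 0).astype(float), (g == 1).astype(float)])
        Xr = np.ones((n, 1))
        Y = np.outer(g, np.ones(4)) * 1.0
        res = rrpp_test(Y, Xf, Xr, n_perm=199, seed=5)
        assert res.p_value == pytest.approx(1 / 200)

    def test_exhaustive_enumeration_matches_oracle(self, rng):
        from itertools import permutations

        n = 6
        g = np.repeat([0, 1], 3)
        Xf = np.column_stack([(g == 0).astype(float), (g == 1).astype(float)])
        Xr = np.ones((n, 1))
        Y = rng.normal(size=(n, 3))
        res = rrpp_test(Y, Xf, Xr, exhaustive=True)

        # independent brute-force oracle with explicit per-permutation OLS
        def rss(X, Ymat):
            b = np.linalg.lstsq(X, Ymat, rcond=None)[0]
            return ((Ymat - X @ b) ** 2).sum()

        br = np.linalg.lstsq(Xr, Y, rcond=None)[0]
        fit_r = Xr @ br
        resid_r = Y - fit_r
        df_eff, df_res = 1, n - 2

        def fstat(Ymat):
            rf, rr = rss(Xf, Ymat), rss(Xr, Ymat)
            return ((rr - rf) / df_eff) / (rf / df_res)

        f_obs = fstat(Y)
        fs = [fstat(fit_r + resid_r[list(p)]) for p in permutations(range(n))]
        p_oracle = np.mean(np.asarray(fs) >= f_obs - 1e-12)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)
        assert res.f_stat == pytest.approx(f_obs, rel=1e-10)

    def test_seed_invariance_in_distribution(self, rng):
        n = 30
        g = np.repeat([0, 1], 15)
        Xf = np.column_stack([(g == 0).astype(float), (g == 1).astype(float)])
        Xr = np.ones((n, 1))
        Y = rng.normal(size=(n, 4))
        Y[g == 1] += 0.35
        p1 = rrpp_test(Y, Xf, Xr, n_perm=10000, seed=1).p_value
        p2 = rrpp_test(Y, Xf, Xr, n_perm=10000, seed=2).p_value
        assert abs(p1 - p2) < 0.02

    def test_non_nested_designs_rejected(self, rng):
        n = 10
        Xf = np.column_stack([np.ones(n), rng.normal(size=n)])
        Xr = np.column_stack([rng.normal(size=n)])
        with pytest.raises(ValueError, match="nested"):
            rrpp_test(rng.normal(size=(n, 2)), Xf, Xr, n_perm=9)


class TestAllometry:
    def test_perfect_allometry_scores(self, rng):
        n, p = 30, 8
        logcs = rng.uniform(0, 1, n)
        u = rng.normal(size=p)
        u /= np.linalg.norm(u)
        Y = np.outer(logcs, u) * 0.3
        species = np.repeat(["a", "b", "c"], 10)
        res = allometry_regression_score(Y, logcs, species)
        r = np.corrcoef(res.scores, logcs)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_score_invariant_to_orthogonal_variation(self, rng):
        n, p = 24, 6
        logcs = rng.uniform(0, 1, n)
        u = np.zeros(p); u[0] = 1.0
        w = np.zeros(p); w[1] = 1.0
        species = np.repeat(["a", "b"], 12)
        Y = np.outer(logcs, u)
        res1 = allometry_regression_score(Y, logcs, species)
        # same orthogonal offset on every specimen: slope and scores unchanged
        res2 = allometry_regression_score(Y + 3.7 * w, logcs, species)
        assert np.abs(res1.scores - res2.scores).max() < 1e-10
        # per-specimen orthogonal variation decorrelated from size in-sample
        coef = rng.normal(size=n)
        X = np.column_stack([(species == "a") * 1.0, (species == "b") * 1.0, logcs])
        coef -= X @ np.linalg.lstsq(X, coef, rcond=None)[0]
        res3 = allometry_regression_score(Y + np.outer(coef, w), logcs, species)
        assert np.abs(res1.common_slope - res3.common_slope).max() < 1e-10

    def test_constant_size_rejected(self, rng):
        logcs = np.concatenate([np.ones(5), np.arange(5.0)])
        species = np.repeat(["a", "b"], 5)
        with pytest.raises(ValueError, match="constant"):
            allometry_regression_score(rng.normal(size=(10, 4)), logcs, species)


class TestPCA:
    def test_single_direction(self, rng):
        u = rng.normal(size=7)
        Y = np.outer(rng.normal(size=20), u)
        res = shape_pca(Y)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_fractions_sum_to_one(self, rng):
        res = shape_pca(rng.normal(size=(15, 6)))
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-12)

    def test_scores_reproduce_distances(self, rng):
        Y = rng.normal(size=(10, 6))
        res = shape_pca(Y)
        D1 = np.linalg.norm(Y[:, None] - Y[None, :], axis=2)
        D2 = np.linalg.norm(res.scores[:, None] - res.scores[None, :], axis=2)
        assert np.abs(D1 - D2).max() < 1e-8

    def test_sign_convention_deterministic(self, rng):
        Y = rng.normal(size=(12, 5))
        res = shape_pca(Y)
        for comp in res.components:
            assert comp[np.argmax(np.abs(comp))] > 0


class TestGroupVariance:
    def test_identical_specimens_zero_within(self):
        meta = make_meta(["a"], [1, 2], 3)
        Y = np.repeat(np.arange(2.0)[:, None], 3, axis=0).reshape(6, 1) @ np.ones((1, 4))
        out = group_variance_summary(Y, meta)
        assert np.allclose(out["within_variance"], 0.0)

    def test_noise_scaling_quadruples_variance(self, rng):
        meta = make_meta(["a"], [1], 50)
        base = rng.normal(size=(1, 6))
        Y1 = base + 0.1 * rng.normal(size=(50, 6))
        Y2 = base + 0.2 * rng.normal(size=(50, 6))
        v1 = group_variance_summary(Y1, meta)["within_variance"][0]
        v2 = group_variance_summary(Y2, meta)["within_variance"][0]
        assert v2 / v1 == pytest.approx(4.0, rel=0.15)

    def test_within_smaller_than_ontogenetic_by_construction(self, rng):
        meta = make_meta(["a"], [1, 2, 3], 5)
        steps = np.repeat(np.arange(3.0), 5)
        Y = np.outer(steps, np.ones(4)) + 0.01 * rng.normal(size=(15, 4))
        out = group_variance_summary(Y, meta)
        assert (out["within_variance"] < out["ontogenetic_variance"]).all()

    def test_singleton_cells_warn(self, rng):
        meta = make_meta(["a"], [1, 2], 1)
        with pytest.warns(RuntimeWarning, match="single specimen"):
            out = group_variance_summary(rng.normal(size=(2, 3)), meta)
        assert out["within_variance"].isna().all()
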