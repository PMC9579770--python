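"""Growth-vector statistics: magnitudes, rates, angles, path distances,
matrix-normal uncertainty, permutation and random-direction nulls."""

import numpy as np
import pandas as pd
import pytest

from ontotraj import (
    GrowthVector,
    build_design,
    fit_shape_model,
    vector_angle,
    path_distance,
    sample_uncertainty,
    weaning_deflection,
    pairwise_trajectory_tests,
    random_angle_null,
    compare_to_axis,
    average_direction,
)
from ontotraj.trajectory import (
    growth_vectors,
    matrix_normal_draws,
    corrected_gram,
)


def cellmeans_context(rng, species=("a", "b"), ages=(7, 14, 35), n=4, p=12, scale=0.05):
    rows = [{"species": s, "age": a} for s in species for a in ages for _ in range(n)]
    meta = pd.DataFrame(rows)
    design = build_design(meta)
    Y = scale * rng.normal(size=(len(meta), p))
    fit = fit_shape_model(Y, design)
    return meta, design, fit, Y


class TestGrowthVectors:
    def test_vectors_are_stage_mean_differences(self, rng):
        meta, design, fit, Y = cellmeans_context(rng)
        vecs = growth_vectors(fit.beta, design)
        zhat = design.L @ fit.beta
        v = [x for x in vecs if x.species == "a" and x.age_from == 7][0]
        expected = zhat[design.cell_column("a", 14)] - zhat[design.cell_column("a", 7)]
        assert np.abs(v.v - expected).max() < 1e-12

    def test_magnitude_and_rate(self):
        v = GrowthVector("a", 10, 35, np.r_[3.0, 4.0, np.zeros(10)])
        assert v.magnitude == pytest.approx(5.0)
        assert v.rate == pytest.approx(0.2)
        assert v.rate * (v.age_to - v.age_from) == pytest.approx(v.magnitude)

    def test_unordered_ages_rejected(self, rng):
        meta, design, fit, _ = cellmeans_context(rng)
        with pytest.raises(ValueError, match="ascending"):
            growth_vectors(fit.beta, design, ages=[14, 7, 35])


class TestAngles:
    def test_canonical_values(self):
        v = np.r_[1.0, np.zeros(5)]
        w = np.r_[0.0, 1.0, np.zeros(4)]
        assert vector_angle(v, v) == pytest.approx(0.0)
        assert vector_angle(v, -v) == pytest.approx(180.0)
        assert vector_angle(v, w) == pytest.approx(90.0)

    def test_symmetry_and_scale_invariance(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=6)
        assert vector_angle(a, b) == pytest.approx(vector_angle(b, a))
        assert vector_angle(3.2 * a, 0.1 * b) == pytest.approx(vector_angle(a, b))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            vector_angle(np.zeros(4), np.ones(4))

    def test_clamping_of_near_parallel(self):
        a = np.ones(4)
        assert vector_angle(a, a * (1 + 1e-16)) == pytest.approx(0.0, abs=1e-6)


class TestPathDistance:
    def test_summation(self):
        vecs = [
            GrowthVector("a", 0, 1, 0.10 * np.r_[1.0, np.zeros(3)]),
            GrowthVector("a", 1, 2, 0.05 * np.r_[0.0, 1.0, 0.0, 0.0]),
            GrowthVector("a", 2, 3, 0.02 * np.r_[0.0, 0.0, 1.0, 0.0]),
        ]
        assert path_distance(vecs) == pytest.approx(0.17)
        assert path_distance(vecs[:1]) == pytest.approx(0.10)

    def test_path_bounds_net_displacement(self, rng):
        vecs = [rng.normal(size=8) for _ in range(4)]
        net = np.linalg.norm(np.sum(vecs, axis=0))
        assert path_distance(vecs) >= net - 1e-12
        collinear = [np.r_[1.0, np.zeros(3)] * m for m in (0.2, 0.3)]
        assert path_distance(collinear) == pytest.approx(
            np.linalg.norm(np.sum(collinear, axis=0))
        )


class TestSampling:
    def test_zero_Se_gives_point_mass(self, rng):
        v = rng.normal(size=10)
        unc = sample_uncertainty(v, np.zeros((10, 10)), np.eye(2), np.r_[1.0, -1.0], n_draws=50, seed=0)
        assert np.abs(unc.draws - v).max() < 1e-14
        assert unc.se_magnitude < 1e-12

    def test_draw_covariance_matches_kronecker(self, rng):
        # 4-landmark toy, explicit Kronecker oracle
        p, m = 12, 2
        B = rng.normal(size=(p, p))
        Se = B @ B.T / p
        dL = rng.normal(size=(m, 3))
        XtX_inv = np.eye(3) * 0.3
        A = dL @ XtX_inv @ dL.T
        draws = matrix_normal_draws(np.zeros((m, p)), A, Se, 50000, np.random.default_rng(5))
        flat = draws.reshape(50000, m * p)
        emp = flat.T @ flat / 50000
        exact = np.kron(A, Se)
        assert np.abs(emp - exact).max() <= 0.05 * np.abs(exact).max()

    def test_doubling_Se_doubles_magnitude_variance(self, rng):
        p = 8
        B = rng.normal(size=(p, p))
        Se = B @ B.T / p
        v = np.zeros(p)
        dL = np.r_[1.0, -1.0]
        u1 = sample_uncertainty(v, Se, np.eye(2) * 0.2, dL, n_draws=30000, seed=1)
        u2 = sample_uncertainty(v, 2 * Se, np.eye(2) * 0.2, dL, n_draws=30000, seed=2)
        r = (u2.draws**2).sum(axis=1).mean() / (u1.draws**2).sum(axis=1).mean()
        assert r == pytest.approx(2.0, rel=0.1)

    def test_non_psd_rejected(self):
        M = np.diag([1.0, -1.0])
        with pytest.raises(ValueError, match="PSD"):
            matrix_normal_draws(np.zeros((2, 2)), M, np.eye(2), 10, np.random.default_rng(0))

    def test_corrected_gram_unbiased(self, rng):
        # estimated vectors = truth + matrix-normal noise; the corrected
        # Gram averages to the true Gram
        p = 10
        v = np.vstack([np.r_[0.3, np.zeros(p - 1)], np.r_[0.0, 0.2, np.zeros(p - 2)]])
        Se = 0.01 * np.eye(p)
        XtX_inv = np.eye(2) * 0.5
        dL = np.eye(2)
        acc = np.zeros((2, 2))
        reps = 3000
        draws = matrix_normal_draws(v, dL @ XtX_inv @ dL.T, Se, reps, rng)
        for d in draws:
            acc += corrected_gram(d, dL, Se, XtX_inv)
        acc /= reps
        assert np.abs(acc - v @ v.T).max() < 5e-3


class TestWeaningDeflection:
    def _context(self, rng, beta_fn):
        species = ["a"]
        ages = [7, 14, 35, 63]
        rows = [{"species": s, "age": a} for s in species for a in ages for _ in range(3)]
        meta = pd.DataFrame(rows)
        design = build_design(meta)
        beta = beta_fn(design)
        return design, beta

    def test_collinear_steps_zero_angle(self, rng):
        def mk(design):
            u = np.r_[1.0, np.zeros(8)]
            return np.array([0 * u, 1 * u, 2 * u, 3 * u])

        design, beta = self._context(rng, mk)
        out = weaning_deflection(beta, design, np.zeros((9, 9)), np.eye(4) / 3, n_draws=10, seed=0)
        assert out["alpha_prior"][0] == pytest.approx(0.0, abs=1e-8)
        assert out["alpha_after"][0] == pytest.approx(0.0, abs=1e-8)

    def test_reversal_is_180(self, rng):
        def mk(design):
            u = np.r_[1.0, np.zeros(8)]
            return np.array([0 * u, 1 * u, 2 * u, 1 * u])

        design, beta = self._context(rng, mk)
        out = weaning_deflection(beta, design, np.zeros((9, 9)), np.eye(4) / 3, n_draws=10, seed=0)
        assert out["alpha_after"][0] == pytest.approx(180.0, abs=1e-8)

    def test_missing_interval_named(self, rng):
        def mk(design):
            return np.zeros((4, 9))

        design, beta = self._context(rng, mk)
        with pytest.raises(ValueError, match="100"):
            weaning_deflection(
                beta, design, np.zeros((9, 9)), np.eye(4) / 3,
                intervals=((7, 14), (14, 35), (35, 100)), n_draws=5,
            )


class TestRandomAngleNull:
    def test_two_dimensions_uniform(self):
        p = random_angle_null(90.0, 2, n_sim=10000, seed=3)
        assert p == pytest.approx(0.5, abs=0.02)

    def test_high_dimension_concentrates_at_90(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((5000, 100))
        b = rng.standard_normal((5000, 100))
        cos = np.einsum("ij,ij->i", a, b) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
        )
        assert np.degrees(np.arccos(cos)).mean() == pytest.approx(90.0, abs=1.0)

    def test_zero_observed_minimal_p(self):
        assert random_angle_null(0.0, 5, n_sim=999, seed=0) == pytest.approx(1 / 1000)

    def test_low_dimension_rejected(self):
        with pytest.raises(ValueError):
            random_angle_null(45.0, 1)


class TestCompareToAxis:
    def test_sign_invariance(self, rng):
        axis = rng.normal(size=9)
        axis /= np.linalg.norm(axis)
        vecs = [GrowthVector("a", 7, 14, 0.2 * axis), GrowthVector("b", 7, 14, -0.5 * axis)]
        out = compare_to_axis(vecs, axis)
        assert np.allclose(out["angle_to_axis"], 0.0, atol=1e-8)

    def test_zero_axis_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            compare_to_axis([], np.zeros(4))


class TestAverageDirection:
    def test_net_mode_is_normalized_sum(self, rng):
        vs = [rng.normal(size=5) for _ in range(3)]
        d = average_direction(vs)
        total = np.sum(vs, axis=0)
        assert np.abs(d - total / np.linalg.norm(total)).max() < 1e-12
        assert np.linalg.norm(average_direction(vs, mode="mean")) == pytest.approx(1.0)


class TestPairwiseTests:
    def test_identical_trajectories_nonsignificant(self, rng):
        # both species follow the exact same trajectory, no noise:
        # observed differences are zero and every permutation ties
        species, ages, n, p = ("a", "b"), (7, 14, 35), 4, 8
        rows = [{"species": s, "age": a} for s in species for a in ages for _ in range(n)]
        meta = pd.DataFrame(rows)
        u = np.zeros(p); u[0] = 1.0
        Y = np.array([{7: 0.0, 14: 0.1, 35: 0.15}[r.age] * u for r in meta.itertuples()])
        out = pairwise_trajectory_tests(Y, meta, n_perm=99, seed=9)
        assert out["path_distance_diff"][0] == pytest.approx(0.0, abs=1e-12)
        assert (out[["p_path", "p_angle", "p_shape"]].to_numpy() > 0.9).all()

    def test_planted_angle_recovered_and_significant(self, rng):
        species, ages, n, p = ("a", "b"), (7, 14, 35), 20, 14
        rows = [{"species": s, "age": a} for s in species for a in ages for _ in range(n)]
        meta = pd.DataFrame(rows)
        u = np.zeros(p); u[0] = 1.0
        w = np.zeros(p); w[1] = 1.0
        th = np.radians(60.0)
        dir_b = np.cos(th) * u + np.sin(th) * w
        means = {
            ("a", 7): np.zeros(p), ("a", 14): 0.1 * u, ("a", 35): 0.2 * u,
            ("b", 7): np.zeros(p), ("b", 14): 0.1 * dir_b, ("b", 35): 0.2 * dir_b,
        }
        Y = np.array([means[(r.species, r.age)] for r in meta.itertuples()])
        Y += 0.01 * rng.normal(size=Y.shape)
        out = pairwise_trajectory_tests(Y, meta, n_perm=499, seed=2)
        assert out["direction_angle"][0] == pytest.approx(60.0, abs=6.0)
        assert out["p_angle"][0] < 0.05

    def test_exhaustive_enumeration_matches_oracle(self, rng):
        from itertools import permutations

        species, ages = ("a", "b"), (7, 14)
        rows = [
            {"species": s, "age": a} for s in species for a in ages
        ] + [{"species": "a", "age": 7}, {"species": "b", "age": 14}]
        meta = pd.DataFrame(rows)
        Y = rng.normal(size=(6, 4))
        out = pairwise_trajectory_tests(Y, meta, seed=0, exhaustive=True)

        # independent enumeration oracle for the path-distance attribute
        sp = meta["species"].to_numpy()
        ag = meta["age"].to_numpy()
        Xr = np.column_stack(
            [(sp == "a") * 1.0, (sp == "b") * 1.0, (ag == 14) * 1.0]
        )
        H = Xr @ np.linalg.pinv(Xr)
        fit_r, res_r = H @ Y, Y - H @ Y

        def path_diff(Ym):
            def path(s):
                m7 = Ym[(sp == s) & (ag == 7)].mean(axis=0)
                m14 = Ym[(sp == s) & (ag == 14)].mean(axis=0)
                return np.linalg.norm(m14 - m7)

            return abs(path("a") - path("b"))

        obs = path_diff(Y)
        stats = [path_diff(fit_r + res_r[list(pm)]) for pm in permutations(range(6))]
        p_oracle = np.mean(np.asarray(stats) >= obs - 1e-12)
        assert out["p_path"][0] == pytest.approx(p_oracle, abs=1e-12)
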