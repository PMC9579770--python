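"""Geometry core: centroid size, OPA/GPA superimposition, tangent
projection, thin-plate splines, vertex distances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ontotraj import (
    centroid_size,
    gpa,
    opa_align,
    opa_distance,
    project_to_tangent,
    tangent_to_config,
    tps_bending_energy,
    bending_energy,
    tps_warp,
    vertex_distances,
)
from ontotraj.geometry import (
    DegenerateConfigurationError,
    SingularKernelError,
)
from ontotraj.dataset import SchemeError

from conftest import random_rotation


class TestCentroidSize:
    def test_triangle_value(self):
        tri = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        assert centroid_size(tri) == pytest.approx(np.sqrt(4 / 3), abs=1e-12)

    def test_rigid_invariance_and_homogeneity(self, rng):
        x = rng.normal(size=(9, 3))
        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        assert centroid_size(x @ R + 5.0) == pytest.approx(
            centroid_size(x), rel=1e-12
        )
        assert centroid_size(2.0 * x) == pytest.approx(
            2.0 * centroid_size(x), rel=1e-12
        )

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateConfigurationError):
            centroid_size(np.zeros((2, 3)))
        with pytest.raises(DegenerateConfigurationError):
            centroid_size(np.ones((5, 3)))


def _grid_rotation_residual(src, tgt):
    """Brute-force hierarchical Euler-angle grid search for the minimal
    rotation-only residual (final step ~2.5e-4 rad)."""
    src = src - src.mean(0)
    tgt = tgt - tgt.mean(0)

    def residuals(angles):
        Rm = Rotation.from_euler("zyz", angles).as_matrix()
        diff = np.einsum("kj,bji->bki", src, Rm) - tgt
        return np.einsum("bki,bki->b", diff, diff)

    center = np.zeros(3)
    width = np.pi
    best = None
    for level in range(4):
        ax = [np.linspace(c - width, c + width, 21) for c in center]
        grid = np.stack(np.meshgrid(*ax, indexing="ij"), -1).reshape(-1, 3)
        res = residuals(grid)
        i = np.argmin(res)
        best = res[i]
        center = grid[i]
        width = width / 10.0
    return float(best)


class TestOPA:
    def test_exact_recovery_of_rigid_motion(self, rng):
        tgt = rng.normal(size=(8, 3))
        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        src = tgt @ R + np.array([5.0, 5.0, 5.0])
        aligned, tf = opa_align(src, tgt)
        assert np.abs(aligned - tgt).max() < 1e-10
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-10)

    def test_reflection_excluded(self, rng):
        tgt = rng.normal(size=(8, 3))
        src = tgt * np.array([-1.0, 1.0, 1.0])  # mirror image
        aligned, tf = opa_align(src, tgt, allow_reflection=False)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-10)
        assert ((aligned - tgt) ** 2).sum() > 1e-4
        # allowing reflections recovers the mirror exactly
        aligned2, _ = opa_align(src, tgt, allow_reflection=True)
        assert np.abs(aligned2 - tgt).max() < 1e-10

    def test_matches_rotation_grid_oracle(self, rng):
        src = rng.normal(size=(10, 3))
        tgt = rng.normal(size=(10, 3))
        aligned, _ = opa_align(src, tgt)
        tgt_c = tgt - tgt.mean(0)
        res_opa = ((aligned - tgt.mean(0) - tgt_c) ** 2).sum()
        res_grid = _grid_rotation_residual(src, tgt)
        assert res_opa <= res_grid + 1e-9
        assert res_grid - res_opa < 1e-5

    def test_residual_symmetric_without_scaling(self, rng):
        a = rng.normal(size=(7, 3))
        b = rng.normal(size=(7, 3))
        ra, _ = opa_align(a, b)
        rb, _ = opa_align(b, a)
        assert ((np.asarray(ra) - (b - b.mean(0) + b.mean(0))) ** 2).sum() == pytest.approx(
            ((np.asarray(rb) - (a - a.mean(0) + a.mean(0))) ** 2).sum(), rel=1e-9
        )

    def test_scheme_mismatch(self, rng):
        with pytest.raises(SchemeError):
            opa_align(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))


class TestGPA:
    def test_pure_nuisance_removal(self, rng):
        shape = rng.normal(size=(10, 3))
        coords = []
        for _ in range(6):
            coords.append(shape @ random_rotation(rng) + rng.normal(size=3))
        res = gpa(np.array(coords), scaling=False)
        spread = res.aligned - res.aligned.mean(0)
        assert np.abs(spread).max() < 1e-8
        assert np.abs(res.tangent).max() < 1e-8

    def test_scaled_copies_zero_tangent_variance(self, rng):
        shape = rng.normal(size=(10, 3))
        coords = np.array([s * shape for s in (0.5, 1.0, 2.0, 3.7)])
        res = gpa(coords, scaling=True)
        assert res.tangent.var(axis=0).max() < 1e-16

    def test_idempotence(self, rng):
        coords = rng.normal(size=(5, 8, 3))
        res1 = gpa(coords)
        res2 = gpa(res1.aligned)
        assert np.abs(res2.consensus - res1.consensus).max() < 1e-8

    def test_objective_non_increasing(self, rng):
        coords = rng.normal(size=(6, 9, 3)) + 5 * rng.normal(size=(6, 1, 3))
        res = gpa(coords)
        obj = np.array(res.objective_history)
        assert np.all(np.diff(obj) <= 1e-12)

    def test_two_configs_match_opa_distance(self, rng):
        base = rng.normal(size=(9, 3))
        other = base + 0.05 * rng.normal(size=(9, 3))
        res = gpa(np.array([base, other]), scaling=True)
        d_gpa = np.linalg.norm(res.aligned[0] - res.aligned[1])
        d_opa = opa_distance(base, other, scaling=True)
        assert d_gpa == pytest.approx(d_opa, rel=1e-6)

    def test_consensus_is_mean_of_aligned(self, rng):
        shape = rng.normal(size=(8, 3))
        coords = np.array(
            [shape @ random_rotation(rng) for _ in range(5)]
        )
        res = gpa(coords, scaling=True)
        mean = res.aligned.mean(0)
        mean = mean / centroid_size(mean)
        assert np.abs(res.consensus - mean).max() < 1e-8


class TestTangentProjection:
    def test_consensus_maps_to_zero_and_orthogonality(self, rng):
        coords = rng.normal(size=(6, 10, 3))
        res = gpa(coords)
        c = res.consensus.ravel() / np.linalg.norm(res.consensus.ravel())
        assert np.abs(project_to_tangent(res.consensus, res.consensus)).max() < 1e-12
        assert np.abs(res.tangent @ c).max() < 1e-12

    def test_tangent_distances_match_procrustes_distances(self, rng):
        base = rng.normal(size=(12, 3))
        base /= centroid_size(base)
        coords = np.array([base + 1e-3 * rng.normal(size=(12, 3)) for _ in range(6)])
        res = gpa(coords, scaling=True)
        for i in range(3):
            for j in range(i + 1, 6):
                dt = np.linalg.norm(res.tangent[i] - res.tangent[j])
                dp = opa_distance(coords[i], coords[j], scaling=True)
                assert dt == pytest.approx(dp, rel=1e-4)

    def test_tangent_metric_axioms(self, rng):
        coords = rng.normal(size=(5, 7, 3))
        T = gpa(coords).tangent
        D = np.linalg.norm(T[:, None, :] - T[None, :, :], axis=2)
        assert np.allclose(D, D.T)
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-12

    def test_roundtrip_config(self, rng):
        coords = rng.normal(size=(4, 6, 3))
        res = gpa(coords)
        cfg = tangent_to_config(res.tangent[2], res.consensus)
        # reconstruction inverts the projection up to the removed
        # consensus-direction component
        assert np.abs(project_to_tangent(cfg, res.consensus) - res.tangent[2]).max() < 1e-10


class TestTPS:
    def test_bending_energy_psd_and_affine_null(self, rng):
        ref = rng.normal(size=(12, 3))
        Be = tps_bending_energy(ref)
        ev = np.linalg.eigvalsh(Be)
        assert ev.min() > -1e-10
        A = rng.normal(size=(3, 3))
        b = rng.normal(size=3)
        assert abs(bending_energy(Be, ref @ A + b)) < 1e-9

    def test_energy_quadratic_scaling(self, rng):
        ref = rng.normal(size=(10, 3))
        Be = tps_bending_energy(ref)
        d = np.zeros((10, 3))
        d[4] = [0.05, 0.0, 0.0]
        e1 = bending_energy(Be, ref + d)
        e2 = bending_energy(Be, ref + 2 * d)
        assert e2 / e1 == pytest.approx(4.0, abs=1e-3)

    def test_coincident_points_named(self):
        ref = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        with pytest.raises(SingularKernelError, match="1 and 2"):
            tps_bending_energy(ref)

    def test_warp_identity_translation_interpolation(self, rng):
        ref = rng.normal(size=(9, 3))
        q = rng.normal(size=(30, 3))
        assert np.abs(tps_warp(ref, ref, q) - q).max() < 1e-8
        t = np.array([1.0, 2.0, 3.0])
        assert np.abs(tps_warp(ref, ref + t, q) - (q + t)).max() < 1e-8
        tgt = ref + 0.1 * rng.normal(size=(9, 3))
        assert np.abs(tps_warp(ref, tgt, ref) - tgt).max() < 1e-8


class TestVertexDistances:
    def test_basic_and_oracle(self, rng):
        a = rng.normal(size=(20, 3))
        assert np.all(vertex_distances(a, a) == 0)
        assert np.allclose(vertex_distances(a, a + [0, 0, 2.0]), 2.0)
        b = rng.normal(size=(20, 3))
        expected = np.array([np.sqrt(((x - y) ** 2).sum()) for x, y in zip(a, b)])
        assert np.allclose(vertex_distances(a, b), expected)
        with pytest.raises(SchemeError):
            vertex_distances(a, b[:-1])
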