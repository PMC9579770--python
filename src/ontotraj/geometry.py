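"""Core shape geometry.

Centroid size, ordinary and generalized Procrustes superimposition,
orthogonal tangent projection at the mean shape, thin-plate-spline (TPS)
bending energy and warps, and per-vertex distance fields.

Conventions used throughout the package
---------------------------------------
* Configurations are (k, 3) arrays; flattened vectors are landmark-major
  (x1, y1, z1, x2, ...), i.e. ``coords.ravel()`` in C order.
* Reflections are disallowed by default in every superimposition
  (biological homology); pass ``allow_reflection=True`` to permit them.
* The 3D TPS kernel is U(r) = -r, which yields a positive semi-definite
  bending-energy form whose null space is exactly the affine maps.
* Angles exposed by this module are in degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .dataset import LandmarkConfiguration, SchemeError, ShapeDataset

__all__ = [
    "RigidTransform",
    "ProcrustesResult",
    "DegenerateConfigurationError",
    "GPAConvergenceError",
    "SingularKernelError",
    "centroid_size",
    "opa_align",
    "opa_distance",
    "gpa",
    "project_to_tangent",
    "tangent_to_config",
    "tps_bending_energy",
    "bending_energy",
    "tps_warp",
    "vertex_distances",
]


class DegenerateConfigurationError(ValueError):
    """Configuration has too few points or no spatial extent."""


class GPAConvergenceError(RuntimeError):
    """Generalized Procrustes analysis failed to converge."""

    def __init__(self, msg: str, last_delta: float):
        super().__init__(msg)
        self.last_delta = last_delta


class SingularKernelError(ValueError):
    """TPS kernel system is singular (typically coincident landmarks)."""


@dataclass
class RigidTransform:
    """Similarity transform ``x -> scale * x @ rotation + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(coords) @ self.rotation + self.translation


@dataclass
class ProcrustesResult:
    """Output of a generalized Procrustes analysis.

    ``tangent`` holds the flattened 3k tangent-space coordinates of every
    aligned configuration, obtained by orthogonal projection at the
    consensus; the consensus itself maps to the zero vector.
    """

    consensus: np.ndarray
    aligned: np.ndarray
    centroid_sizes: np.ndarray
    tangent: np.ndarray
    scaled: bool
    n_iterations: int = 0
    consensus_deltas: list = field(default_factory=list)
    objective_history: list = field(default_factory=list)


def _coords_of(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return config.coords
    return np.asarray(config, dtype=float)


def centroid_size(config) -> float:
    """Square root of summed squared deviations from the centroid.

    The size variable of geometric morphometrics; invariant to rotation
    and translation, homogeneous of degree one under scaling.
    """
    x = _coords_of(config)
    if x.ndim != 2 or x.shape[0] < 3:
        raise DegenerateConfigurationError(
            "centroid size needs at least 3 points"
        )
    c = x - x.mean(axis=0)
    cs = float(np.sqrt((c**2).sum()))
    if cs == 0.0:
        raise DegenerateConfigurationError("all landmarks coincide")
    return cs


def _optimal_rotation(H: np.ndarray, allow_reflection: bool) -> np.ndarray:
    """Rotation R maximizing trace(R' H) for cross-covariance H = Xc' Yc."""
    U, s, Vt = np.linalg.svd(H)
    R = U @ Vt
    if not allow_reflection and np.linalg.det(R) < 0:
        # flip the sign carried by the smallest singular vector
        U = U.copy()
        U[:, -1] *= -1
        R = U @ Vt
    return R


def opa_align(
    source,
    target,
    allow_scaling: bool = False,
    allow_reflection: bool = False,
):
    """Ordinary Procrustes superimposition of ``source`` onto ``target``.

    Finds the rotation (via SVD of the cross-covariance), optional scale
    and translation minimizing the summed squared distance to the target.

    Returns
    -------
    aligned : ndarray or LandmarkConfiguration
        Source after the optimal similarity transform (matches input type).
    transform : RigidTransform
    """
    xs, xt = _coords_of(source), _coords_of(target)
    if xs.shape != xt.shape:
        raise SchemeError(
            f"landmark count mismatch: {xs.shape[0]} vs {xt.shape[0]}"
        )
    if (
        isinstance(source, LandmarkConfiguration)
        and isinstance(target, LandmarkConfiguration)
        and source.labels != target.labels
    ):
        raise SchemeError("label sequences differ between source and target")
    cs, ct = xs.mean(axis=0), xt.mean(axis=0)
    Xs, Xt = xs - cs, xt - ct
    H = Xs.T @ Xt
    if np.linalg.matrix_rank(H) < 2:
        warnings.warn(
            "rank-deficient cross-covariance; alignment may be unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    U, s, Vt = np.linalg.svd(H)
    flip = np.ones(3)
    if not allow_reflection and np.linalg.det(U @ Vt) < 0:
        flip[-1] = -1.0
    R = (U * flip) @ Vt
    if allow_scaling:
        scale = float((s * flip).sum() / (Xs**2).sum())
    else:
        scale = 1.0
    aligned = scale * Xs @ R + ct
    transform = RigidTransform(
        rotation=R, translation=ct - scale * cs @ R, scale=scale
    )
    if isinstance(source, LandmarkConfiguration):
        aligned = LandmarkConfiguration(aligned, list(source.labels))
    return aligned, transform


def opa_distance(a, b, scaling: bool = True) -> float:
    """Procrustes distance between two configurations.

    With ``scaling`` both configurations are first scaled to unit centroid
    size (partial Procrustes distance after size removal); the distance is
    the root summed squared difference after optimal superimposition.
    """
    xa, xb = _coords_of(a).copy(), _coords_of(b).copy()
    xa -= xa.mean(axis=0)
    xb -= xb.mean(axis=0)
    if scaling:
        xa /= centroid_size(xa)
        xb /= centroid_size(xb)
    aligned, _ = opa_align(xa, xb)
    return float(np.sqrt(((aligned - xb) ** 2).sum()))


def gpa(
    dataset,
    scaling: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
    allow_reflection: bool = False,
) -> ProcrustesResult:
    """Generalized Procrustes analysis.

    Iterative superimposition: centre all configurations, optionally scale
    each to unit centroid size, then repeatedly rotate each onto the
    current consensus and re-average until the root-mean-square change of
    the consensus falls below ``tol`` (or ``max_iter`` is exceeded, which
    raises :class:`GPAConvergenceError`). With ``scaling`` the consensus is
    kept at unit centroid size.

    ``dataset`` may be a :class:`ShapeDataset` or an (n, k, 3) array.
    """
    if isinstance(dataset, ShapeDataset):
        coords = dataset.coords
    else:
        coords = np.asarray(dataset, dtype=float)
    if coords.ndim != 3 or coords.shape[0] < 2:
        raise SchemeError("GPA needs at least 2 configurations of shape (k, 3)")
    n = coords.shape[0]
    X = coords - coords.mean(axis=1, keepdims=True)
    sizes = np.sqrt((X**2).sum(axis=(1, 2)))
    if np.any(sizes == 0):
        raise DegenerateConfigurationError("degenerate configuration in dataset")
    if scaling:
        X = X / sizes[:, None, None]

    consensus = X.mean(axis=0)
    if scaling:
        consensus = consensus / centroid_size(consensus)
    deltas = []
    objectives = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            R = _optimal_rotation(X[i].T @ consensus, allow_reflection)
            X[i] = X[i] @ R
        new_consensus = X.mean(axis=0)
        if scaling:
            new_consensus = new_consensus / centroid_size(new_consensus)
        objectives.append(float(((X - new_consensus) ** 2).sum()))
        delta = float(
            np.sqrt(((new_consensus - consensus) ** 2).mean())
        )
        deltas.append(delta)
        consensus = new_consensus
        if delta < tol:
            converged = True
            break
    if not converged:
        raise GPAConvergenceError(
            f"GPA did not converge in {max_iter} iterations "
            f"(last consensus RMS change {deltas[-1]:.3e})",
            last_delta=deltas[-1],
        )
    tangent = project_to_tangent(X, consensus)
    return ProcrustesResult(
        consensus=consensus,
        aligned=X,
        centroid_sizes=sizes,
        tangent=tangent,
        scaled=scaling,
        n_iterations=it,
        consensus_deltas=deltas,
        objective_history=objectives,
    )


def project_to_tangent(aligned: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Orthogonal projection onto the tangent plane at the consensus.

    ``t_i = (I - c c') vec(aligned_i)`` with ``c`` the unit-norm flattened
    consensus. The consensus itself maps to the zero vector.
    """
    cons = np.asarray(consensus, dtype=float).ravel()
    norm = np.linalg.norm(cons)
    if norm == 0:
        raise DegenerateConfigurationError("zero consensus")
    c = cons / norm
    X = np.asarray(aligned, dtype=float).reshape(-1, cons.size)
    T = X - np.outer(X @ c, c)
    if np.asarray(aligned).ndim == 2:
        return T[0]
    return T


def tangent_to_config(tangent: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Map a tangent vector back to a (k, 3) configuration near the mean."""
    cons = np.asarray(consensus, dtype=float)
    t = np.asarray(tangent, dtype=float).ravel()
    if t.size != cons.size:
        raise SchemeError("tangent vector length does not match consensus")
    return cons + t.reshape(cons.shape)


def _tps_system(ref: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    k = ref.shape[0]
    K = -cdist(ref, ref)  # 3D TPS kernel U(r) = -r
    if ridge:
        K = K + ridge * np.eye(k)
    P = np.hstack([np.ones((k, 1)), ref])
    L = np.zeros((k + 4, k + 4))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    return L


def _check_distinct(ref: np.ndarray) -> None:
    d = cdist(ref, ref)
    np.fill_diagonal(d, np.inf)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    if d[i, j] == 0.0:
        raise SingularKernelError(
            f"coincident landmarks {i} and {j}; TPS kernel is singular "
            "(consider a small ridge term, e.g. ridge=1e-8)"
        )


def tps_bending_energy(reference, ridge: float = 0.0) -> np.ndarray:
    """Bending-energy matrix of the 3D thin-plate spline at ``reference``.

    Returns the k x k matrix ``B`` such that the bending energy of a
    deformation taking the reference onto a target ``Y`` is
    ``sum_d Y[:, d]' B Y[:, d]``. Symmetric positive semi-definite; affine
    transforms of the reference have exactly zero energy.
    """
    ref = _coords_of(reference)
    _check_distinct(ref)
    k = ref.shape[0]
    L = _tps_system(ref, ridge)
    try:
        Li = np.linalg.inv(L)
    except np.linalg.LinAlgError as exc:
        raise SingularKernelError(
            "singular TPS system; consider ridge=1e-8"
        ) from exc
    Be = Li[:k, :k]
    return (Be + Be.T) / 2.0


def bending_energy(Be: np.ndarray, coords) -> float:
    """Evaluate the bending-energy quadratic form on a configuration."""
    Y = _coords_of(coords)
    return float(np.einsum("id,ij,jd->", Y, Be, Y))


def tps_warp(reference, target, query_points, ridge: float = 0.0) -> np.ndarray:
    """Thin-plate-spline interpolant mapping reference landmarks exactly
    onto target landmarks, evaluated at ``query_points``.

    Used e.g. to deform mesh vertices along an estimated shape change.
    """
    ref, tgt = _coords_of(reference), _coords_of(target)
    if ref.shape != tgt.shape:
        raise SchemeError("reference and target have different schemes")
    if (
        isinstance(reference, LandmarkConfiguration)
        and isinstance(target, LandmarkConfiguration)
        and reference.labels != target.labels
    ):
        raise SchemeError("label sequences differ between reference and target")
    _check_distinct(ref)
    k = ref.shape[0]
    L = _tps_system(ref, ridge)
    rhs = np.zeros((k + 4, 3))
    rhs[:k] = tgt
    try:
        coefs = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:
        raise SingularKernelError(
            "singular TPS system; consider ridge=1e-8"
        ) from exc
    W, A = coefs[:k], coefs[k:]
    q = np.asarray(query_points, dtype=float)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    U = -cdist(q, ref)
    out = U @ W + np.hstack([np.ones((q.shape[0], 1)), q]) @ A
    return out[0] if single else out


def vertex_distances(mesh_a_vertices, mesh_b_vertices) -> np.ndarray:
    """Euclidean distance per corresponding vertex pair."""
    a = np.asarray(mesh_a_vertices, dtype=float)
    b = np.asarray(mesh_b_vertices, dtype=float)
    if a.shape != b.shape:
        raise SchemeError(
            f"vertex count mismatch: {a.shape} vs {b.shape}"
        )
    return np.linalg.norm(a - b, axis=-1)
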