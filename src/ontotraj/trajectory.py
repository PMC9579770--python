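"""Growth-vector statistics on transported trajectories.

A growth vector is the difference between the transported expected
marginal means of two consecutive developmental stages,
``v = (L_j - L_{j-1}) beta_tr``. This module computes their magnitudes
(Procrustes units), per-day rates, path distances (summed step norms),
angles between vectors (between species at the same interval, between
consecutive intervals within a species — the weaning deflection — and
against a reference axis such as a transported principal component),
sampled standard errors from the matrix-normal sampling distribution of
the contrast estimates, permutation tests of pairwise trajectory
differences, and a random-direction null for observed angles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .shapemodel import DesignSpec, build_design

__all__ = [
    "GrowthVector",
    "VectorUncertainty",
    "growth_vectors",
    "interval_contrast",
    "vector_angle",
    "path_distance",
    "matrix_normal_draws",
    "sample_uncertainty",
    "angle_uncertainty",
    "weaning_deflection",
    "pairwise_trajectory_tests",
    "corrected_gram",
    "corrected_magnitude",
    "corrected_angle",
    "random_angle_null",
    "compare_to_axis",
    "average_direction",
    "circular_sd",
]


@dataclass
class GrowthVector:
    """Shape change between two consecutive transported stage means."""

    species: str
    age_from: float
    age_to: float
    v: np.ndarray
    magnitude: float = 0.0
    rate: float = 0.0

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float).ravel()
        self.magnitude = float(np.linalg.norm(self.v))
        days = self.age_to - self.age_from
        if days <= 0:
            raise ValueError("age_to must exceed age_from")
        self.rate = self.magnitude / days


def interval_contrast(design: DesignSpec, species, age_from, age_to) -> np.ndarray:
    """Contrast row ``L_{a=j} - L_{a=j-1}`` selecting one growth vector."""
    row = np.zeros(design.q)
    row[design.cell_column(species, age_to)] = 1.0
    row[design.cell_column(species, age_from)] = -1.0
    return row @ design.L  # identity for cell-means coding


def growth_vectors(beta_tr: np.ndarray, design: DesignSpec, ages=None) -> list:
    """Ordered growth vectors per species from transported coefficients."""
    ages = list(ages) if ages is not None else list(design.age_levels)
    if sorted(ages) != ages:
        raise ValueError("ages must be ascending")
    if len(ages) < 2:
        raise ValueError("need at least 2 stages per species")
    out = []
    for s in design.species_levels:
        for a0, a1 in zip(ages[:-1], ages[1:]):
            dL = interval_contrast(design, s, a0, a1)
            out.append(GrowthVector(s, a0, a1, dL @ beta_tr))
    return out


def vector_angle(v1, v2, acute: bool = False) -> float:
    """Angle in degrees between two vectors (unit-normalized dot product,
    clamped to [-1, 1] before the arccosine).

    ``acute=True`` folds the angle to [0, 90] — appropriate against
    eigenvector axes whose sign is arbitrary; species-vs-species angles
    keep the full [0, 180] range because direction is meaningful there.
    """
    a = np.asarray(getattr(v1, "v", v1), dtype=float).ravel()
    b = np.asarray(getattr(v2, "v", v2), dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("angle with a zero vector is undefined")
    c = float(np.clip(a @ b / (na * nb), -1.0, 1.0))
    theta = float(np.degrees(np.arccos(c)))
    return min(theta, 180.0 - theta) if acute else theta


def path_distance(vectors) -> float:
    """Sum of growth-vector norms: total shape change along a trajectory."""
    vecs = list(vectors)
    if not vecs:
        raise ValueError("need at least one growth vector")
    return float(
        sum(
            v.magnitude if isinstance(v, GrowthVector) else np.linalg.norm(v)
            for v in vecs
        )
    )


def average_direction(vectors, mode: str = "net") -> np.ndarray:
    """Average direction of a trajectory.

    ``net`` (default): unit-normalized vector sum of the growth vectors,
    i.e. the direction of the net displacement from first to last stage.
    ``mean``: unit-normalized mean of the per-interval unit directions.
    """
    vs = [np.asarray(getattr(v, "v", v), float).ravel() for v in vectors]
    if mode == "net":
        total = np.sum(vs, axis=0)
    elif mode == "mean":
        total = np.sum([v / np.linalg.norm(v) for v in vs], axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    norm = np.linalg.norm(total)
    if norm == 0:
        raise ValueError("zero net displacement; average direction undefined")
    return total / norm


def _psd_factor(M: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Square-root factor of a PSD matrix via eigendecomposition.

    Eigenvalues in [-tol*scale, 0) are zeroed; more negative ones raise.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim == 0:
        M = M.reshape(1, 1)
    w, V = np.linalg.eigh((M + M.T) / 2.0)
    scale = max(w.max(), 1.0) if w.size else 1.0
    if w.min() < -tol * scale:
        raise ValueError(
            f"matrix is not PSD within tolerance (min eigenvalue {w.min():.3e})"
        )
    w = np.clip(w, 0.0, None)
    keep = w > 0
    return V[:, keep] * np.sqrt(w[keep])


def matrix_normal_draws(
    M: np.ndarray,
    row_cov: np.ndarray,
    col_cov: np.ndarray,
    n_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draws from MN(M, row_cov, col_cov) without forming the Kronecker
    covariance: ``M + A Z B'`` with A, B square-root factors and Z iid
    standard normal."""
    M = np.atleast_2d(np.asarray(M, dtype=float))
    A = _psd_factor(row_cov)
    B = _psd_factor(col_cov)
    Z = rng.standard_normal((n_draws, A.shape[1], B.shape[1]))
    return M[None] + A @ Z @ B.T


def circular_sd(angles_deg: np.ndarray) -> float:
    """Circular standard deviation sqrt(-2 ln Rbar) of angles, in degrees."""
    theta = np.radians(np.asarray(angles_deg, float))
    rbar = float(np.abs(np.exp(1j * theta).mean()))
    rbar = min(max(rbar, 1e-300), 1.0)
    return float(np.degrees(np.sqrt(-2.0 * np.log(rbar))))


def circular_mean(angles_deg: np.ndarray) -> float:
    theta = np.radians(np.asarray(angles_deg, float))
    return float(np.degrees(np.angle(np.exp(1j * theta).mean())))


@dataclass
class VectorUncertainty:
    """Matrix-normal draws of a growth vector with derived standard errors.

    Draws follow ``v* ~ N(v, Se (x) dL (X'X)^-1 dL')`` where Se is the
    residual covariance of the shape model and dL the interval contrast.
    ``se_magnitude`` is the standard deviation of the draw norms;
    ``se_angle`` the circular standard deviation of the angles between
    the draws and the estimated direction.
    """

    draws: np.ndarray = field(repr=False)
    se_magnitude: float
    se_angle: float
    n_draws: int
    seed: int | None


def sample_uncertainty(
    v_hat: np.ndarray,
    Se: np.ndarray,
    XtX_inv: np.ndarray,
    delta_L: np.ndarray,
    n_draws: int = 1000,
    seed: int | None = None,
) -> VectorUncertainty:
    """Sampling distribution of one (or several stacked) growth vectors."""
    v_hat = np.atleast_2d(np.asarray(v_hat, dtype=float))
    dL = np.atleast_2d(np.asarray(delta_L, dtype=float))
    A = dL @ XtX_inv @ dL.T
    rng = np.random.default_rng(seed)
    draws = matrix_normal_draws(v_hat, A, Se, n_draws, rng)
    mags = np.linalg.norm(draws[:, 0, :], axis=1)
    se_mag = float(mags.std(ddof=1)) if n_draws > 1 else 0.0
    ref = v_hat[0]
    nref = np.linalg.norm(ref)
    if nref > 0:
        cos = np.clip(
            draws[:, 0, :] @ ref / (np.linalg.norm(draws[:, 0, :], axis=1) * nref + 1e-300),
            -1.0,
            1.0,
        )
        se_ang = circular_sd(np.degrees(np.arccos(cos)))
    else:
        se_ang = float("nan")
    return VectorUncertainty(
        draws=draws if draws.shape[1] > 1 else draws[:, 0, :],
        se_magnitude=se_mag,
        se_angle=se_ang,
        n_draws=n_draws,
        seed=seed,
    )


def angle_uncertainty(
    fit_Se: np.ndarray,
    XtX_inv: np.ndarray,
    beta_tr: np.ndarray,
    dL_pair: np.ndarray,
    n_draws: int = 1000,
    seed: int | None = None,
) -> dict:
    """SE of the angle between two growth vectors via joint draws.

    ``dL_pair`` stacks the two interval contrasts (2, q); drawing them
    jointly keeps the correlation induced by shared coefficients.
    """
    dL = np.atleast_2d(dL_pair)
    V = dL @ beta_tr
    A = dL @ XtX_inv @ dL.T
    rng = np.random.default_rng(seed)
    draws = matrix_normal_draws(V, A, fit_Se, n_draws, rng)
    n1 = np.linalg.norm(draws[:, 0, :], axis=1)
    n2 = np.linalg.norm(draws[:, 1, :], axis=1)
    cos = np.clip(
        np.einsum("np,np->n", draws[:, 0, :], draws[:, 1, :]) / (n1 * n2 + 1e-300),
        -1.0,
        1.0,
    )
    angles = np.degrees(np.arccos(cos))
    return {
        "angle": vector_angle(V[0], V[1]),
        "se_angle": circular_sd(angles),
        "circular_mean": circular_mean(angles),
        "draw_angles": angles,
    }


def weaning_deflection(
    beta_tr: np.ndarray,
    design: DesignSpec,
    Se: np.ndarray,
    XtX_inv: np.ndarray,
    intervals=((7, 14), (14, 35), (35, 63)),
    n_draws: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Deflection of growth at weaning, per species.

    ``alpha_prior`` is the angle between the pre-weaning growth vector and
    the weaning-interval vector; ``alpha_after`` between the post-weaning
    and weaning vectors. Standard errors propagate the matrix-normal
    sampling distribution of the coefficients through the angles.
    """
    (prior, weaning, after) = intervals
    for iv in intervals:
        for a in iv:
            if a not in design.age_levels:
                raise ValueError(f"age {a} not present in the design")
    rng = np.random.default_rng(seed)
    rows = []
    for s in design.species_levels:
        dLs = np.array(
            [
                interval_contrast(design, s, *prior),
                interval_contrast(design, s, *weaning),
                interval_contrast(design, s, *after),
            ]
        )
        sub_seed = int(rng.integers(2**31))
        V = dLs @ beta_tr
        res_prior = angle_uncertainty(
            Se, XtX_inv, beta_tr, dLs[[0, 1]], n_draws, sub_seed
        )
        res_after = angle_uncertainty(
            Se, XtX_inv, beta_tr, dLs[[2, 1]], n_draws, sub_seed + 1
        )
        rows.append(
            {
                "species": s,
                "alpha_prior": res_prior["angle"],
                "alpha_prior_corrected": corrected_angle(
                    V[0], V[1], dLs[[0, 1]], Se, XtX_inv
                ),
                "se_prior": res_prior["se_angle"],
                "alpha_after": res_after["angle"],
                "alpha_after_corrected": corrected_angle(
                    V[2], V[1], dLs[[2, 1]], Se, XtX_inv
                ),
                "se_after": res_after["se_angle"],
                "n_draws": n_draws,
            }
        )
    return pd.DataFrame(rows)


def corrected_gram(
    V: np.ndarray,
    dLs: np.ndarray,
    Se: np.ndarray,
    XtX_inv: np.ndarray,
) -> np.ndarray:
    """Bias-corrected inner products of estimated growth vectors.

    The raw inner product of two estimated vectors overestimates the true
    one by the trace of their sampling cross-covariance,
    ``E[v_i' v_j] = v_i' v_j + (dL_i (X'X)^-1 dL_j') tr(Se)``;
    in particular raw norms (hence magnitudes, rates and path distances)
    are inflated and raw angles are pushed towards 90 degrees. This
    returns the corrected Gram matrix ``V V' - A tr(Se)`` with
    ``A = dLs (X'X)^-1 dLs'``.
    """
    V = np.atleast_2d(np.asarray(V, float))
    dLs = np.atleast_2d(np.asarray(dLs, float))
    A = dLs @ XtX_inv @ dLs.T
    return V @ V.T - A * float(np.trace(Se))


def corrected_magnitude(
    v_hat: np.ndarray, Se: np.ndarray, XtX_inv: np.ndarray, delta_L: np.ndarray
) -> float:
    """Bias-corrected growth-vector magnitude (clipped at zero)."""
    g = corrected_gram(v_hat, delta_L, Se, XtX_inv)
    return float(np.sqrt(max(g[0, 0], 0.0)))


def corrected_angle(
    v1: np.ndarray,
    v2: np.ndarray,
    dL_pair: np.ndarray,
    Se: np.ndarray,
    XtX_inv: np.ndarray,
) -> float:
    """Bias-corrected angle (degrees) between two estimated vectors."""
    G = corrected_gram(np.vstack([np.ravel(v1), np.ravel(v2)]), dL_pair, Se, XtX_inv)
    m1, m2 = np.sqrt(max(G[0, 0], 1e-300)), np.sqrt(max(G[1, 1], 1e-300))
    return float(np.degrees(np.arccos(np.clip(G[0, 1] / (m1 * m2), -1.0, 1.0))))


def random_angle_null(
    observed_angle: float,
    dimension: int,
    n_sim: int = 10000,
    seed: int | None = None,
) -> float:
    """P(angle between two uniform random directions <= observed).

    Uses Monte-Carlo pairs of uniform directions in ``dimension``
    dimensions and the +1 convention; small p means the observed angle is
    smaller than expected between unrelated directions.
    """
    if dimension < 2:
        raise ValueError("dimension must be >= 2")
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_sim, dimension))
    b = rng.standard_normal((n_sim, dimension))
    cos = np.einsum("ij,ij->i", a, b) / (
        np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
    )
    angles = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    return float((np.sum(angles <= observed_angle) + 1) / (n_sim + 1))


def compare_to_axis(vectors, axis: np.ndarray) -> pd.DataFrame:
    """Acute angle between growth vectors and a reference axis.

    The acute convention is used because the sign of an eigenvector axis
    is arbitrary.
    """
    axis = np.asarray(axis, dtype=float).ravel()
    if np.linalg.norm(axis) == 0:
        raise ValueError("zero axis")
    rows = []
    for v in vectors:
        rows.append(
            {
                "species": v.species,
                "age_from": v.age_from,
                "age_to": v.age_to,
                "angle_to_axis": vector_angle(v.v, axis, acute=True),
            }
        )
    return pd.DataFrame(rows)


def _trajectory_attributes(Y: np.ndarray, design: DesignSpec, ages):
    """Per-species (path distance, net direction, stage-mean matrix)."""
    fit_beta = np.linalg.lstsq(design.X, Y, rcond=None)[0]
    zhat = design.L @ fit_beta
    out = {}
    for s in design.species_levels:
        means = np.array([zhat[design.cell_column(s, a)] for a in ages])
        steps = np.diff(means, axis=0)
        path = float(np.linalg.norm(steps, axis=1).sum())
        net = steps.sum(axis=0)
        out[s] = (path, net, means)
    return out


def _trajectory_shape_distance(m1: np.ndarray, m2: np.ndarray) -> float:
    """Procrustes distance between two stage-mean sequences treated as
    point configurations (translation, scale and rotation removed;
    reflections allowed, following the trajectory-analysis convention)."""
    A = m1 - m1.mean(axis=0)
    B = m2 - m2.mean(axis=0)
    na, nb = np.linalg.norm(A), np.linalg.norm(B)
    if na == 0 or nb == 0:
        return 0.0
    A, B = A / na, B / nb
    s = np.linalg.svd(A.T @ B, compute_uv=False)
    return float(np.sqrt(max(0.0, 2.0 - 2.0 * s.sum())))


def pairwise_trajectory_tests(
    Y_tr: np.ndarray,
    metadata: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    ages=None,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Permutation tests of pairwise trajectory differences.

    For every species pair the observed differences in (i) path distance,
    (ii) angle between average trajectory directions (net displacement)
    and (iii) trajectory shape (Procrustes distance between the ordered
    stage-mean sequences, scaling enabled) are compared against a residual
    randomization null: residuals of the additive (species + age) model —
    under which all species share one trajectory — are permuted across
    specimens, added back to the additive fitted values, and the
    attributes recomputed. P-values use the +1 convention.
    """
    if n_perm < 99:
        import warnings

        warnings.warn(
            "fewer than 99 permutations gives a very coarse p-value",
            RuntimeWarning,
            stacklevel=2,
        )
    metadata = metadata.reset_index(drop=True)
    Y_tr = np.asarray(Y_tr, dtype=float)
    design = build_design(metadata)
    ages = list(ages) if ages is not None else list(design.age_levels)
    if len(design.species_levels) < 2:
        raise ValueError("need at least 2 species")
    # additive reduced model: species + age main effects
    sp = metadata["species"].to_numpy()
    ag = metadata["age"].to_numpy()
    Xr = np.column_stack(
        [(sp == s).astype(float) for s in design.species_levels]
        + [(ag == a).astype(float) for a in design.age_levels[1:]]
    )
    Hr = Xr @ np.linalg.pinv(Xr)
    fitted_r = Hr @ Y_tr
    resid_r = Y_tr - fitted_r

    pairs = [
        (s1, s2)
        for i, s1 in enumerate(design.species_levels)
        for s2 in design.species_levels[i + 1 :]
    ]

    def attributes(Y):
        attrs = _trajectory_attributes(Y, design, ages)
        out = {}
        for s1, s2 in pairs:
            p1, d1, m1 = attrs[s1]
            p2, d2, m2 = attrs[s2]
            out[(s1, s2)] = (
                abs(p1 - p2),
                vector_angle(d1, d2),
                _trajectory_shape_distance(m1, m2),
            )
        return out

    obs = attributes(Y_tr)
    n = Y_tr.shape[0]
    counts = {pair: np.zeros(3) for pair in pairs}
    if exhaustive:
        from itertools import permutations as _perms
        from math import factorial

        if n > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8")
        perm_iter = (np.asarray(p) for p in _perms(range(n)))
        n_perm = factorial(n)
    else:
        rng = np.random.default_rng(seed)
        perm_iter = (rng.permutation(n) for _ in range(n_perm))
    for idx in perm_iter:
        Ystar = fitted_r + resid_r[idx]
        perm = attributes(Ystar)
        for pair in pairs:
            counts[pair] += np.asarray(perm[pair]) >= np.asarray(obs[pair]) - 1e-12
    rows = []
    for s1, s2 in pairs:
        pd_, ang, shp = obs[(s1, s2)]
        c = counts[(s1, s2)]
        if exhaustive:
            pvals = c / n_perm
        else:
            pvals = (c + 1) / (n_perm + 1)
        rows.append(
            {
                "species_1": s1,
                "species_2": s2,
                "path_distance_diff": pd_,
                "p_path": pvals[0],
                "direction_angle": ang,
                "p_angle": pvals[1],
                "shape_distance": shp,
                "p_shape": pvals[2],
                "n_perm": n_perm,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)
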